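"""The composite modelling pipeline.

One call chains the whole workflow on an indicator table: feature
assembly -> seeded 2:1:1 split -> candidate search over hidden-layer
sizes -> sensitivity analysis on the validation partition -> input
pruning with retraining -> final report.  Every artefact (model JSON,
report CSV, sensitivity CSV, predictions CSV, run log) lands in the
output directory, and the run is fully reproducible from its logged
configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, SizeError
from .indicators import design_matrix
from .io import read_indicator_table, read_landmarks
from .indicators import compute_indicators, indicator_table
from .landmarks import AGE_MAX, AGE_MIN
from .rbf import (
    DataSplit,
    ModelReport,
    RBFModel,
    designer_search,
    report,
    save_model,
    split_cohort,
)
from .sensitivity import SensitivityReport, prune_and_retrain, sensitivity_analysis

log = logging.getLogger("dentage")

DEFAULT_H_CANDIDATES = (5, 10, 15, 20, 25)


@dataclass
class PipelineConfig:
    """Everything a composite run needs; flags mirror these names."""

    outdir: str | Path = "dentage-run"
    indicators: str | Path | None = None   # indicator CSV, or
    landmarks: str | Path | None = None    # landmark CSV to derive it from
    sex_filter: str = "all"                # all | F | M
    include_sex: bool | None = None        # default: only for sex_filter=all
    h_candidates: tuple[int, ...] = DEFAULT_H_CANDIDATES
    n_test: int = 20
    n_retain: int = 10
    prune_threshold: float = 1.0
    ridge: float = 1e-8
    spread: float = 2.0
    seed: int = 0
    allow_any_age: bool = False
    clamp_predictions: bool = False

    def validate(self) -> None:
        if self.sex_filter not in ("all", "F", "M"):
            raise ConfigurationError(f"sex_filter must be all/F/M, got {self.sex_filter!r}")
        if not self.h_candidates:
            raise ConfigurationError("h_candidates must be non-empty")
        if not (self.n_test >= self.n_retain >= 1):
            raise ConfigurationError("need n_test >= n_retain >= 1")
        if self.prune_threshold <= 0:
            raise ConfigurationError("prune_threshold must be positive")


@dataclass
class PipelineResult:
    """Artefacts of one composite run."""

    config: PipelineConfig
    split: DataSplit
    initial_model: RBFModel
    initial_report: ModelReport
    sensitivity: SensitivityReport
    final_model: RBFModel
    final_report: ModelReport
    predictions: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _load_table(config: PipelineConfig, table: pd.DataFrame | None) -> pd.DataFrame:
    if table is not None:
        return table
    if config.indicators is not None:
        return read_indicator_table(config.indicators)
    if config.landmarks is not None:
        cases = read_landmarks(
            config.landmarks, enforce_age_range=not config.allow_any_age
        )
        return indicator_table([compute_indicators(c) for c in cases])
    raise ConfigurationError("no input: set indicators, landmarks, or pass a table")


def run_pipeline(
    config: PipelineConfig, table: pd.DataFrame | None = None
) -> PipelineResult:
    """Execute the full workflow and write the artefact bundle.

    ``table`` short-circuits file input (used by the simulator and by
    tests); otherwise ``config.indicators`` / ``config.landmarks``
    names the input file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    df = _load_table(config, table)
    if not config.allow_any_age:
        ages = df["age_months"]
        bad = ages.notna() & ((ages < AGE_MIN) | (ages > AGE_MAX))
        if bad.any():
            raise SizeError(
                f"{int(bad.sum())} case(s) outside the [{AGE_MIN}, {AGE_MAX}] month "
                "validity window; rerun with allow_any_age to keep them"
            )
    if config.sex_filter != "all":
        df = df[df["sex"] == config.sex_filter]
    include_sex = (
        config.include_sex if config.include_sex is not None
        else config.sex_filter == "all"
    )
    X, y = design_matrix(df, include_sex=include_sex)
    log.info("cohort: %d cases, %d inputs", len(X), X.shape[1])

    split = split_cohort(list(X.index), config.seed)
    log.info(
        "split %d/%d/%d (train/valid/test)",
        len(split.train_ids), len(split.valid_ids), len(split.test_ids),
    )

    retained = designer_search(
        X, y, split, config.h_candidates,
        n_test=config.n_test, n_retain=config.n_retain,
        seed=config.seed, ridge=config.ridge, spread=config.spread,
    )
    best = retained[0]
    log.info(
        "designer search: kept %d candidates; best %s (validation RMSE %.4f)",
        len(retained), best.model.topology, best.validation_rmse,
    )
    initial_report = report(best.model, X, y, split)

    X_va, y_va = X.loc[list(split.valid_ids)], y.loc[list(split.valid_ids)]
    sens = sensitivity_analysis(best.model, X_va, y_va)

    final = prune_and_retrain(
        best.model, sens, X, y, split,
        threshold=config.prune_threshold, seed=config.seed,
        ridge=config.ridge, spread=config.spread,
    )
    log.info("pruned %s -> %s", best.model.topology, final.topology)
    final_report = report(final, X, y, split)

    part = pd.Series("training", index=X.index, dtype=object)
    part.loc[list(split.valid_ids)] = "validation"
    part.loc[list(split.test_ids)] = "testing"
    predictions = pd.DataFrame(
        {
            "case_id": X.index,
            "partition": part,
            "age_months": y,
            "predicted_months": final.predict(X, clamp=config.clamp_predictions),
        }
    )

    paths = {
        "model": outdir / "model.json",
        "initial_model": outdir / "initial_model.json",
        "report": outdir / "report.csv",
        "sensitivity": outdir / "sensitivity.csv",
        "predictions": outdir / "predictions.csv",
        "log": outdir / "run_log.txt",
    }
    save_model(final, paths["model"])
    save_model(best.model, paths["initial_model"])
    rep = initial_report.to_frame().rename(columns={"value": "initial"})
    rep["final"] = final_report.to_frame()["value"]
    rep.to_csv(paths["report"], index=False)
    sens.to_csv(paths["sensitivity"])
    predictions.to_csv(paths["predictions"], index=False)
    cfg_lines = [f"{k} = {v}" for k, v in asdict(config).items()]
    paths["log"].write_text(
        "\n".join(
            ["# dentage pipeline run"]
            + cfg_lines
            + [
                f"n_cases = {len(X)}",
                f"initial_topology = {best.model.topology}",
                f"final_topology = {final.topology}",
                f"final_testing_quality = {final_report.testing_quality!r}",
                f"final_testing_error = {final_report.testing_error!r}",
            ]
        )
        + "\n",
        encoding="utf-8",
    )

    return PipelineResult(
        config, split, best.model, initial_report, sens, final, final_report,
        predictions, paths,
    )
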