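"""Sensitivity-quotient analysis and input pruning.

For every input variable of a fitted model, the sensitivity quotient is

    q_k = RMSE(model with input k mean-substituted) / RMSE(full model)

evaluated on a chosen partition, where "mean-substituted" replaces the
variable in every case by its training-partition mean — the classic
missing-value substitution that makes an input uninformative without
refitting.  A quotient above 1 marks a variable the model relies on;
a quotient of exactly 1 means the substitution changed nothing.

Rankings sort quotients in descending order with stable tie-breaking
(the earlier-listed variable keeps the smaller rank).  Pruning drops
inputs below a quotient threshold and refits on the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import NumericalError, PruningError, SizeError
from .rbf import DataSplit, RBFModel, fit_rbf, rmse_scaled


@dataclass
class SensitivityReport:
    """Ordered (variable, quotient, rank) rows, rank 1 = most important."""

    rows: list[tuple[str, float, int]]

    def quotients(self) -> dict[str, float]:
        return {v: q for v, q, _ in self.rows}

    def ranks(self) -> dict[str, int]:
        return {v: r for v, q, r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["variable", "quotient", "rank"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def rank_quotients(quotients: Mapping[str, float]) -> SensitivityReport:
    """Rank a variable -> quotient mapping.

    Descending stable sort: equal quotients keep the mapping's own
    order, so the earlier-listed variable gets the smaller rank.
    """
    if not quotients:
        raise SizeError("cannot rank an empty quotient mapping")
    ordered = sorted(quotients.items(), key=lambda kv: -kv[1])
    return SensitivityReport(
        [(name, float(q), rank) for rank, (name, q) in enumerate(ordered, start=1)]
    )


def sensitivity_analysis(model: RBFModel, X: pd.DataFrame, y) -> SensitivityReport:
    """Quotient per input of ``model``, evaluated on the cases given.

    The substitution value for each input is the model's stored
    training-partition mean, so the analysis partition may differ from
    the training one (the default workflow uses validation cases).
    """
    base = rmse_scaled(model, X, y)
    if base < 1e-9:  # numerically zero baseline
        raise NumericalError(
            "full-model RMSE is zero on these cases; an interpolating model "
            "cannot be analyzed on its own training set"
        )
    quot: dict[str, float] = {}
    for i, name in enumerate(model.input_names):
        X_sub = X.copy()
        X_sub[name] = model.input_means[i]
        quot[name] = rmse_scaled(model, X_sub, y) / base
    return rank_quotients(quot)


def prune_and_retrain(
    model: RBFModel,
    sens: SensitivityReport,
    X: pd.DataFrame,
    y: pd.Series,
    split: DataSplit,
    *,
    threshold: float = 1.0,
    seed: int = 0,
    ridge: float = 1e-8,
    spread: float = 2.0,
) -> RBFModel:
    """Drop inputs with quotient below ``threshold`` and refit.

    Retained inputs keep the model's original order.  The hidden-layer
    size is preserved unless it exceeds the training-case count after
    pruning.  Raises :class:`PruningError` if nothing would survive.
    """
    if threshold <= 0:
        raise PruningError("threshold must be positive")
    q = sens.quotients()
    retained = [n for n in model.input_names if q.get(n, float("inf")) >= threshold]
    if not retained:
        raise PruningError(
            f"threshold {threshold} would prune every input; lower it"
        )
    X_tr = X.loc[list(split.train_ids), retained]
    y_tr = y.loc[list(split.train_ids)]
    H = min(model.n_hidden, len(X_tr))
    return fit_rbf(X_tr, y_tr, H, seed=seed, ridge=ridge, spread=spread)
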