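"""Radial-basis-function regression of chronological age.

The model is a single hidden layer of Gaussian radial units followed by
a linear output unit:

    f(x) = b + sum_j  w_j * exp( -||x_s - c_j||^2 / (2 s_j^2) )

where ``x_s`` is the input min-max scaled to [0, 1] with parameters
fitted on the training partition only, ``c_j`` are hidden-unit centers
(scaled units), ``s_j`` their widths, and the output is mapped back to
months by the inverse output scaling.  Centers come from seeded k-means
on the scaled training inputs; the width of each unit is its
nearest-other-center distance times a spread factor; output weights are
the ridge-regularized least-squares solution (bias unpenalized).

Reporting follows the convention of the source methodology: per
partition a "quality" (Pearson correlation of predicted and observed
age, close to 1 for a good model) and an "error" (RMSE on the scaled
output, so 0.036 means about 3.5 months over a 96-month span).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .errors import (
    CapacityError,
    ConfigurationError,
    DegenerateColumnError,
    FormatError,
    MissingFeatureError,
    NumericalError,
    SchemaVersionError,
    SizeError,
    UndefinedQualityError,
)
from .landmarks import AGE_MAX, AGE_MIN

_SCHEMA = "dentage-rbf/1"

DEFAULT_RIDGE = 1e-8
DEFAULT_SPREAD = 2.0
_WIDTH_EPS = 1e-6


# ---------------------------------------------------------------------------
# scaling

@dataclass
class ScaleParams:
    """Min-max scaling parameters fitted on the training partition."""

    names: tuple[str, ...]
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> "ScaleParams":
        x_min = X.min(axis=0)
        x_max = X.max(axis=0)
        flat = np.flatnonzero(x_max <= x_min)
        if flat.size:
            raise DegenerateColumnError(
                f"zero-range input column(s): {[names[i] for i in flat]}"
            )
        y_min, y_max = float(y.min()), float(y.max())
        if y_max <= y_min:
            # Constant target: center it in a unit output range so the fit
            # degenerates gracefully to a constant predictor.
            y_min, y_max = y_min - 0.5, y_max + 0.5
        return cls(tuple(names), x_min, x_max, y_min, y_max)

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_min) / (self.x_max - self.x_min)

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_min) / (self.y_max - self.y_min)

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        return np.asarray(ys, dtype=float) * (self.y_max - self.y_min) + self.y_min


def minimax_scale(values: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Affine map of ``values`` onto [0, 1] given a (min, max) pair."""
    if vmax <= vmin:
        raise DegenerateColumnError(f"degenerate range [{vmin}, {vmax}]")
    return (np.asarray(values, dtype=float) - vmin) / (vmax - vmin)


def minimax_unscale(scaled: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Inverse of :func:`minimax_scale`."""
    if vmax <= vmin:
        raise DegenerateColumnError(f"degenerate range [{vmin}, {vmax}]")
    return np.asarray(scaled, dtype=float) * (vmax - vmin) + vmin


# ---------------------------------------------------------------------------
# splitting

@dataclass
class DataSplit:
    """Disjoint train/validation/test case ids in 2:1:1 allocation."""

    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.train_ids + self.valid_ids + self.test_ids


def split_cohort(ids: Sequence[str], seed: int) -> DataSplit:
    """Seeded random 2:1:1 split: floor(n/2) / floor(n/4) / remainder."""
    ids = list(ids)
    n = len(ids)
    if n < 4:
        raise SizeError(f"need at least 4 cases to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = n // 2
    n_valid = n // 4
    shuffled = [ids[i] for i in perm]
    return DataSplit(
        tuple(shuffled[:n_train]),
        tuple(shuffled[n_train : n_train + n_valid]),
        tuple(shuffled[n_train + n_valid :]),
    )


# ---------------------------------------------------------------------------
# topology strings

_TOPOLOGY_RE = re.compile(r"^RBF (\d+):(\d+)-(\d+)-(\d+):(\d+)$")


def format_topology(n_inputs: int, n_hidden: int, n_outputs: int = 1) -> str:
    return f"RBF {n_inputs}:{n_inputs}-{n_hidden}-{n_outputs}:{n_outputs}"


def parse_topology(s: str) -> tuple[int, int, int]:
    """Parse ``'RBF I:I-H-O:O'`` into ``(inputs, hidden, outputs)``."""
    m = _TOPOLOGY_RE.match(s)
    if not m:
        raise FormatError(f"malformed topology string {s!r}")
    i1, i2, h, o1, o2 = (int(g) for g in m.groups())
    if i1 != i2 or o1 != o2:
        raise FormatError(f"inconsistent layer counts in topology {s!r}")
    return i1, h, o1


# ---------------------------------------------------------------------------
# the model

@dataclass
class RBFModel:
    """A fitted radial-basis-function age-regression network."""

    input_names: tuple[str, ...]
    centers: np.ndarray       # (H, d), scaled units
    widths: np.ndarray        # (H,)
    weights: np.ndarray       # (H + 1,); last entry is the output bias
    scale: ScaleParams
    input_means: np.ndarray   # raw-unit training means, for sensitivity analysis
    topology: str = ""

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.asarray(self.widths, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.input_means = np.asarray(self.input_means, dtype=float)
        H = self.centers.shape[0]
        if H < 1:
            raise ConfigurationError("model needs at least one hidden unit")
        if np.any(self.widths <= 0):
            raise ConfigurationError("all widths must be positive")
        if self.widths.shape != (H,) or self.weights.shape != (H + 1,):
            raise ConfigurationError("inconsistent center/width/weight shapes")
        if not self.topology:
            self.topology = format_topology(len(self.input_names), H)

    @property
    def n_hidden(self) -> int:
        return self.centers.shape[0]

    # -- evaluation ---------------------------------------------------------

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.input_names if n not in X.columns]
            if missing:
                raise MissingFeatureError(f"input(s) absent from data: {missing}")
            X = X[list(self.input_names)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.input_names):
            raise MissingFeatureError(
                f"expected {len(self.input_names)} inputs, got {X.shape[1]}"
            )
        if np.isnan(X).any():
            raise MissingFeatureError("feature matrix contains missing values")
        return X

    def activations(self, X) -> np.ndarray:
        """Hidden-layer Gaussian activations, one row per case."""
        Xs = self.scale.scale_x(self._as_matrix(X))
        d2 = cdist(Xs, self.centers, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * self.widths**2))

    def predict_scaled(self, X) -> np.ndarray:
        phi = self.activations(X)
        return phi @ self.weights[:-1] + self.weights[-1]

    def predict(self, X, *, clamp: bool = False) -> np.ndarray:
        """Predicted age in months; ``clamp`` limits to [48, 144]."""
        y = self.scale.unscale_y(self.predict_scaled(X))
        if clamp:
            y = np.clip(y, AGE_MIN, AGE_MAX)
        return y


def predict_age(model: RBFModel, features, *, clamp: bool = False):
    """Predict age for one feature vector or a feature matrix."""
    vals = getattr(features, "values", features)
    arr = np.asarray(vals, dtype=float)
    out = model.predict(arr, clamp=clamp)
    return float(out[0]) if arr.ndim == 1 else out


# ---------------------------------------------------------------------------
# fitting

def _choose_centers(Xs: np.ndarray, H: int, seed: int) -> np.ndarray:
    uniq = np.unique(Xs, axis=0)
    if H >= len(uniq):
        # As many units as distinct cases: every distinct point is a center
        # (the interpolation regime); k-means would only reproduce this.
        return uniq
    km = KMeans(n_clusters=H, n_init=10, random_state=int(seed) % (2**32))
    km.fit(Xs)
    centers = km.cluster_centers_
    # Guard against coincident centers (possible on adversarial ties): keep
    # distinct ones and pad with unused distinct training points.
    dist = cdist(centers, centers)
    np.fill_diagonal(dist, np.inf)
    keep = []
    for i in range(len(centers)):
        if all(dist[i, j] > 1e-12 for j in keep):
            keep.append(i)
    centers = centers[keep]
    if len(centers) < H:
        rng = np.random.default_rng(seed)
        pool = rng.permutation(len(uniq))
        for idx in pool:
            if len(centers) == H:
                break
            cand = uniq[idx]
            if cdist(cand[None, :], centers).min() > 1e-12:
                centers = np.vstack([centers, cand])
    return centers


def _widths_for(centers: np.ndarray, Xs: np.ndarray, spread: float) -> np.ndarray:
    H = centers.shape[0]
    if H == 1:
        # No neighbouring center: use the data radius around the center.
        d = cdist(Xs, centers).max()
        return np.array([max(d, _WIDTH_EPS) * spread])
    dist = cdist(centers, centers)
    np.fill_diagonal(dist, np.inf)
    nearest = dist.min(axis=1)
    return np.maximum(nearest, _WIDTH_EPS) * spread


def _solve_output_weights(phi: np.ndarray, ys: np.ndarray, ridge: float) -> np.ndarray:
    """Ridge least squares for [hidden weights, bias]; bias unpenalized."""
    n, H = phi.shape
    A = np.hstack([phi, np.ones((n, 1))])
    if ridge > 0:
        pen = np.sqrt(ridge) * np.eye(H + 1)
        pen[H, H] = 0.0  # bias not penalized
        A_aug = np.vstack([A, pen[:H]])
        b_aug = np.concatenate([ys, np.zeros(H)])
        w, *_ = np.linalg.lstsq(A_aug, b_aug, rcond=None)
        return w
    if n >= H + 1 and np.linalg.matrix_rank(A) < H + 1:
        raise NumericalError(
            "singular design matrix with ridge = 0; set ridge > 0 to regularize"
        )
    w, *_ = np.linalg.lstsq(A, ys, rcond=None)
    return w


def fit_rbf(
    X,
    y,
    H: int,
    *,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    spread: float = DEFAULT_SPREAD,
    input_names: Sequence[str] | None = None,
    centers: np.ndarray | None = None,
) -> RBFModel:
    """Fit an RBF network on a training set.

    ``X`` is a DataFrame (columns = input names) or an array with
    ``input_names`` given; ``y`` is age in months.  ``centers``
    (scaled units) overrides the seeded k-means selection — used for
    controlled experiments with fixed hidden layers.
    """
    if isinstance(X, pd.DataFrame):
        input_names = tuple(X.columns)
        Xr = X.to_numpy(dtype=float)
    else:
        Xr = np.atleast_2d(np.asarray(X, dtype=float))
        if input_names is None:
            input_names = tuple(f"V{i+1:02d}" for i in range(Xr.shape[1]))
    yr = np.asarray(y, dtype=float)
    n = Xr.shape[0]
    if np.isnan(Xr).any() or np.isnan(yr).any():
        raise MissingFeatureError("training data contains missing values")
    if H < 1:
        raise ConfigurationError("H must be at least 1")
    if H > n:
        raise CapacityError(f"H = {H} exceeds the {n} training cases")

    scale = ScaleParams.fit(Xr, yr, input_names)
    Xs = scale.scale_x(Xr)
    ys = scale.scale_y(yr)

    C = np.atleast_2d(np.asarray(centers, dtype=float)) if centers is not None \
        else _choose_centers(Xs, H, seed)
    widths = _widths_for(C, Xs, spread)
    d2 = cdist(Xs, C, metric="sqeuclidean")
    phi = np.exp(-d2 / (2.0 * widths**2))
    w = _solve_output_weights(phi, ys, ridge)

    return RBFModel(
        input_names=tuple(input_names),
        centers=C,
        widths=widths,
        weights=w,
        scale=scale,
        input_means=Xr.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# quality / error metrics

def quality(predictions, targets) -> float:
    """Pearson correlation between predicted and observed age."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.size != t.size or p.size < 2:
        raise UndefinedQualityError("quality needs at least 2 paired cases")
    if np.std(p) == 0 or np.std(t) == 0:
        raise UndefinedQualityError("quality undefined for zero-variance vectors")
    return float(np.corrcoef(p, t)[0, 1])


def rmse_scaled(model: RBFModel, X, y) -> float:
    """RMSE between scaled predictions and scaled targets."""
    yt = np.asarray(y, dtype=float)
    if yt.size == 0:
        raise SizeError("empty case set")
    resid = model.predict_scaled(X) - model.scale.scale_y(yt)
    return float(np.sqrt(np.mean(resid**2)))


@dataclass
class ModelReport:
    """Quality and scaled RMSE per partition (the six summary numbers)."""

    training_quality: float
    validation_quality: float
    testing_quality: float
    training_error: float
    validation_error: float
    testing_error: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Training quality", self.training_quality),
            ("Validation quality", self.validation_quality),
            ("Testing quality", self.testing_quality),
            ("Training error", self.training_error),
            ("Validation error", self.validation_error),
            ("Testing error", self.testing_error),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def report(model: RBFModel, X: pd.DataFrame, y: pd.Series, split: DataSplit) -> ModelReport:
    """Evaluate a model on all three partitions of a cohort."""
    vals = {}
    for part, ids in (
        ("training", split.train_ids),
        ("validation", split.valid_ids),
        ("testing", split.test_ids),
    ):
        Xp, yp = X.loc[list(ids)], y.loc[list(ids)]
        vals[f"{part}_quality"] = quality(model.predict(Xp), yp)
        vals[f"{part}_error"] = rmse_scaled(model, Xp, yp)
    return ModelReport(**vals)


# ---------------------------------------------------------------------------
# candidate search ("automatic designer")

@dataclass
class Candidate:
    """One trained search candidate with its validation error."""

    model: RBFModel
    H: int
    fit_seed: int
    validation_rmse: float


def designer_search(
    X: pd.DataFrame,
    y: pd.Series,
    split: DataSplit,
    H_candidates: Sequence[int],
    *,
    n_test: int = 20,
    n_retain: int = 10,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    spread: float = DEFAULT_SPREAD,
) -> list[Candidate]:
    """Train ``n_test`` seeded candidates and keep the best ``n_retain``.

    Candidates draw a hidden-unit count from ``H_candidates`` and a
    fitting seed from the search seed.  Retention ranks by validation
    RMSE under a diversity rule: at most ceil(n_retain / 2) retained
    models may share one H, so the short-list is never a single
    topology.
    """
    if not len(H_candidates):
        raise ConfigurationError("H_candidates must be non-empty")
    if not (n_test >= n_retain >= 1):
        raise ConfigurationError("need n_test >= n_retain >= 1")
    rng = np.random.default_rng(seed)
    Hs = rng.choice(np.asarray(H_candidates, dtype=int), size=n_test)
    fit_seeds = rng.integers(0, 2**31 - 1, size=n_test)
    n_train = len(split.train_ids)
    X_tr, y_tr = X.loc[list(split.train_ids)], y.loc[list(split.train_ids)]
    X_va, y_va = X.loc[list(split.valid_ids)], y.loc[list(split.valid_ids)]

    cands: list[Candidate] = []
    for H, fs in zip(Hs, fit_seeds):
        H_eff = int(min(H, n_train))
        m = fit_rbf(X_tr, y_tr, H_eff, seed=int(fs), ridge=ridge, spread=spread)
        cands.append(Candidate(m, H_eff, int(fs), rmse_scaled(m, X_va, y_va)))

    cands.sort(key=lambda c: c.validation_rmse)  # stable: ties keep draw order
    cap = -(-n_retain // 2)  # ceil
    retained: list[Candidate] = []
    per_h: dict[int, int] = {}
    for c in cands:
        if len(retained) == n_retain:
            break
        if per_h.get(c.H, 0) >= cap:
            continue
        retained.append(c)
        per_h[c.H] = per_h.get(c.H, 0) + 1
    return retained


# ---------------------------------------------------------------------------
# persistence

def save_model(model: RBFModel, path) -> None:
    """Serialize to schema-versioned JSON at full float precision."""
    doc = {
        "schema": _SCHEMA,
        "input_names": list(model.input_names),
        "centers": model.centers.tolist(),
        "widths": model.widths.tolist(),
        "weights": model.weights.tolist(),
        "input_means": model.input_means.tolist(),
        "scale": {
            "names": list(model.scale.names),
            "x_min": model.scale.x_min.tolist(),
            "x_max": model.scale.x_max.tolist(),
            "y_min": model.scale.y_min,
            "y_max": model.scale.y_max,
        },
        "topology": model.topology,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")


def load_model(path) -> RBFModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != _SCHEMA:
        raise SchemaVersionError(
            f"{path}: expected schema {_SCHEMA!r}, found {doc.get('schema')!r}"
        )
    try:
        sc = doc["scale"]
        scale = ScaleParams(
            tuple(sc["names"]),
            np.asarray(sc["x_min"], dtype=float),
            np.asarray(sc["x_max"], dtype=float),
            float(sc["y_min"]),
            float(sc["y_max"]),
        )
        return RBFModel(
            input_names=tuple(doc["input_names"]),
            centers=np.asarray(doc["centers"], dtype=float),
            widths=np.asarray(doc["widths"], dtype=float),
            weights=np.asarray(doc["weights"], dtype=float),
            scale=scale,
            input_means=np.asarray(doc["input_means"], dtype=float),
            topology=doc["topology"],
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing model field {exc.args[0]!r}") from None
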