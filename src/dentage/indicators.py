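"""The 21 ratio indicators and model-ready feature vectors.

Each indicator is the ratio of two Euclidean segment lengths between
named pantomogram landmarks.  Ratios are dimensionless, so the values
are invariant to translation, rotation and uniform scaling of the image
— the property that makes measurements portable across radiographic
devices with different magnification.

The set splits into three anatomical families:

* X01–X06 — inter-arch proportions between the canine/premolar/molar
  crown-to-crown segments (|C13C43| … |C17C47|);
* X07–X14 — per-tooth maturation ratios of crown–apex against the
  projected reference segment, and of the cemento-enamel crown width
  against its projected counterpart;
* X15–X21 — crown/apex position relative to the mandibular border and
  proportions between the apex–border segments of neighbouring teeth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingFeatureError, MissingLandmarkError
from .io import INDICATOR_NAMES
from .landmarks import LandmarkSet, is_valid_label

SEX_NAME = "SEX"


@dataclass(frozen=True)
class SegmentDef:
    """A straight segment between two distinct vocabulary labels."""

    endpoint_a: str
    endpoint_b: str

    def __post_init__(self):
        if not (is_valid_label(self.endpoint_a) and is_valid_label(self.endpoint_b)):
            raise ValueError(f"segment endpoints must be vocabulary labels: {self}")
        if self.endpoint_a == self.endpoint_b:
            raise ValueError(f"segment endpoints must differ: {self}")


def _seg(a: str, b: str) -> SegmentDef:
    return SegmentDef(a, b)


#: indicator -> (numerator segment, denominator segment)
INDICATOR_SEGMENTS: dict[str, tuple[SegmentDef, SegmentDef]] = {
    "X01": (_seg("C13", "C43"), _seg("C15", "C45")),
    "X02": (_seg("C13", "C43"), _seg("C16", "C46")),
    "X03": (_seg("C13", "C43"), _seg("C17", "C47")),
    "X04": (_seg("C15", "C45"), _seg("C16", "C46")),
    "X05": (_seg("C15", "C45"), _seg("C17", "C47")),
    "X06": (_seg("C16", "C46"), _seg("C17", "C47")),
    "X07": (_seg("C43", "A43"), _seg("P43", "A43")),
    "X08": (_seg("C45", "A45"), _seg("P45", "A45")),
    "X09": (_seg("C46", "A46"), _seg("P46", "A46")),
    "X10": (_seg("C47", "A47"), _seg("P47", "A47")),
    "X11": (_seg("CeM43", "CeD43"), _seg("PCeM43", "PCeD43")),
    "X12": (_seg("CeM45", "CeD45"), _seg("PCeM45", "PCeD45")),
    "X13": (_seg("CeM46", "CeD46"), _seg("PCeM46", "PCeD46")),
    "X14": (_seg("CeM47", "CeD47"), _seg("PCeM47", "PCeD47")),
    "X15": (_seg("C43", "M43"), _seg("A43", "M43")),
    "X16": (_seg("C45", "M45"), _seg("A45", "M45")),
    "X17": (_seg("C46", "M46"), _seg("A46", "M46")),
    "X18": (_seg("C47", "M47"), _seg("A47", "M47")),
    "X19": (_seg("A43", "M43"), _seg("A45", "M45")),
    "X20": (_seg("A43", "M43"), _seg("A46", "M46")),
    "X21": (_seg("A45", "M45"), _seg("A46", "M46")),
}

assert tuple(INDICATOR_SEGMENTS) == INDICATOR_NAMES


def indicator_labels(name: str) -> frozenset[str]:
    """The (up to four) landmark labels an indicator depends on."""
    num, den = INDICATOR_SEGMENTS[name]
    return frozenset({num.endpoint_a, num.endpoint_b, den.endpoint_a, den.endpoint_b})


def segment_length(s: LandmarkSet, d: SegmentDef) -> float:
    """Euclidean length, in pixels, of segment ``d`` on case ``s``."""
    try:
        xa, ya = s.points[d.endpoint_a]
        xb, yb = s.points[d.endpoint_b]
    except KeyError as exc:
        raise MissingLandmarkError(
            f"case {s.case_id!r}: landmark {exc.args[0]!r} absent"
        ) from None
    return math.hypot(xa - xb, ya - yb)


@dataclass
class IndicatorVector:
    """The 21 dimensionless ratios of one case; absent slots allowed."""

    case_id: str
    sex: str
    age_months: int | None = None
    values: dict[str, float] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(n in self.values for n in INDICATOR_NAMES)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class FeatureVector:
    """An ordered, model-ready input vector with optional target age."""

    names: tuple[str, ...]
    values: np.ndarray
    age_months: int | None = None


def compute_indicators(s: LandmarkSet) -> IndicatorVector:
    """Compute every indicator whose four endpoints are present.

    A zero (or non-positive) denominator, or a zero numerator, makes the
    ratio degenerate: the slot stays absent and a warning is issued,
    because a non-positive ratio carries no anatomical meaning.
    """
    v = IndicatorVector(s.case_id, s.sex, s.age_months)
    for name, (num, den) in INDICATOR_SEGMENTS.items():
        if not indicator_labels(name).issubset(s.points):
            continue
        dlen = segment_length(s, den)
        nlen = segment_length(s, num)
        if dlen <= 0.0 or nlen <= 0.0:
            warnings.warn(
                f"case {s.case_id!r}: degenerate segment for {name}; value omitted",
                stacklevel=2,
            )
            continue
        v.values[name] = nlen / dlen
    return v


def encode_sex(sex: str) -> float:
    """Binary sex encoding used in model inputs: F -> 0, M -> 1."""
    return {"F": 0.0, "M": 1.0}[sex]


def assemble_features(
    v: IndicatorVector,
    *,
    include_sex: bool = True,
    retained: list[str] | None = None,
) -> FeatureVector:
    """Build one model input vector from an indicator vector.

    Default order is X01..X21 followed by SEX (22 inputs); sex-specific
    models drop SEX (21).  With ``retained``, names follow exactly that
    list (which may include SEX).
    """
    if retained is None:
        names = list(INDICATOR_NAMES) + ([SEX_NAME] if include_sex else [])
    else:
        if len(set(retained)) != len(retained):
            raise MissingFeatureError(f"retained names are not unique: {retained}")
        names = list(retained)
    vals = []
    for n in names:
        if n == SEX_NAME:
            vals.append(encode_sex(v.sex))
        elif n in v.values:
            vals.append(v.values[n])
        else:
            raise MissingFeatureError(f"case {v.case_id!r}: feature {n!r} absent")
    return FeatureVector(tuple(names), np.asarray(vals, dtype=float), v.age_months)


def indicator_table(vectors: list[IndicatorVector]) -> pd.DataFrame:
    """Assemble indicator vectors into the indicator-CSV DataFrame."""
    rows = []
    for v in vectors:
        row = {"case_id": v.case_id, "sex": v.sex, "age_months": v.age_months}
        row.update({n: v.values.get(n, np.nan) for n in INDICATOR_NAMES})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["case_id", "sex", "age_months"] + list(INDICATOR_NAMES))
    df["age_months"] = df["age_months"].astype("Int64")
    df = df.set_index("case_id", drop=False)
    df.index.name = None
    return df


def design_matrix(
    df: pd.DataFrame,
    *,
    include_sex: bool = True,
    retained: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Indicator table -> (X, y) for model fitting.

    Rows with any required input absent, or without age, are dropped
    with a warning — models require complete features and a target.
    Returns ``X`` (columns = input names, index = case_id) and ``y``
    (age in months).
    """
    if retained is None:
        names = list(INDICATOR_NAMES) + ([SEX_NAME] if include_sex else [])
    else:
        names = list(retained)
    work = df.copy()
    work[SEX_NAME] = work["sex"].map({"F": 0.0, "M": 1.0})
    missing = [n for n in names if n not in work.columns]
    if missing:
        raise MissingFeatureError(f"columns absent from indicator table: {missing}")
    X = work[names].astype(float)
    y = work["age_months"].astype(float)
    keep = X.notna().all(axis=1) & y.notna()
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(
            f"dropping {n_drop} case(s) with incomplete features or missing age",
            stacklevel=2,
        )
    return X.loc[keep], y.loc[keep]
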