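"""Synthetic study-emulating cohorts.

No public dataset of annotated pantomograms exists for this method, so
the package ships a generator that emulates the study population: 296
girls and 323 boys aged 48-144 months, with indicator values that
change monotonically with age.  Root-maturation ratios (X07-X18) follow
logistic curves rising toward an asymptote, mimicking progressive root
elongation and apex closure; arch-proportion ratios follow gentle
linear trends.  Girls run ahead of boys by a configurable offset
(default 3 months), reflecting earlier dental maturation.

Geometric consistency.  Four of the 21 indicators are exact products of
others because they share landmark segments:

    X02 = X01 * X04,   X03 = X01 * X04 * X06,
    X05 = X04 * X06,   X20 = X19 * X21.

The generator therefore draws the 17 free indicators from their noisy
trajectories and derives the dependent four, so every synthetic case is
realizable by an actual landmark configuration — which is what
:func:`generate_landmarks` produces, exactly inverting the indicator
computation on a parametric jaw template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .indicators import INDICATOR_NAMES, IndicatorVector
from .landmarks import AGE_MAX, AGE_MIN, LOWER_TEETH, LandmarkSet

#: dependent indicator -> the free indicators whose product it equals
DERIVED_INDICATORS: dict[str, tuple[str, ...]] = {
    "X02": ("X01", "X04"),
    "X03": ("X01", "X04", "X06"),
    "X05": ("X04", "X06"),
    "X20": ("X19", "X21"),
}

FREE_INDICATORS = tuple(n for n in INDICATOR_NAMES if n not in DERIVED_INDICATORS)


@dataclass(frozen=True)
class IndicatorTrajectory:
    """Monotone age-response curve of one indicator.

    ``curve`` is "logistic" (start -> end around ``midpoint`` months
    with rate ``steepness`` per month) or "linear" (start at 48 months,
    end at 144).  ``sex_offset`` advances girls' effective age in
    months.  Noise s.d. is ``noise_frac * |end - start|`` unless an
    absolute ``noise_sd`` is given (needed for flat, signal-free
    indicators whose range is zero).
    """

    curve: str
    start: float
    end: float
    midpoint: float = 96.0
    steepness: float = 0.05
    sex_offset: float = 3.0
    noise_frac: float = 0.05
    noise_sd: float | None = None

    def value(self, age_months: np.ndarray, sex: str) -> np.ndarray:
        a = np.asarray(age_months, dtype=float)
        if sex == "F":
            a = a + self.sex_offset
        if self.curve == "linear":
            t = (a - AGE_MIN) / (AGE_MAX - AGE_MIN)
            return self.start + (self.end - self.start) * t
        if self.curve == "logistic":
            z = -self.steepness * (a - self.midpoint)
            return self.start + (self.end - self.start) / (1.0 + np.exp(z))
        raise ParameterError(f"unknown curve family {self.curve!r}")

    def sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return self.noise_frac * abs(self.end - self.start)


def default_trajectories() -> dict[str, IndicatorTrajectory]:
    """Low-noise study-emulation defaults for the 17 free indicators.

    Later-developing teeth (second premolar 45, second molar 47) get
    later logistic midpoints; all curves increase with age so the
    derived product indicators are monotone too.
    """
    lin = lambda a, b: IndicatorTrajectory("linear", a, b)
    log = lambda a, b, mid: IndicatorTrajectory("logistic", a, b, midpoint=mid)
    mids = {"43": 80.0, "45": 100.0, "46": 86.0, "47": 108.0}
    t: dict[str, IndicatorTrajectory] = {
        # arch proportions: gentle linear drift
        "X01": lin(0.95, 1.10),
        "X04": lin(0.90, 1.05),
        "X06": lin(0.88, 1.02),
        # apex-border proportions between teeth
        "X19": lin(0.95, 1.12),
        "X21": lin(0.92, 1.08),
    }
    # crown-apex vs projected reference: root elongation
    for name, tooth in zip(("X07", "X08", "X09", "X10"), LOWER_TEETH):
        t[name] = log(0.55, 1.45, mids[tooth])
    # cemento-enamel width vs projection
    for name, tooth in zip(("X11", "X12", "X13", "X14"), LOWER_TEETH):
        t[name] = log(0.70, 1.30, mids[tooth])
    # crown-border vs apex-border: kept > 1 so crown-apex segments exist
    for name, tooth in zip(("X15", "X16", "X17", "X18"), LOWER_TEETH):
        t[name] = log(1.15, 1.85, mids[tooth])
    return t


@dataclass
class CohortParams:
    """Cohort-level generator settings (study-emulation defaults)."""

    n_female: int = 296
    n_male: int = 323
    months_min: int = AGE_MIN
    months_max: int = AGE_MAX
    seed: int = 0
    noise_scale: float = 1.0  # global multiplier; >1 gives stress presets
    trajectories: dict[str, IndicatorTrajectory] = field(
        default_factory=default_trajectories
    )

    def validate(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ParameterError("cohort sizes must be non-negative")
        if not (self.months_min < self.months_max):
            raise ParameterError("months_min must be below months_max")
        if self.months_min < AGE_MIN or self.months_max > AGE_MAX:
            raise ParameterError(
                f"study-emulation ages must stay within [{AGE_MIN}, {AGE_MAX}]"
            )
        if self.noise_scale < 0:
            raise ParameterError("noise_scale must be non-negative")
        missing = [n for n in FREE_INDICATORS if n not in self.trajectories]
        if missing:
            raise ParameterError(f"missing trajectories for {missing}")


def high_noise_params(seed: int = 0, factor: float = 3.0) -> CohortParams:
    """Stress preset: same curves, noise inflated by ``factor``."""
    return CohortParams(seed=seed, noise_scale=factor)


_VALUE_FLOOR = 1e-3  # indicators are ratios of positive lengths


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw a cohort as an indicator table (one row per case).

    Ages are seeded uniform integers on [months_min, months_max]; each
    free indicator is its curve value plus Gaussian noise; dependent
    indicators are derived so cases stay geometrically consistent.
    Deterministic for a fixed seed.
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows: list[pd.DataFrame] = []
    for sex, n, prefix in (("F", params.n_female, "F"), ("M", params.n_male, "M")):
        ages = rng.integers(params.months_min, params.months_max + 1, size=n)
        data = {
            "case_id": [f"{prefix}{i+1:04d}" for i in range(n)],
            "sex": sex,
            "age_months": ages,
        }
        free: dict[str, np.ndarray] = {}
        for name in FREE_INDICATORS:
            tr = params.trajectories[name]
            noise = rng.normal(0.0, tr.sd() * params.noise_scale, size=n)
            free[name] = np.maximum(tr.value(ages, sex) + noise, _VALUE_FLOOR)
        for name in INDICATOR_NAMES:
            if name in DERIVED_INDICATORS:
                val = np.ones(n)
                for parent in DERIVED_INDICATORS[name]:
                    val = val * free[parent]
                data[name] = val
            else:
                data[name] = free[name]
        rows.append(pd.DataFrame(data))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["case_id", "sex", "age_months", *INDICATOR_NAMES]
    )
    df["age_months"] = df["age_months"].astype("Int64")
    df = df.set_index("case_id", drop=False)
    df.index.name = None
    return df


# ---------------------------------------------------------------------------
# landmark realization on a parametric jaw template

_COLS = {"43": 120.0, "45": 190.0, "46": 260.0, "47": 330.0}
_UPPER = {"13": "43", "15": "45", "16": "46", "17": "47"}
_ARCH_BASE = 100.0  # |C17C47| template length, px
_AM_BASE = 40.0     # |A46M46| template length, px
_CE_WIDTH = 12.0    # |CeM CeD| template width, px
_CE_Y = 300.0
_PCE_DY = 8.0


def generate_landmarks(
    values: Mapping[str, float] | IndicatorVector,
    *,
    case_id: str = "synthetic",
    sex: str = "F",
    age_months: int | None = None,
    template_scale: float = 1.0,
) -> LandmarkSet:
    """Place the 36 landmarks so they realize a target indicator vector.

    The template fixes denominator segments (arch base, apex-border
    base, crown widths) and positions numerator endpoints to produce
    each requested ratio, so ``compute_indicators`` on the result
    recovers the target exactly (up to rounding) whenever the target
    satisfies the product identities in :data:`DERIVED_INDICATORS`.
    The free indicators used for construction are X01, X04, X06,
    X07-X18, X20 and X21.
    """
    if isinstance(values, IndicatorVector):
        if age_months is None:
            age_months = values.age_months
        case_id, sex = values.case_id, values.sex
        values = values.values
    v = {n: float(values[n]) for n in values}
    needed = [n for n in FREE_INDICATORS if n != "X19"] + ["X20"]
    for name in needed:
        if name not in v:
            raise ParameterError(f"indicator {name} required to build landmarks")
        if not (v[name] > 0.0 and math.isfinite(v[name])):
            raise ParameterError(f"indicator {name}={v[name]} is not realizable")
    if template_scale <= 0:
        raise ParameterError("template_scale must be positive")

    k = template_scale
    s = LandmarkSet(case_id, sex, age_months)

    # arch segments: vertical, upper crowns on y = 0
    arch = {"47": _ARCH_BASE}
    arch["46"] = v["X06"] * arch["47"]
    arch["45"] = v["X04"] * arch["46"]
    arch["43"] = v["X01"] * arch["45"]
    for up, lo in _UPPER.items():
        x = _COLS[lo]
        s.add_point(f"C{up}", x * k, 0.0)
        s.add_point(f"C{lo}", x * k, arch[lo] * k)

    # apex-border lengths from X20/X21 relative to the template base
    am = {
        "46": _AM_BASE,
        "47": _AM_BASE,
        "43": v["X20"] * _AM_BASE,  # |A43M43| = X20 * |A46M46|
        "45": v["X21"] * _AM_BASE,  # |A45M45| = X21 * |A46M46|
    }
    crown_border = {"43": "X15", "45": "X16", "46": "X17", "47": "X18"}
    crown_apex_q = {"43": "X07", "45": "X08", "46": "X09", "47": "X10"}
    ce_q = {"43": "X11", "45": "X12", "46": "X13", "47": "X14"}
    for tooth in LOWER_TEETH:
        x = _COLS[tooth]
        c_y = arch[tooth]
        lam = am[tooth]
        m_y = c_y + v[crown_border[tooth]] * lam  # |C M| = Xc * |A M|
        s.add_point(f"M{tooth}", x * k, m_y * k)
        # apex on the circle of radius |A M| around M, at the same height,
        # offset toward the midline so |C A| is always positive
        a_x, a_y = x - lam, m_y
        if a_x < 0:
            raise ParameterError(
                f"apex-border length for tooth {tooth} too large for the template"
            )
        s.add_point(f"A{tooth}", a_x * k, a_y * k)
        lca = math.hypot(x - a_x, c_y - a_y)  # |C A|
        # projected reference point at |P A| = |C A| / X07-family value
        p_x = a_x + lca / v[crown_apex_q[tooth]]
        s.add_point(f"P{tooth}", p_x * k, a_y * k)
        # cemento-enamel width and its projection
        half = _CE_WIDTH / 2.0
        phalf = half / v[ce_q[tooth]]
        s.add_point(f"CeM{tooth}", (x - half) * k, _CE_Y * k)
        s.add_point(f"CeD{tooth}", (x + half) * k, _CE_Y * k)
        s.add_point(f"PCeM{tooth}", (x - phalf) * k, (_CE_Y + _PCE_DY) * k)
        s.add_point(f"PCeD{tooth}", (x + phalf) * k, (_CE_Y + _PCE_DY) * k)
        if x - phalf < 0:
            raise ParameterError(
                f"cemento-enamel projection for tooth {tooth} leaves the image"
            )
    return s


def generate_landmark_cohort(params: CohortParams | None = None) -> list[LandmarkSet]:
    """A full synthetic cohort as landmark sets (indicator table inverted)."""
    df = generate_cohort(params)
    out = []
    for _, row in df.iterrows():
        vals = {n: row[n] for n in INDICATOR_NAMES}
        out.append(
            generate_landmarks(
                vals,
                case_id=row["case_id"],
                sex=row["sex"],
                age_months=int(row["age_months"]),
            )
        )
    return out
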