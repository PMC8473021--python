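"""Landmark vocabulary and per-case containers.

A pantomogram (panoramic radiograph) is annotated with 36 named points.
Labels follow FDI tooth numbering: 13 is the upper-right canine; 43, 45,
46, 47 are the lower-right canine, second premolar, first molar and
second molar.  Prefixes encode the anatomical role: ``C`` crown point,
``A`` root apex, ``M`` point on the mandibular border, ``CeM``/``CeD``
mesial/distal cemento-enamel junction, and a leading ``P`` marks the
projected reference counterpart that serves as a ratio denominator.
This reading is documented for orientation only — the package treats
labels as opaque identifiers and its contract is purely geometric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import AgeRangeError, DuplicateLandmarkError, ParameterError

#: Teeth (FDI numbers) carrying root/border landmarks, distal-ward order.
LOWER_TEETH = ("43", "45", "46", "47")

#: Closed vocabulary of the 36 landmark labels, in canonical file order.
VOCABULARY = (
    "C13", "C15", "C16", "C17",
    "C43", "C45", "C46", "C47",
    "A43", "A45", "A46", "A47",
    "P43", "P45", "P46", "P47",
    "M43", "M45", "M46", "M47",
    "CeM43", "CeD43", "CeM45", "CeD45",
    "CeM46", "CeD46", "CeM47", "CeD47",
    "PCeM43", "PCeD43", "PCeM45", "PCeD45",
    "PCeM46", "PCeD46", "PCeM47", "PCeD47",
)

_VOCAB_SET = frozenset(VOCABULARY)

SEXES = ("F", "M")

#: Validity window of the method, in months (4 to 12 years).
AGE_MIN = 48
AGE_MAX = 144


def is_valid_label(label: str) -> bool:
    return label in _VOCAB_SET


def validate_age(age_months: int | None, *, enforce_range: bool = True) -> None:
    """Raise :class:`AgeRangeError` for ages outside [48, 144] months.

    ``enforce_range=False`` disables the window check (the override used
    when ingesting cases outside the method's stated validity).
    """
    if age_months is None:
        return
    if enforce_range and not (AGE_MIN <= age_months <= AGE_MAX):
        raise AgeRangeError(
            f"age {age_months} months outside validity window "
            f"[{AGE_MIN}, {AGE_MAX}]; pass the override flag to accept it"
        )


@dataclass(frozen=True)
class LandmarkRecord:
    """One annotated point: a row of the landmark interchange CSV."""

    case_id: str
    sex: str
    age_months: int | None
    label: str
    x: float
    y: float

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ParameterError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not is_valid_label(self.label):
            raise ParameterError(f"unknown landmark label {self.label!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ParameterError(f"non-finite coordinates for {self.label}")
        if self.x < 0 or self.y < 0:
            raise ParameterError(f"negative pixel coordinate for {self.label}")


@dataclass
class LandmarkSet:
    """All annotated points of one case, keyed by label.

    Coordinates are pixels in image convention (origin top-left, y grows
    downward).  The convention never reaches results: every derived
    quantity is a ratio of Euclidean distances.
    """

    case_id: str
    sex: str
    age_months: int | None = None
    points: dict[str, tuple[float, float]] = field(default_factory=dict)

    def add_point(self, label: str, x: float, y: float) -> None:
        if label in self.points:
            raise DuplicateLandmarkError(
                f"case {self.case_id!r}: duplicate landmark {label!r}"
            )
        self.points[label] = (float(x), float(y))

    @property
    def complete(self) -> bool:
        """True when all 36 vocabulary labels are present."""
        return len(self.points) == len(VOCABULARY) and _VOCAB_SET.issubset(self.points)

    def records(self) -> list[LandmarkRecord]:
        """Rows in canonical vocabulary order (for serialization)."""
        return [
            LandmarkRecord(self.case_id, self.sex, self.age_months, lab, *self.points[lab])
            for lab in VOCABULARY
            if lab in self.points
        ]

    def transformed(self, fn) -> "LandmarkSet":
        """A copy with ``fn((x, y)) -> (x, y)`` applied to every point."""
        return LandmarkSet(
            self.case_id,
            self.sex,
            self.age_months,
            {lab: tuple(fn(p)) for lab, p in self.points.items()},
        )
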