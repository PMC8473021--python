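"""Tabular interchange formats.

Three plain CSV dialects (comma separated, UTF-8, ``.`` decimal point,
mandatory header) cover the whole workflow:

* landmark CSV — ``case_id,sex,age_months,label,x,y``, one row per
  annotated point, the shape of an ImageJ point-measurement export once
  case metadata has been joined in;
* indicator CSV — ``case_id,sex,age_months,X01..X21``, one row per case,
  absent indicators as empty fields;
* quotient CSV — ``variable,quotient``, the two informative columns of a
  sensitivity ranking.
"""

from __future__ import annotations

import csv
import math
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    DuplicateLandmarkError,
    FormatError,
    ParseError,
    VocabularyError,
)
from .landmarks import VOCABULARY, LandmarkSet, is_valid_label, validate_age

LANDMARK_COLUMNS = ("case_id", "sex", "age_months", "label", "x", "y")

INDICATOR_NAMES = tuple(f"X{i:02d}" for i in range(1, 22))
INDICATOR_COLUMNS = ("case_id", "sex", "age_months") + INDICATOR_NAMES


def _check_header(header: Sequence[str], expected: Sequence[str], path) -> None:
    if list(header) != list(expected):
        missing = [c for c in expected if c not in header]
        extra = [c for c in header if c not in expected]
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        if not parts:
            parts.append(f"columns out of order: {list(header)}")
        raise FormatError(f"{path}: bad header: " + "; ".join(parts))


def read_landmarks(
    path, *, strict: bool = True, enforce_age_range: bool = True
) -> list[LandmarkSet]:
    """Read a landmark CSV into one :class:`LandmarkSet` per case.

    Cases appear in file order (first appearance).  In strict mode an
    unknown label raises :class:`VocabularyError` naming the row; in
    lenient mode the row is skipped with a warning.  Duplicate
    ``(case_id, label)`` pairs always raise.
    """
    path = Path(path)
    cases: dict[str, LandmarkSet] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header required") from None
        _check_header(header, LANDMARK_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(LANDMARK_COLUMNS):
                raise FormatError(f"{path}: row {lineno}: expected 6 fields, got {len(row)}")
            case_id, sex, age_s, label, x_s, y_s = (c.strip() for c in row)
            if sex not in ("F", "M"):
                raise FormatError(f"{path}: row {lineno}: sex must be F or M, got {sex!r}")
            if not is_valid_label(label):
                if strict:
                    raise VocabularyError(
                        f"{path}: row {lineno}: unknown landmark label {label!r}"
                    )
                warnings.warn(
                    f"{path}: row {lineno}: skipping unknown label {label!r}",
                    stacklevel=2,
                )
                continue
            age = None
            if age_s:
                try:
                    age = int(age_s)
                except ValueError:
                    raise ParseError(
                        f"{path}: row {lineno}: non-integer age_months {age_s!r}"
                    ) from None
                validate_age(age, enforce_range=enforce_age_range)
            try:
                x, y = float(x_s), float(y_s)
            except ValueError:
                raise ParseError(f"{path}: row {lineno}: non-numeric coordinate") from None
            if not (math.isfinite(x) and math.isfinite(y)):
                raise FormatError(f"{path}: row {lineno}: non-finite coordinate")
            if case_id not in cases:
                cases[case_id] = LandmarkSet(case_id, sex, age)
            else:
                prev = cases[case_id]
                if prev.sex != sex or prev.age_months != age:
                    raise FormatError(
                        f"{path}: row {lineno}: case {case_id!r} has inconsistent "
                        "sex/age across rows"
                    )
            try:
                cases[case_id].add_point(label, x, y)
            except DuplicateLandmarkError as exc:
                raise DuplicateLandmarkError(f"{path}: row {lineno}: {exc}") from None
    return list(cases.values())


def write_landmarks(cases: Iterable[LandmarkSet], path) -> None:
    """Write cases in input order, labels in vocabulary order."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LANDMARK_COLUMNS)
        for case in cases:
            age = "" if case.age_months is None else case.age_months
            for rec in case.records():
                writer.writerow([rec.case_id, rec.sex, age, rec.label, repr(rec.x), repr(rec.y)])


def read_quotient_table(path) -> dict[str, float]:
    """Read a two-column ``variable,quotient`` CSV, preserving file order."""
    path = Path(path)
    out: dict[str, float] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header required") from None
        if len(header) != 2:
            raise FormatError(f"{path}: expected 2 columns, got {len(header)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise FormatError(f"{path}: row {lineno}: expected 2 fields")
            name, q_s = row[0].strip(), row[1].strip()
            try:
                out[name] = float(q_s)
            except ValueError:
                raise ParseError(
                    f"{path}: row {lineno}: non-numeric quotient {q_s!r}"
                ) from None
    return out


def read_indicator_table(path) -> pd.DataFrame:
    """Read an indicator CSV into a DataFrame indexed by ``case_id``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"case_id": str, "sex": str})
    _check_header(df.columns, INDICATOR_COLUMNS, path)
    bad = df.loc[~df["sex"].isin(("F", "M")), "sex"]
    if len(bad):
        raise FormatError(f"{path}: invalid sex value {bad.iloc[0]!r}")
    df["age_months"] = df["age_months"].astype("Int64")
    df = df.set_index("case_id", drop=False)
    df.index.name = None
    return df


def write_indicator_table(df: pd.DataFrame, path) -> None:
    """Write an indicator DataFrame; absent values become empty fields."""
    out = df.loc[:, list(INDICATOR_COLUMNS)]
    out.to_csv(Path(path), index=False, na_rep="")
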