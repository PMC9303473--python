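"""Domain types and tabular I/O for CRVS maternal-mortality misclassification data.

Two kinds of input feed the model:

* **CRVS series** — for each country-year, the number of maternal deaths
  reported by the civil registration system (``y_mat``) and the total
  reported deaths to women aged 15-49 (``y_crvs``, the "envelope").
* **Specialized studies** — country-period records that confirm the true
  maternal status of CRVS-reported deaths.  Studies report with varying
  levels of detail; the level of detail is encoded as a
  :class:`ReportingPattern` and is inferred from which count columns are
  populated.

Counts use the confusion-matrix vocabulary of diagnostic testing: a death
in the CRVS envelope is truly maternal or not (rows) and coded maternal or
not (columns), giving cells T+ (true positive), F+ (false positive),
F- (false negative) and T- (true negative).  Marginals:
``z_mat = T+ + F+`` (CRVS-coded maternal) and ``z_true = T+ + F-``
(study-confirmed maternal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReportingPattern",
    "CRVSSeries",
    "StudyObservation",
    "Dataset",
    "DataValidationError",
    "classify_reporting_pattern",
    "derive_midyear",
    "read_dataset",
    "write_dataset",
]

DEFAULT_YEAR_SPAN = (1985, 2017)

STUDY_COLUMNS = [
    "study_id",
    "country",
    "t1",
    "t2",
    "z_crvs",
    "z_mat",
    "z_true",
    "z_tpos",
    "z_fpos",
    "z_fneg",
    "z_tneg",
]
CRVS_COLUMNS = ["country", "year", "y_mat", "y_crvs"]


class DataValidationError(ValueError):
    """Raised when an input table violates the dataset contract."""


class ReportingPattern(str, Enum):
    """How much detail a specialized study reports.

    FULL_BREAKDOWN
        All four confusion-matrix cells (T+, F+, F-, T-).
    PARTIAL_FNEG
        False negatives, true negatives and the CRVS-coded maternal total
        (the split of ``z_mat`` into T+ and F+ is not observed).
    TRUE_TOTAL_ONLY
        Only the study-confirmed maternal total and the CRVS-coded maternal
        total — two *overlapping* marginals of the latent table.
    """

    FULL_BREAKDOWN = "FULL_BREAKDOWN"
    PARTIAL_FNEG = "PARTIAL_FNEG"
    TRUE_TOTAL_ONLY = "TRUE_TOTAL_ONLY"


def derive_midyear(t1: int, t2: int) -> int:
    """Midyear of an observation period: floor of the arithmetic mean."""
    if t1 > t2:
        raise DataValidationError(f"period start {t1} after end {t2}")
    return (t1 + t2) // 2


def _present(value) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and math.isnan(value):
        return False
    return True


def classify_reporting_pattern(record: Mapping) -> ReportingPattern:
    """Classify a raw study row by which count fields are populated.

    Classification depends only on field *presence*, never on values.
    """
    cells = [record.get(k) for k in ("z_tpos", "z_fpos", "z_fneg", "z_tneg")]
    has = [_present(v) for v in cells]
    has_true = _present(record.get("z_true"))
    has_mat = _present(record.get("z_mat"))
    if all(has):
        return ReportingPattern.FULL_BREAKDOWN
    if has[2] and has[3] and not has[0] and not has[1]:
        if not has_mat:
            raise DataValidationError(
                "partial breakdown (F-, T-) requires z_mat to be present"
            )
        return ReportingPattern.PARTIAL_FNEG
    if not any(has):
        if has_true and has_mat:
            return ReportingPattern.TRUE_TOTAL_ONLY
        raise DataValidationError(
            "study without cell counts must report z_true and z_mat"
        )
    raise DataValidationError(
        f"unsupported combination of populated cell counts: "
        f"tpos={has[0]}, fpos={has[1]}, fneg={has[2]}, tneg={has[3]}"
    )


@dataclass(frozen=True)
class CRVSSeries:
    """One country-year of CRVS-reported counts."""

    country: str
    year: int
    y_mat: int
    y_crvs: int

    def __post_init__(self):
        if not (0 <= self.y_mat <= self.y_crvs):
            raise DataValidationError(
                f"{self.country} {self.year}: need 0 <= y_mat <= y_crvs, "
                f"got y_mat={self.y_mat}, y_crvs={self.y_crvs}"
            )


def _as_count(value, what: str, record: str) -> int:
    if value is None:
        raise DataValidationError(f"{record}: missing required count {what}")
    iv = int(value)
    if iv != value or iv < 0:
        raise DataValidationError(
            f"{record}: {what}={value!r} is not a nonnegative integer"
        )
    return iv


@dataclass(frozen=True)
class StudyObservation:
    """One specialized-study record, validated per its reporting pattern."""

    study_id: str
    country: str
    t1: int
    t2: int
    z_crvs: int
    z_mat: int | None = None
    z_true: int | None = None
    z_tpos: int | None = None
    z_fpos: int | None = None
    z_fneg: int | None = None
    z_tneg: int | None = None
    pattern: ReportingPattern = field(init=False)
    t_mid: int = field(init=False)

    def __post_init__(self):
        rid = f"study {self.study_id}"
        object.__setattr__(self, "t_mid", derive_midyear(self.t1, self.t2))
        pattern = classify_reporting_pattern(self.__dict__)
        object.__setattr__(self, "pattern", pattern)
        object.__setattr__(self, "z_crvs", _as_count(self.z_crvs, "z_crvs", rid))

        if pattern is ReportingPattern.FULL_BREAKDOWN:
            cells = {
                k: _as_count(getattr(self, k), k, rid)
                for k in ("z_tpos", "z_fpos", "z_fneg", "z_tneg")
            }
            for k, v in cells.items():
                object.__setattr__(self, k, v)
            total = sum(cells.values())
            if total != self.z_crvs:
                raise DataValidationError(
                    f"{rid}: four cells sum to {total} != z_crvs={self.z_crvs}"
                )
            mat = cells["z_tpos"] + cells["z_fpos"]
            true = cells["z_tpos"] + cells["z_fneg"]
            if _present(self.z_mat) and int(self.z_mat) != mat:
                raise DataValidationError(
                    f"{rid}: z_mat={self.z_mat} inconsistent with cells ({mat})"
                )
            if _present(self.z_true) and int(self.z_true) != true:
                raise DataValidationError(
                    f"{rid}: z_true={self.z_true} inconsistent with cells ({true})"
                )
            object.__setattr__(self, "z_mat", mat)
            object.__setattr__(self, "z_true", true)
        elif pattern is ReportingPattern.PARTIAL_FNEG:
            for k in ("z_fneg", "z_tneg", "z_mat"):
                object.__setattr__(self, k, _as_count(getattr(self, k), k, rid))
            if _present(self.z_true):
                raise DataValidationError(
                    f"{rid}: z_true cannot be reported without the T+/F+ split"
                )
            total = self.z_fneg + self.z_tneg + self.z_mat
            if total != self.z_crvs:
                raise DataValidationError(
                    f"{rid}: z_fneg+z_tneg+z_mat={total} != z_crvs={self.z_crvs}"
                )
        else:  # TRUE_TOTAL_ONLY
            object.__setattr__(self, "z_mat", _as_count(self.z_mat, "z_mat", rid))
            object.__setattr__(self, "z_true", _as_count(self.z_true, "z_true", rid))
            if self.z_mat > self.z_crvs or self.z_true > self.z_crvs:
                raise DataValidationError(
                    f"{rid}: marginal exceeds envelope z_crvs={self.z_crvs} "
                    f"(z_mat={self.z_mat}, z_true={self.z_true})"
                )
            lo = max(0, self.z_mat + self.z_true - self.z_crvs)
            hi = min(self.z_mat, self.z_true)
            if lo > hi:
                raise DataValidationError(
                    f"{rid}: no latent table satisfies the marginals "
                    f"(z_crvs={self.z_crvs}, z_mat={self.z_mat}, z_true={self.z_true})"
                )

    def to_row(self) -> dict:
        row = {k: getattr(self, k) for k in STUDY_COLUMNS}
        if self.pattern is ReportingPattern.PARTIAL_FNEG:
            row["z_true"] = None
        return row


@dataclass(frozen=True)
class Dataset:
    """A validated collection of CRVS series and specialized studies."""

    crvs: tuple[CRVSSeries, ...]
    studies: tuple[StudyObservation, ...]
    year_span: tuple[int, int] = DEFAULT_YEAR_SPAN

    def __post_init__(self):
        object.__setattr__(self, "crvs", tuple(self.crvs))
        object.__setattr__(self, "studies", tuple(self.studies))
        first, last = self.year_span
        if first > last:
            raise DataValidationError(f"invalid year_span {self.year_span}")
        seen = set()
        for rec in self.crvs:
            key = (rec.country, rec.year)
            if key in seen:
                raise DataValidationError(f"duplicate CRVS record for {key}")
            seen.add(key)
        crvs_countries = {rec.country for rec in self.crvs}
        for s in self.studies:
            if s.country not in crvs_countries:
                raise DataValidationError(
                    f"study {s.study_id}: country {s.country!r} has no CRVS series"
                )
            if s.t1 < first or s.t2 > last:
                raise DataValidationError(
                    f"study {s.study_id}: period {s.t1}-{s.t2} outside "
                    f"year span {first}-{last}"
                )

    @property
    def countries(self) -> list[str]:
        """Countries in stable (first-appearance) order."""
        out: list[str] = []
        for rec in self.crvs:
            if rec.country not in out:
                out.append(rec.country)
        return out

    @property
    def years(self) -> np.ndarray:
        first, last = self.year_span
        return np.arange(first, last + 1)

    @property
    def n_years(self) -> int:
        return self.year_span[1] - self.year_span[0] + 1

    def time_index(self, year: int) -> int:
        """0-based position of a calendar year on the estimation grid."""
        first, last = self.year_span
        if not (first <= year <= last):
            raise KeyError(f"year {year} outside span {self.year_span}")
        return year - first

    def with_studies(self, studies: Iterable[StudyObservation]) -> "Dataset":
        return replace(self, studies=tuple(studies))

    def crvs_frame(self) -> pd.DataFrame:
        return pd.DataFrame([rec.__dict__ for rec in self.crvs], columns=CRVS_COLUMNS)

    def studies_frame(self) -> pd.DataFrame:
        rows = [s.to_row() for s in self.studies]
        return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def _studies_from_frame(df: pd.DataFrame) -> list[StudyObservation]:
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"studies table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for k in STUDY_COLUMNS:
            v = row[k]
            if k in ("study_id", "country"):
                kwargs[k] = str(v)
            elif _present(v):
                kwargs[k] = int(v)
            elif k in ("t1", "t2", "z_crvs"):
                raise DataValidationError(
                    f"study {row['study_id']}: missing required column {k}"
                )
        out.append(StudyObservation(**kwargs))
    return out


def read_dataset(
    crvs_path: str | Path,
    studies_path: str | Path,
    year_span: tuple[int, int] = DEFAULT_YEAR_SPAN,
) -> Dataset:
    """Read and validate the two CSV inputs.

    ``crvs.csv`` columns: country, year, y_mat, y_crvs.
    ``studies.csv`` columns: study_id, country, t1, t2, z_crvs, z_mat,
    z_true, z_tpos, z_fpos, z_fneg, z_tneg — empty cells encode the
    reporting pattern.
    """
    crvs_df = pd.read_csv(crvs_path)
    missing = set(CRVS_COLUMNS) - set(crvs_df.columns)
    if missing:
        raise DataValidationError(f"CRVS table missing columns: {sorted(missing)}")
    crvs = [
        CRVSSeries(str(r.country), int(r.year), int(r.y_mat), int(r.y_crvs))
        for r in crvs_df.itertuples()
    ]
    studies_df = pd.read_csv(studies_path)
    studies = _studies_from_frame(studies_df)
    return Dataset(crvs=tuple(crvs), studies=tuple(studies), year_span=year_span)


def write_dataset(
    dataset: Dataset, crvs_path: str | Path, studies_path: str | Path
) -> None:
    """Write a dataset back to the two-file CSV layout (round-trip safe)."""
    dataset.crvs_frame().to_csv(crvs_path, index=False)
    df = dataset.studies_frame()
    int_cols = [c for c in STUDY_COLUMNS if c not in ("study_id", "country")]
    df[int_cols] = df[int_cols].astype("Int64")
    df.to_csv(studies_path, index=False)
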