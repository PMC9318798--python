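"""Cohort data model for LOD-censored serum biomonitoring panels.

A cohort is a tidy set of one-infant-one-analyte serum concentration
measurements (ng/mL), each carrying the infant's age in completed months
(0-11), together with the analyte panel that defines each assay's limit of
detection (LOD).  Concentrations reported below the LOD are *censored*: the
laboratory knows only that the true value lies under the LOD, and summary
statistics conventionally replace them with a fixed fraction of the LOD
(LOD/sqrt(2) in NHANES practice).
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AnalyteDef",
    "SerumMeasurement",
    "DetectionCount",
    "CohortTable",
    "CohortValidationError",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_panel_csv",
    "substitute_nondetects",
    "detection_counts",
    "SUBSTITUTION_POLICIES",
]

SEXES = ("male", "female", "unknown")

#: Supported below-LOD substitution policies.
SUBSTITUTION_POLICIES = ("lod_over_sqrt2", "lod_over_2", "zero", "as_is")


class CohortValidationError(ValueError):
    """Raised when cohort input fails validation.

    ``errors`` holds ``(row_number, message)`` pairs for file-level problems
    (row numbers are 1-based data rows, excluding the header).
    """

    def __init__(self, message: str, errors: Sequence[tuple[int, str]] = ()):
        super().__init__(message)
        self.errors = list(errors)


@dataclass(frozen=True)
class AnalyteDef:
    """One analyte panel entry: assay code, chemical name and LOD (ng/mL)."""

    abbreviation: str
    full_name: str = ""
    lod: float | None = None

    def __post_init__(self) -> None:
        if not self.abbreviation:
            raise ValueError("analyte abbreviation must be non-empty")
        if self.lod is not None and not self.lod > 0:
            raise ValueError(f"{self.abbreviation}: LOD must be > 0, got {self.lod}")


@dataclass(frozen=True)
class SerumMeasurement:
    """One infant x analyte serum observation.

    ``below_lod`` marks a censored (non-detect) observation; ``value`` then
    holds whatever placeholder the active substitution policy assigned.
    """

    subject_id: str
    age_months: int
    sex: str
    analyte: str
    value: float
    below_lod: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.age_months, int) and 0 <= self.age_months <= 11):
            raise ValueError(f"age_months must be an integer in [0, 11], got {self.age_months}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.value >= 0:
            raise ValueError(f"concentration must be >= 0 ng/mL, got {self.value}")


@dataclass(frozen=True)
class DetectionCount:
    """Detects ``k`` out of ``n`` tested for one analyte."""

    analyte: str
    k: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"{self.analyte}: need 0 <= k <= n, got k={self.k}, n={self.n}")


@dataclass
class CohortTable:
    """An analyte panel plus the measurement records that reference it."""

    panel: list[AnalyteDef]
    records: list[SerumMeasurement]
    provenance: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a in self.panel:
            if a.abbreviation in seen:
                raise ValueError(f"duplicate analyte in panel: {a.abbreviation}")
            seen.add(a.abbreviation)
        for r in self.records:
            if r.analyte not in seen:
                raise ValueError(f"record references unknown analyte {r.analyte!r}")

    def __len__(self) -> int:
        return len(self.records)

    def analyte(self, abbreviation: str) -> AnalyteDef:
        for a in self.panel:
            if a.abbreviation == abbreviation:
                return a
        raise KeyError(f"analyte {abbreviation!r} not in panel")

    def subset(self, analyte: str) -> list[SerumMeasurement]:
        self.analyte(analyte)  # raises KeyError when absent
        return [r for r in self.records if r.analyte == analyte]

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame view (one row per record)."""
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "age_months": [r.age_months for r in self.records],
                "sex": [r.sex for r in self.records],
                "analyte": [r.analyte for r in self.records],
                "value_ng_ml": [r.value for r in self.records],
                "below_lod": [int(r.below_lod) for r in self.records],
            }
        )


_CSV_COLUMNS = ["subject_id", "age_months", "sex", "analyte", "value_ng_ml", "below_lod"]


def read_panel_csv(path: str | Path) -> list[AnalyteDef]:
    """Read an analyte panel (abbreviation, full_name, lod_ng_ml) from CSV."""
    path = Path(path)
    if not path.exists():
        raise CohortValidationError(f"panel file not found: {path}")
    panel = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            lod = row.get("lod_ng_ml", "").strip()
            panel.append(
                AnalyteDef(
                    abbreviation=row["abbreviation"].strip(),
                    full_name=row.get("full_name", "").strip(),
                    lod=float(lod) if lod else None,
                )
            )
    return panel


def read_cohort_csv(path: str | Path, panel: Sequence[AnalyteDef]) -> CohortTable:
    """Read tidy measurement records, validating every row.

    All malformed rows are collected and reported together in a
    :class:`CohortValidationError` whose ``errors`` list gives the 1-based
    data-row number and reason for each rejection.
    """
    path = Path(path)
    if not path.exists():
        raise CohortValidationError(f"cohort file not found: {path}")
    known = {a.abbreviation for a in panel}
    records: list[SerumMeasurement] = []
    errors: list[tuple[int, str]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_CSV_COLUMNS) <= set(reader.fieldnames):
            missing = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
            raise CohortValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=1):
            try:
                analyte = row["analyte"].strip()
                if analyte not in known:
                    raise ValueError(f"unknown analyte {analyte!r}")
                records.append(
                    SerumMeasurement(
                        subject_id=row["subject_id"].strip(),
                        age_months=int(row["age_months"]),
                        sex=row["sex"].strip() or "unknown",
                        analyte=analyte,
                        value=float(row["value_ng_ml"]),
                        below_lod=bool(int(row["below_lod"])),
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append((i, str(exc)))
    if errors:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in errors[:10])
        raise CohortValidationError(f"{path}: {len(errors)} invalid rows ({detail})", errors)
    return CohortTable(panel=list(panel), records=records, provenance=str(path))


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write records in the tidy CSV dialect read by :func:`read_cohort_csv`."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in table.records:
            writer.writerow(
                [r.subject_id, r.age_months, r.sex, r.analyte,
                 repr(r.value), int(r.below_lod)]
            )


def _substituted_value(lod: float, policy: str) -> float:
    if policy == "lod_over_sqrt2":
        return lod / math.sqrt(2)
    if policy == "lod_over_2":
        return lod / 2
    if policy == "zero":
        return 0.0
    raise ValueError(f"unknown substitution policy {policy!r}")


def substitute_nondetects(
    records: Iterable[SerumMeasurement],
    panel: Sequence[AnalyteDef],
    policy: str = "lod_over_sqrt2",
) -> list[SerumMeasurement]:
    """Replace censored values by the policy's fraction of the analyte LOD.

    Detected values and record order are untouched; censoring flags are never
    altered (substitution changes the placeholder value, not the status).
    ``as_is`` returns copies with values unchanged.
    """
    if policy not in SUBSTITUTION_POLICIES:
        raise ValueError(f"policy must be one of {SUBSTITUTION_POLICIES}, got {policy!r}")
    lods = {a.abbreviation: a.lod for a in panel}
    out = []
    for r in records:
        if r.below_lod and policy != "as_is":
            lod = lods.get(r.analyte)
            if policy != "zero" and lod is None:
                raise CohortValidationError(
                    f"policy {policy!r} requires a known LOD for {r.analyte}"
                )
            out.append(replace(r, value=_substituted_value(lod if lod else 0.0, policy)))
        else:
            out.append(r)
    return out


def detection_counts(table: CohortTable, analyte: str) -> DetectionCount:
    """Count detects (k) out of all tested records (n) for one analyte."""
    recs = table.subset(analyte)  # KeyError if absent from panel
    k = sum(1 for r in recs if not r.below_lod)
    return DetectionCount(analyte=analyte, k=k, n=len(recs))
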