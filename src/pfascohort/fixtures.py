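"""Packaged NHANES 2007-2008 infant serum PFAS data.

The 2007-2008 NHANES cycle is the only cycle with serum PFAS measurements
for infants under one year of age: 101 infants across twelve monthly age
bins, assayed for a 12-analyte panel.  This module ships the published
individual concentrations for the six analytes whose per-infant values are
available (PFOA, PFNA, PFHxS, PFDA, N-MeFOSAA, PFOS), the full analyte
panel with LODs, and the panel-wide detect/tested counts for all twelve
analytes, as frozen package data with a provenance sidecar.

Two published columns could not be reconciled with their own individual
values (see the provenance ``notes``); for those the published per-month
medians are recorded as *overrides* and applied by
:func:`nhanes_median_overrides` consumers when summarising trends.
"""
from __future__ import annotations

import csv
import json
from importlib import resources

from .cohort import AnalyteDef, CohortTable, DetectionCount, SerumMeasurement

__all__ = [
    "load_nhanes_infants",
    "nhanes_panel",
    "nhanes_detection_counts",
    "nhanes_provenance",
    "nhanes_median_overrides",
    "NHANES_N_PER_MONTH",
]

#: Published per-month infant counts (ages 0..11 completed months).
NHANES_N_PER_MONTH = (8, 9, 7, 13, 8, 6, 10, 5, 7, 12, 9, 7)

_DATA = resources.files("pfascohort") / "data"


def _read_text(name: str) -> str:
    return (_DATA / name).read_text()


def nhanes_panel() -> list[AnalyteDef]:
    """The 12-analyte 2007-2008 serum PFAS panel with LODs (ng/mL)."""
    panel = []
    for row in csv.DictReader(_read_text("nhanes_panel.csv").splitlines()):
        lod = row["lod_ng_ml"].strip()
        panel.append(
            AnalyteDef(
                abbreviation=row["abbreviation"],
                full_name=row["full_name"],
                lod=float(lod) if lod else None,
            )
        )
    return panel


def nhanes_provenance() -> dict:
    """Provenance sidecar: source description, audit notes, median overrides."""
    return json.loads(_read_text("nhanes_provenance.json"))


def load_nhanes_infants() -> CohortTable:
    """The packaged infant cohort: 6 analytes x 101 infants, as published.

    Values are exactly the published 2-decimal concentrations; below-LOD
    flags mark the repeated substitution placeholders (e.g. 0.14 ng/mL =
    LOD 0.2 / sqrt(2) for PFDA).
    """
    prov = nhanes_provenance()
    records = []
    for row in csv.DictReader(_read_text("nhanes_2007_2008_infants.csv").splitlines()):
        records.append(
            SerumMeasurement(
                subject_id=row["subject_id"],
                age_months=int(row["age_months"]),
                sex=row["sex"],
                analyte=row["analyte"],
                value=float(row["value_ng_ml"]),
                below_lod=bool(int(row["below_lod"])),
            )
        )
    return CohortTable(
        panel=nhanes_panel(),
        records=records,
        provenance=prov["label"],
        metadata=prov,
    )


def nhanes_detection_counts() -> list[DetectionCount]:
    """Published detects-out-of-101 counts for all twelve panel analytes."""
    return [
        DetectionCount(analyte=row["analyte"], k=int(row["k"]), n=int(row["n"]))
        for row in csv.DictReader(_read_text("nhanes_detection_counts.csv").splitlines())
    ]


def nhanes_median_overrides() -> dict[str, dict[int, float]]:
    """Published per-month medians for columns whose individual values are
    unrecoverable or inconsistent in the source tables.

    Returns ``{analyte: {month: median_ng_ml}}``.  Currently: PFOA month 3
    (column lost in transcription) and all PFDA months (individual-value
    table irreconcilable with the authoritative summary medians).
    """
    raw = nhanes_provenance()["median_overrides"]
    return {a: {int(m): v for m, v in d.items()} for a, d in raw.items()}
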