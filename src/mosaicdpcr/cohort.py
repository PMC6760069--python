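"""Cohort sheet loading and detection-rate tabulation across methods.

A cohort sheet holds one row per tissue sample with the per-variant calls of
four detection methods — Sanger sequencing, allele-specific PCR, COLD-MAMA
PCR and digital PCR — plus the dPCR quantities.  This module tabulates
sample-level detection rates by tissue class (bone; cutis/fibroblasts;
ovarian cyst/cyst liquid/tissue; blood), patient-level detection rates, the
method comparison restricted to the subcohort tested by all four methods,
and false-negative counts of each method against digital PCR.

A sample counts as positive for a method when either variant is called MUT,
and as tested when at least one variant has a non-ND call; a patient is
positive when any of their samples is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from ._rounding import round_half_up

__all__ = [
    "METHODS",
    "VARIANTS",
    "TISSUE_CLASSES",
    "SampleRecord",
    "DetectionCell",
    "DetectionTable",
    "PatientRate",
    "load_cohort",
    "packaged_cohort",
    "packaged_cohort_path",
    "tissue_class",
    "sample_tested",
    "sample_positive",
    "detection_table",
    "patient_rate",
    "subcohort_comparison",
    "false_negative_count",
    "rate_percent",
    "render_table",
]

METHODS = ("SANGER", "ASPCR", "COLD", "DPCR")
VARIANTS = ("c.604C>T", "c.605G>A")

#: tissue classes partitioning all tissue codes
TISSUE_CLASSES: dict[str, frozenset[str]] = {
    "BO": frozenset({"BO"}),
    "CB/FB": frozenset({"CB", "FB"}),
    "OC/OCL/OT": frozenset({"OC", "OCL", "OT"}),
    "BL": frozenset({"BL"}),
}
_ALL_CODES = frozenset().union(*TISSUE_CLASSES.values())

_CALLS = ("MUT", "WT", "ND")

# TSV column stems per method, suffixed _604 / _605
_METHOD_COLUMNS = {
    "SANGER": "sanger",
    "ASPCR": "aspcr",
    "DPCR": "dpcr_call",
    "COLD": "cold_call",
}
_VARIANT_SUFFIX = {"c.604C>T": "604", "c.605G>A": "605"}


def tissue_class(code: str) -> str:
    for label, members in TISSUE_CLASSES.items():
        if code in members:
            return label
    raise ValueError(f"unknown tissue code: {code!r}")


@dataclass(frozen=True)
class SampleRecord:
    """One tissue sample: per-method, per-variant calls and dPCR quantities."""

    patient_id: str
    tissue_label: str  # raw label, e.g. "BO-LJ"
    tissue: str  # normalized code, e.g. "BO"
    calls: dict[tuple[str, str], str]  # (method, variant) -> MUT/WT/ND
    dpcr_cpm: dict[str, float | None] = field(default_factory=dict)
    dpcr_rma: dict[str, str | None] = field(default_factory=dict)
    cold_rma: dict[str, str | None] = field(default_factory=dict)

    @property
    def tissue_class(self) -> str:
        return tissue_class(self.tissue)


def _norm_call(raw: str) -> str:
    value = raw.strip().upper()
    if value in ("", "ND"):
        return "ND"
    if value in ("MUT", "WT"):
        return value
    raise ValueError(f"unrecognized call: {raw!r}")


def load_cohort(path: str | Path) -> list[SampleRecord]:
    """Load a cohort TSV into sample records.

    Blank and ``nd`` cells become ND (not tested); tissue suffixes such as
    ``BO-LJ`` normalize to the base code.  Unknown tissue codes and
    duplicate (patient, tissue-label) rows are parse errors naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"patient_id", "tissue"} | {
        f"{stem}_{sfx}" for stem in _METHOD_COLUMNS.values() for sfx in ("604", "605")
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort sheet missing columns: {sorted(missing)}")

    records: list[SampleRecord] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        label = row["tissue"].strip()
        code = label.split("-")[0].upper()
        if code not in _ALL_CODES:
            raise ValueError(f"row {idx + 2}: unknown tissue code {label!r}")
        key = (row["patient_id"].strip(), label)
        if key in seen:
            raise ValueError(f"row {idx + 2}: duplicate sample {key}")
        seen.add(key)

        calls: dict[tuple[str, str], str] = {}
        cpm: dict[str, float | None] = {}
        rma: dict[str, str | None] = {}
        cold_rma: dict[str, str | None] = {}
        for variant, sfx in _VARIANT_SUFFIX.items():
            for method, stem in _METHOD_COLUMNS.items():
                calls[(method, variant)] = _norm_call(row[f"{stem}_{sfx}"])
            raw_cpm = row.get(f"dpcr_cpm_{sfx}", "").strip()
            cpm[variant] = float(raw_cpm) if raw_cpm else None
            rma[variant] = row.get(f"dpcr_rma_{sfx}", "").strip() or None
            cold_rma[variant] = row.get(f"cold_rma_{sfx}", "").strip() or None

        records.append(
            SampleRecord(
                patient_id=key[0],
                tissue_label=label,
                tissue=code,
                calls=calls,
                dpcr_cpm=cpm,
                dpcr_rma=rma,
                cold_rma=cold_rma,
            )
        )
    return records


def packaged_cohort_path() -> Path:
    return Path(str(resources.files("mosaicdpcr.data").joinpath("cohort_table1.tsv")))


def packaged_cohort() -> list[SampleRecord]:
    """The packaged 79-sample, 54-patient cohort transcription."""
    return load_cohort(packaged_cohort_path())


def sample_tested(rec: SampleRecord, method: str) -> bool:
    return any(rec.calls[(method, v)] != "ND" for v in VARIANTS)


def sample_positive(rec: SampleRecord, method: str) -> bool:
    return any(rec.calls[(method, v)] == "MUT" for v in VARIANTS)


class DetectionCell(NamedTuple):
    positive: int
    tested: int


class PatientRate(NamedTuple):
    positives: int
    tested: int
    rate: float  # percent, 1 decimal (half-up)


def rate_percent(positive: int, tested: int, style: str = "half_up") -> float:
    """Detection rate in percent to 1 decimal; 0 when nothing was tested.

    ``style='truncate'`` cuts toward zero instead of rounding, the variant
    needed to render repeating decimals like 10/15 as 66.6.
    """
    if tested == 0:
        return 0.0
    raw = 100.0 * positive / tested
    if style == "truncate":
        return math.floor(raw * 10) / 10
    if style == "half_up":
        return round_half_up(raw, 1)
    raise ValueError(f"unknown rate style: {style!r}")


@dataclass(frozen=True)
class DetectionTable:
    """Per-tissue-class and patient-level detection counts for one method."""

    method: str
    by_class: dict[str, DetectionCell]
    samples: DetectionCell  # all samples pooled
    patients: DetectionCell

    def rate(self, label: str, style: str = "half_up") -> float:
        cell = self.by_class[label]
        return rate_percent(cell.positive, cell.tested, style)

    @property
    def patient_rate(self) -> float:
        return rate_percent(self.patients.positive, self.patients.tested)


def _patient_cell(records: Sequence[SampleRecord], method: str) -> DetectionCell:
    by_patient: dict[str, list[SampleRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    tested = sum(
        1 for recs in by_patient.values() if any(sample_tested(r, method) for r in recs)
    )
    positive = sum(
        1 for recs in by_patient.values() if any(sample_positive(r, method) for r in recs)
    )
    return DetectionCell(positive, tested)


def detection_table(records: Sequence[SampleRecord], method: str) -> DetectionTable:
    """Tissue-class x method detection table plus the patient-level row.

    Denominators count samples (or patients) with at least one non-ND call
    for the method; an untested method yields explicit zero denominators.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method: {method!r}")
    by_class = {}
    for label in TISSUE_CLASSES:
        class_recs = [r for r in records if r.tissue_class == label]
        tested = sum(sample_tested(r, method) for r in class_recs)
        positive = sum(
            sample_positive(r, method) for r in class_recs if sample_tested(r, method)
        )
        by_class[label] = DetectionCell(positive, tested)
    samples = DetectionCell(
        sum(c.positive for c in by_class.values()),
        sum(c.tested for c in by_class.values()),
    )
    return DetectionTable(
        method=method,
        by_class=by_class,
        samples=samples,
        patients=_patient_cell(records, method),
    )


def patient_rate(records: Sequence[SampleRecord], method: str) -> PatientRate:
    """Patient-level detection: positives, tested, percent."""
    cell = _patient_cell(records, method)
    return PatientRate(cell.positive, cell.tested, rate_percent(*cell))


def all_methods_tested_samples(records: Sequence[SampleRecord]) -> list[SampleRecord]:
    return [r for r in records if all(sample_tested(r, m) for m in METHODS)]


def subcohort_comparison(records: Sequence[SampleRecord]) -> dict[str, DetectionTable]:
    """Method comparison over the subcohort tested by every method.

    Restricts to samples with a non-ND result for all four methods; the
    patient rows then cover exactly the patients comparable across methods.
    Returns one table per method (empty cells when the subcohort is empty).
    """
    sub = all_methods_tested_samples(records)
    return {method: detection_table(sub, method) for method in METHODS}


def false_negative_count(
    records: Sequence[SampleRecord], other: str, reference: str = "DPCR"
) -> int:
    """Patients positive by the reference method but negative by `other`.

    Only patients actually tested (non-ND) by the other method are counted,
    so untested patients are not charged as false negatives.
    """
    by_patient: dict[str, list[SampleRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    count = 0
    for recs in by_patient.values():
        if not any(sample_positive(r, reference) for r in recs):
            continue
        if not any(sample_tested(r, other) for r in recs):
            continue
        if not any(sample_positive(r, other) for r in recs):
            count += 1
    return count


def render_table(tables: dict[str, DetectionTable], style: str = "half_up") -> str:
    """Text rendering of detection tables, one column per method."""
    rows = {}
    for label in TISSUE_CLASSES:
        rows[label] = {
            m: f"{t.by_class[label].positive}/{t.by_class[label].tested}; "
            f"{t.rate(label, style):g}%"
            for m, t in tables.items()
        }
    rows["Patients (overall DR)"] = {
        m: f"{t.patients.positive}/{t.patients.tested}; {t.patient_rate:g}%"
        for m, t in tables.items()
    }
    return pd.DataFrame(rows).T.to_string()
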