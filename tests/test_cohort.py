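"""Cohort loading and detection-rate tabulation on the packaged sheet."""

import pytest

from mosaicdpcr import (
    METHODS,
    detection_table,
    false_negative_count,
    load_cohort,
    patient_rate,
    subcohort_comparison,
)
from mosaicdpcr.cohort import (
    all_methods_tested_samples,
    rate_percent,
    render_table,
    sample_tested,
)


def test_packaged_sheet_loads_79_samples_54_patients(cohort_records):
    assert len(cohort_records) == 79
    assert len({r.patient_id for r in cohort_records}) == 54
    by_class = {}
    for rec in cohort_records:
        by_class[rec.tissue_class] = by_class.get(rec.tissue_class, 0) + 1
    assert by_class == {"BO": 15, "CB/FB": 16, "OC/OCL/OT": 11, "BL": 37}


def test_blank_and_nd_cells_mean_not_tested(cohort_records):
    pt5_bo = next(r for r in cohort_records if r.patient_id == "5")
    assert pt5_bo.calls[("ASPCR", "c.604C>T")] == "ND"
    assert pt5_bo.calls[("COLD", "c.605G>A")] == "ND"
    pt1_bo = next(r for r in cohort_records if r.patient_id == "1")
    assert pt1_bo.calls[("COLD", "c.604C>T")] == "ND"  # blank cell


def test_unknown_tissue_and_duplicate_rows_rejected(tmp_path, cohort_records):
    header = (
        "patient_id\ttissue\tsanger_604\taspcr_604\tdpcr_call_604\tdpcr_cpm_604"
        "\tdpcr_rma_604\tcold_call_604\tcold_rma_604\tsanger_605\taspcr_605"
        "\tdpcr_call_605\tdpcr_cpm_605\tdpcr_rma_605\tcold_call_605\tcold_rma_605\n"
    )
    row = "1\t{}\tWT\tWT\tWT\t0.1\t\t\t\tWT\tWT\tWT\t0.1\t\t\t\n"
    bad = tmp_path / "bad.tsv"
    bad.write_text(header + row.format("XX"))
    with pytest.raises(ValueError, match="tissue"):
        load_cohort(bad)
    dup = tmp_path / "dup.tsv"
    dup.write_text(header + row.format("BL") + row.format("BL"))
    with pytest.raises(ValueError, match="duplicate"):
        load_cohort(dup)


def test_dpcr_detection_table_matches_published_cells(cohort_records):
    t = detection_table(cohort_records, "DPCR")
    assert tuple(t.by_class["BO"]) == (10, 15)
    assert tuple(t.by_class["CB/FB"]) == (3, 16)
    assert tuple(t.by_class["OC/OCL/OT"]) == (10, 11)
    assert tuple(t.by_class["BL"]) == (14, 37)
    assert t.rate("BL") == 37.8
    assert t.rate("OC/OCL/OT") == 90.9
    assert t.rate("BO", style="truncate") == 66.6
    assert t.rate("BO") == 66.7  # half-up variant of the repeating decimal


def test_other_methods_detection_tables(cohort_records):
    sanger = detection_table(cohort_records, "SANGER")
    assert tuple(sanger.by_class["BL"]) == (0, 37)
    assert tuple(sanger.by_class["BO"]) == (5, 15)
    aspcr = detection_table(cohort_records, "ASPCR")
    assert tuple(aspcr.by_class["BL"]) == (3, 33)
    assert aspcr.rate("BL") == 9.1


def test_patient_level_rates(cohort_records):
    assert patient_rate(cohort_records, "DPCR") == (23, 54, 42.6)
    assert patient_rate(cohort_records, "SANGER") == (4, 54, 7.4)
    assert patient_rate(cohort_records, "ASPCR") == (9, 46, 19.6)
    assert patient_rate(cohort_records, "COLD") == (9, 14, 64.3)


def test_subcohort_restricted_comparison(cohort_records):
    sub = subcohort_comparison(cohort_records)
    assert tuple(sub["DPCR"].patients) == (10, 14)
    assert sub["DPCR"].patient_rate == 71.4
    assert tuple(sub["SANGER"].patients) == (2, 14)
    assert tuple(sub["ASPCR"].patients) == (5, 14)
    assert tuple(sub["COLD"].patients) == (9, 14)
    # sample-level rows over the all-methods-tested samples
    assert tuple(sub["DPCR"].by_class["BO"]) == (3, 3)
    assert tuple(sub["DPCR"].by_class["BL"]) == (6, 11)
    assert sub["DPCR"].rate("BL") == 54.5


def test_all_methods_tested_sample_count(cohort_records):
    assert len(all_methods_tested_samples(cohort_records)) == 26


def test_false_negative_counts_against_dpcr(cohort_records):
    assert false_negative_count(cohort_records, "SANGER") == 19
    assert false_negative_count(cohort_records, "ASPCR") == 10
    assert false_negative_count(cohort_records, "COLD") == 1
    assert false_negative_count(cohort_records, "DPCR") == 0  # self-comparison


def test_class_numerators_partition_the_total(cohort_records):
    for method in METHODS:
        t = detection_table(cohort_records, method)
        assert sum(c.positive for c in t.by_class.values()) == t.samples.positive
        assert sum(c.tested for c in t.by_class.values()) == t.samples.tested


def test_patient_detection_dominance_on_fixture(cohort_records):
    # rates are comparable only on the common (all-methods-tested) subcohort;
    # whole-cohort rates have method-specific denominators
    sub = subcohort_comparison(cohort_records)
    rates = {m: sub[m].patient_rate for m in METHODS}
    assert rates["DPCR"] >= rates["COLD"] >= rates["ASPCR"] >= rates["SANGER"]


def test_empty_cohort_gives_zero_denominators():
    t = detection_table([], "DPCR")
    assert all(tuple(c) == (0, 0) for c in t.by_class.values())
    assert tuple(t.patients) == (0, 0)
    assert t.patient_rate == 0.0
    assert subcohort_comparison([])["DPCR"].samples.tested == 0


def test_rate_formatting_styles():
    assert rate_percent(10, 15, "truncate") == 66.6
    assert rate_percent(10, 15, "half_up") == 66.7
    assert rate_percent(2, 11, "truncate") == 18.1
    assert rate_percent(0, 0) == 0.0


def test_text_rendering_contains_published_cells(cohort_records):
    tables = {m: detection_table(cohort_records, m) for m in METHODS}
    text = render_table(tables)
    assert "14/37; 37.8%" in text
    assert "23/54; 42.6%" in text


def test_partially_tested_samples_still_count_as_tested(cohort_records):
    # pt38's cutaneous samples have AS-PCR results only in the c.604 column;
    # they must still enter the AS-PCR denominator
    rec = next(
        r for r in cohort_records if r.patient_id == "38" and r.tissue_label == "CB-WT"
    )
    assert rec.calls[("ASPCR", "c.605G>A")] == "ND"
    assert sample_tested(rec, "ASPCR")
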