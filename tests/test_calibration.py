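"""Calibrator curves, cutoff selection, sample calling and LOD."""

import numpy as np
import pytest

from mosaicdpcr import (
    CalibratorCurve,
    CalibratorPoint,
    Cutoff,
    NoCutoffError,
    assign_rma,
    build_calibrator,
    call_sample,
    compute_lod,
    determine_cutoff,
)
from mosaicdpcr.calibration import summary_ttest_pvalue
from mosaicdpcr.chips import ASSAYS

A604 = ASSAYS["c.604C>T"]
A605 = ASSAYS["c.605G>A"]


def test_build_calibrator_summarizes_replicates():
    curve = build_calibrator({0.0: [0.09, 0.10, 0.11], 3.0: [0.38, 0.39, 0.40]}, A604)
    point = curve.nonzero_points[0]
    assert point.mean_cpm == pytest.approx(0.39)
    assert point.sd_cpm == pytest.approx(0.01)
    assert curve.points[0].rma_percent == 0.0


def test_identical_replicates_have_zero_sd():
    curve = build_calibrator({0.0: [0.1, 0.1], 6.0: [0.5, 0.5, 0.5]}, A604)
    assert curve.nonzero_points[0].sd_cpm == 0.0


def test_missing_zero_dilution_is_a_configuration_error():
    with pytest.raises(ValueError):
        build_calibrator({3.0: [0.38, 0.39, 0.40]}, A604)


def test_cutoffs_from_reference_summaries(curves):
    """The lowest significant dilution is 3% (c.604T) and 1.5% (c.605A)."""
    cut604 = determine_cutoff(curves["c.604C>T"])
    assert cut604.cpm_mean == pytest.approx(0.391)
    assert cut604.rma_percent == 3.0
    assert cut604.p_value == pytest.approx(0.0028, abs=2e-4)

    cut605 = determine_cutoff(curves["c.605G>A"])
    assert cut605.cpm_mean == pytest.approx(0.464)
    assert cut605.rma_percent == 1.5
    assert cut605.p_value == pytest.approx(0.0004, abs=1e-4)


def test_welch_variant_also_separates_both_cutoff_points(curves):
    for variant in ("c.604C>T", "c.605G>A"):
        cut = determine_cutoff(curves[variant], equal_var=False)
        assert cut.p_value < 0.05
        # same point selected under either test flavor
        assert cut.rma_percent == determine_cutoff(curves[variant]).rma_percent


def test_cutoff_skips_points_indistinguishable_from_background():
    points = (
        CalibratorPoint(0.0, 0.10, 0.05, 3),
        CalibratorPoint(1.5, 0.10, 0.05, 3),  # identical to background
        CalibratorPoint(3.0, 0.60, 0.05, 3),
    )
    cutoff = determine_cutoff(CalibratorCurve(A605, points))
    assert cutoff.rma_percent == 3.0


def test_cutoff_selection_invariant_to_point_order(curves):
    curve = curves["c.605G>A"]
    shuffled = CalibratorCurve(curve.assay, tuple(reversed(curve.points)))
    assert determine_cutoff(shuffled) == determine_cutoff(curve)


def test_no_significant_point_raises():
    points = (
        CalibratorPoint(0.0, 0.10, 0.30, 3),
        CalibratorPoint(3.0, 0.12, 0.30, 3),
    )
    with pytest.raises(NoCutoffError):
        determine_cutoff(CalibratorCurve(A604, points))


def test_degenerate_zero_variance_comparison():
    a = CalibratorPoint(3.0, 0.5, 0.0, 3)
    b = CalibratorPoint(0.0, 0.0, 0.0, 3)
    assert summary_ttest_pvalue(a, b) == 0.0
    assert summary_ttest_pvalue(b, b) == 1.0


@pytest.mark.parametrize(
    "cpm, expected",
    [(0.815, "MUT"), (0.383, "WT"), (0.0, "WT"), (0.464, "MUT")],
)
def test_call_sample_point_cutoff_rule(curves, cpm, expected):
    cutoff = determine_cutoff(curves["c.605G>A"])
    assert call_sample(cpm, cutoff) == expected


def test_rma_label_at_point_mean_is_that_level(curves):
    curve = curves["c.605G>A"]
    label = assign_rma(1.171, curve)  # exactly the 6% point mean
    assert (label.relation, label.level) == ("=", 6.0)
    assert str(label) == "6"


def test_rma_label_saturates_at_top_of_ladder(curves):
    label = assign_rma(17.626, curves["c.605G>A"])
    assert str(label) == "100"


def test_rma_label_between_levels_outside_both_bands():
    points = (
        CalibratorPoint(0.0, 0.1, 0.01, 3),
        CalibratorPoint(3.0, 1.0, 0.01, 3),
        CalibratorPoint(6.0, 4.0, 0.01, 3),
        CalibratorPoint(100.0, 40.0, 0.01, 3),
    )
    curve = CalibratorCurve(A605, points)
    label = assign_rma(2.0, curve)  # geometric midpoint of 1.0 and 4.0
    assert label.relation == ">"
    assert label.level == 3.0


def test_rma_assignment_requires_positive_cpm(curves):
    with pytest.raises(ValueError):
        assign_rma(0.0, curves["c.605G>A"])


@pytest.mark.parametrize(
    "cpm_mean, lod",
    [(0.464, 0.01), (0.391, 0.01), (0.0, 0.00)],
)
def test_lod_is_ceiling_rounded_mass_of_cutoff(cpm_mean, lod):
    cutoff = Cutoff(cpm_mean=cpm_mean, cpm_sd=0.01, rma_percent=1.5, p_value=0.001)
    assert compute_lod(cutoff) == lod


def test_synthetic_triplicates_recover_reference_means(curves):
    """Noisy triplicates drawn at the reference means rebuild the curve."""
    rng = np.random.default_rng(2024)
    ref = curves["c.605G>A"]
    reps = {
        p.rma_percent: rng.normal(p.mean_cpm, p.sd_cpm, size=3).clip(min=0).tolist()
        for p in ref.points
    }
    rebuilt = build_calibrator(reps, ref.assay)
    for built, expected in zip(rebuilt.points, ref.points):
        se = expected.sd_cpm / np.sqrt(3)
        assert abs(built.mean_cpm - expected.mean_cpm) <= 3 * se + 1e-9


def test_nonmonotone_curve_warns():
    points = (
        CalibratorPoint(0.0, 0.10, 0.01, 3),
        CalibratorPoint(3.0, 0.80, 0.01, 3),
        CalibratorPoint(6.0, 0.50, 0.01, 3),
    )
    with pytest.warns(UserWarning):
        CalibratorCurve(A604, points)
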