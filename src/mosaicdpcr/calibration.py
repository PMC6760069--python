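"""Calibrator curves, positivity cutoffs, sample calling and detection limit.

Serial dilutions of a pure heterozygous-mutant control (100% relative
mutation abundance, RMA) into wild-type DNA give a ladder of known RMAs,
each run in triplicate.  The 0% point — wild-type DNA only — measures the
assay's false-positive background.  A dilution point whose mean cpm is
statistically distinguishable from that background (two-sample t-test on
the triplicate summaries) defines the lowest RMA the assay can call; the
mean cpm of the lowest such point is the positivity cutoff, and its mass
equivalent, rounded upward, is the limit of detection.

The printed reference summaries place the cutoffs at 0.391 copies/µl (3%
RMA, c.604C>T assay) and 0.464 copies/µl (1.5% RMA, c.605G>A assay).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import round_ceiling
from .chips import AssayDefinition, assay_for
from .quantify import QuantConstants, absolute_quant_exact

__all__ = [
    "CalibratorPoint",
    "CalibratorCurve",
    "Cutoff",
    "RmaLabel",
    "NoCutoffError",
    "build_calibrator",
    "load_calibrator_replicates",
    "reference_curves",
    "summary_ttest_pvalue",
    "determine_cutoff",
    "call_sample",
    "assign_rma",
    "compute_lod",
]


@dataclass(frozen=True)
class CalibratorPoint:
    """Replicate summary (mean, sample SD, n) of cpm at one dilution level."""

    rma_percent: float
    mean_cpm: float
    sd_cpm: float
    n_reps: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.rma_percent <= 100:
            raise ValueError("rma_percent must be in [0, 100]")
        if self.sd_cpm < 0:
            raise ValueError("sd_cpm must be non-negative")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates per dilution")


@dataclass(frozen=True)
class CalibratorCurve:
    """Ordered dilution series for one assay, anchored by the 0% point."""

    assay: AssayDefinition
    points: tuple[CalibratorPoint, ...]

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: p.rma_percent))
        object.__setattr__(self, "points", pts)
        zeros = [p for p in pts if p.rma_percent == 0]
        if len(zeros) != 1:
            raise ValueError("curve needs exactly one 0% RMA point")
        means = [p.mean_cpm for p in pts]
        if any(b < a for a, b in zip(means, means[1:])):
            warnings.warn("calibrator mean cpm not monotone in RMA", stacklevel=2)

    @property
    def zero_point(self) -> CalibratorPoint:
        return self.points[0] if self.points[0].rma_percent == 0 else next(
            p for p in self.points if p.rma_percent == 0
        )

    @property
    def nonzero_points(self) -> tuple[CalibratorPoint, ...]:
        return tuple(p for p in self.points if p.rma_percent > 0)

    @property
    def top_point(self) -> CalibratorPoint:
        return self.points[-1]


@dataclass(frozen=True)
class Cutoff:
    """The lowest dilution point distinguishable from the 0% background."""

    cpm_mean: float
    cpm_sd: float
    rma_percent: float
    p_value: float


@dataclass(frozen=True)
class RmaLabel:
    """Semi-quantitative RMA category: a grid level and a relation to it."""

    relation: str  # one of "=", "<", ">"
    level: float  # rma_percent of the anchoring calibrator point

    def __post_init__(self) -> None:
        if self.relation not in ("=", "<", ">"):
            raise ValueError("relation must be '=', '<' or '>'")

    def __str__(self) -> str:
        lvl = f"{self.level:g}"
        return lvl if self.relation == "=" else f"{self.relation}{lvl}"


class NoCutoffError(RuntimeError):
    """No dilution point differs significantly from background; assay not validated."""


def build_calibrator(
    replicate_cpms: Mapping[float, Sequence[float]],
    assay: AssayDefinition,
) -> CalibratorCurve:
    """Summarize replicate cpm values into a calibrator curve.

    Each dilution needs at least two replicates; SDs use the n−1
    denominator.  A 0% dilution must be present.
    """
    points = []
    for rma, values in replicate_cpms.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"dilution {rma}% has fewer than 2 replicates")
        points.append(
            CalibratorPoint(
                rma_percent=float(rma),
                mean_cpm=float(arr.mean()),
                sd_cpm=float(arr.std(ddof=1)),
                n_reps=int(arr.size),
            )
        )
    if not any(p.rma_percent == 0 for p in points):
        raise ValueError("calibrator series must include a 0% (wild-type) dilution")
    return CalibratorCurve(assay=assay, points=tuple(points))


def load_calibrator_replicates(path: str | Path) -> dict[str, CalibratorCurve]:
    """Read a replicate TSV (`assay_id, rma_percent, replicate, cpm`) into curves."""
    df = pd.read_csv(path, sep="\t")
    curves = {}
    for assay_id, grp in df.groupby("assay_id"):
        assay = assay_for(str(assay_id))
        reps = {
            float(rma): sub["cpm"].tolist() for rma, sub in grp.groupby("rma_percent")
        }
        curves[assay.target_variant] = build_calibrator(reps, assay)
    return curves


def reference_curves() -> dict[str, CalibratorCurve]:
    """The packaged reference calibrator summaries, keyed by target variant."""
    with resources.files("mosaicdpcr.data").joinpath("calibrator_summaries.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    curves = {}
    for assay_id, grp in df.groupby("assay_id"):
        assay = assay_for(str(assay_id))
        points = tuple(
            CalibratorPoint(row.rma_percent, row.mean_cpm, row.sd_cpm, int(row.n_reps))
            for row in grp.itertuples()
        )
        curves[assay.target_variant] = CalibratorCurve(assay=assay, points=points)
    return curves


def summary_ttest_pvalue(
    a: CalibratorPoint, b: CalibratorPoint, equal_var: bool = True
) -> float:
    """Two-sided two-sample t-test p-value from summary statistics.

    Pooled-variance by default (df = n_a + n_b − 2), which reproduces the
    reference p-values of the validated assays; set ``equal_var=False`` for
    Welch's test.  Degenerate zero-variance comparisons resolve by the
    means alone.
    """
    if a.sd_cpm == 0 and b.sd_cpm == 0:
        return 0.0 if a.mean_cpm != b.mean_cpm else 1.0
    result = stats.ttest_ind_from_stats(
        a.mean_cpm, a.sd_cpm, a.n_reps,
        b.mean_cpm, b.sd_cpm, b.n_reps,
        equal_var=equal_var,
    )
    return float(result.pvalue)


def determine_cutoff(
    curve: CalibratorCurve, alpha: float = 0.05, equal_var: bool = True
) -> Cutoff:
    """Select the positivity cutoff from a calibrator curve.

    The cutoff is the lowest-RMA nonzero point whose mean cpm exceeds the
    0% point's and differs from it with two-sided p < alpha.
    """
    zero = curve.zero_point
    for point in curve.nonzero_points:
        p = summary_ttest_pvalue(point, zero, equal_var=equal_var)
        if p < alpha and point.mean_cpm > zero.mean_cpm:
            return Cutoff(
                cpm_mean=point.mean_cpm,
                cpm_sd=point.sd_cpm,
                rma_percent=point.rma_percent,
                p_value=p,
            )
    raise NoCutoffError(
        f"no dilution of {curve.assay.assay_id} separates from the 0% background at alpha={alpha}"
    )


def call_sample(cpm: float, cutoff: Cutoff) -> str:
    """Call MUT when the sample's cpm reaches the cutoff mean, else WT."""
    if cpm < 0:
        raise ValueError("cpm must be non-negative")
    return "MUT" if cpm >= cutoff.cpm_mean else "WT"


def assign_rma(cpm: float, curve: CalibratorCurve) -> RmaLabel:
    """Attribute a MUT sample to an RMA subcluster of the calibrator grid.

    The anchor is the nonzero point nearest in log-cpm; the sample is "="
    that level when within 2 SD of the anchor mean, otherwise above (">")
    or below ("<") it.  At or beyond the top of the ladder the label
    saturates at the 100% level.
    """
    if cpm <= 0:
        raise ValueError("assign_rma applies to MUT samples with positive cpm")
    top = curve.top_point
    if cpm >= top.mean_cpm:
        return RmaLabel("=", top.rma_percent)
    anchor = min(
        curve.nonzero_points,
        key=lambda p: abs(math.log(cpm) - math.log(p.mean_cpm)),
    )
    if abs(cpm - anchor.mean_cpm) <= 2 * anchor.sd_cpm:
        return RmaLabel("=", anchor.rma_percent)
    return RmaLabel(">" if cpm > anchor.mean_cpm else "<", anchor.rma_percent)


def compute_lod(cutoff: Cutoff, k: QuantConstants = QuantConstants()) -> float:
    """Limit of detection in ng/µl: the cutoff's mass equivalent, rounded up.

    The ceiling (rather than half-up) makes the LOD the smallest 2-decimal
    mass concentration reliably distinguishable from wild type.
    """
    return round_ceiling(absolute_quant_exact(cutoff.cpm_mean, k), 2)
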