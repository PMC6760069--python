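"""Poisson quantification of mutant copies per µl and mass conversion.

With template molecules distributed over partitions at random, the fraction
of positive partitions p underestimates occupancy whenever a well can hold
more than one copy.  The standard digital-PCR correction inverts the
Poisson zero term: the mean copies per well is λ = −ln(1 − p), and the
concentration in the reaction mix is λ divided by the per-well volume.  At
the occupancies seen in rare-mosaic work (p well below 1%), the correction
is numerically tiny but applied throughout for correctness.

Mass concentration follows the instrument's absolute-quantification rule:
copies/µl × 0.0033 ng (one haploid genome) × 3.34 (dilution factor for the
15 µl reaction).  The 3.34 constant is used verbatim as printed, not
rederived from volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._rounding import round_half_up
from .calling import PartitionSummary, QcPolicy, call_partitions
from .chips import ChipData, ChipSpec

__all__ = [
    "QuantConstants",
    "QuantResult",
    "SaturationError",
    "poisson_cpm",
    "absolute_quant",
    "absolute_quant_exact",
    "quantify_chip",
]


@dataclass(frozen=True)
class QuantConstants:
    """Constants of the absolute-quantification formula."""

    genome_mass_ng: float = 0.0033  # ng per haploid human genome
    dilution_factor: float = 3.34  # printed factor for the 15 µl reaction

    def __post_init__(self) -> None:
        if self.genome_mass_ng <= 0 or self.dilution_factor <= 0:
            raise ValueError("constants must be strictly positive")


class SaturationError(ValueError):
    """Every valid partition is positive: occupancy is unbounded."""


@dataclass(frozen=True)
class QuantResult:
    """Quantification for one chip: copies/µl, ng/µl, and reportability."""

    cpm: float  # mutant copies per µl of reaction mix, 3 decimals
    abs_ng_per_ul: float  # mass concentration, 2 decimals
    reportable: bool  # False when the chip failed partition QC


def poisson_cpm(summary: PartitionSummary, spec: "ChipSpec | float") -> float:
    """Poisson-corrected concentration (copies/µl) from partition counts.

    λ = −ln(1 − n_positive/n_valid); cpm = λ / partition volume.  A chip
    with no positives gives exactly 0; a saturated chip has no finite
    estimate and raises :class:`SaturationError`.  ``spec`` may be a
    :class:`~mosaicdpcr.chips.ChipSpec` or the per-well volume in µl.
    """
    partition_volume = getattr(spec, "partition_volume", spec)
    if summary.n_valid <= 0:
        raise ValueError("no valid partitions")
    if summary.n_positive == 0:
        return 0.0
    if summary.n_positive >= summary.n_valid:
        raise SaturationError("all valid partitions positive; concentration not estimable")
    p = summary.n_positive / summary.n_valid
    lam = -math.log1p(-p)
    return lam / partition_volume


def absolute_quant_exact(cpm: float, k: QuantConstants = QuantConstants()) -> float:
    """Unrounded mass concentration in ng/µl (linear in cpm)."""
    if cpm < 0:
        raise ValueError("cpm must be non-negative")
    return cpm * k.genome_mass_ng * k.dilution_factor


def absolute_quant(cpm: float, k: QuantConstants = QuantConstants()) -> float:
    """Mass concentration in ng/µl, rounded half-up to 2 decimals."""
    return round_half_up(absolute_quant_exact(cpm, k), 2)


def quantify_chip(
    chip: ChipData,
    policy: QcPolicy = QcPolicy(),
    k: QuantConstants = QuantConstants(),
) -> QuantResult:
    """Full per-chip quantification: call partitions, then convert.

    cpm is reported to 3 decimals and the mass concentration to 2, matching
    the reporting convention of the instrument output.  A chip failing the
    valid-partition floor is still quantified but flagged non-reportable.
    """
    summary = call_partitions(chip, policy)
    cpm = round_half_up(poisson_cpm(summary, chip.spec.partition_volume), 3)
    return QuantResult(
        cpm=cpm,
        abs_ng_per_ul=absolute_quant(cpm, k),
        reportable=summary.qc_pass,
    )
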