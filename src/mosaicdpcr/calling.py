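"""QC filtering and positive/negative partition calling.

Mirrors the analyst workflow on the instrument software: wells whose quality
score clears a fixed floor are *valid*; valid wells whose FAM signal exceeds
the assay's fluorescence threshold are *positive*.  A chip is reportable
only when enough valid data points remain (default 10,000 of 20,000).  Both
comparisons are strict: values exactly at a threshold are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chips import ChipData

__all__ = ["QcPolicy", "PartitionSummary", "call_partitions"]


@dataclass(frozen=True)
class QcPolicy:
    """Chip-level quality policy: per-well score floor and valid-well count floor."""

    min_valid_partitions: int = 10_000
    min_quality: float = 0.6

    def __post_init__(self) -> None:
        if self.min_valid_partitions < 1:
            raise ValueError("min_valid_partitions must be >= 1")
        if not 0 <= self.min_quality <= 1:
            raise ValueError("min_quality must be in [0, 1]")


@dataclass(frozen=True)
class PartitionSummary:
    n_total: int
    n_valid: int
    n_positive: int
    qc_pass: bool

    def __post_init__(self) -> None:
        if not self.n_positive <= self.n_valid <= self.n_total:
            raise ValueError("require n_positive <= n_valid <= n_total")


def call_partitions(chip: ChipData, policy: QcPolicy = QcPolicy()) -> PartitionSummary:
    """Count valid and positive partitions on one chip.

    Valid: quality strictly above ``policy.min_quality``.  Positive: valid
    and FAM RFU strictly above the assay threshold.  ``qc_pass`` records
    whether the valid count reaches the policy floor; counts are returned
    either way so an analyst can inspect a failed chip.
    """
    if len(chip) == 0:
        raise ValueError("chip has no wells")
    valid = np.asarray(chip.quality) > policy.min_quality
    positive = valid & (np.asarray(chip.fam_rfu) > chip.assay.rfu_threshold)
    n_valid = int(valid.sum())
    return PartitionSummary(
        n_total=len(chip),
        n_valid=n_valid,
        n_positive=int(positive.sum()),
        qc_pass=n_valid >= policy.min_valid_partitions,
    )
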