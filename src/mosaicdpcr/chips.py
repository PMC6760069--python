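"""Synthetic nanowell digital-PCR chips with known ground truth.

Digital PCR partitions a reaction into thousands of nanoliter wells so that
rare mutant template molecules end up isolated in individual wells, where a
mutation-specific FAM-labelled assay amplifies them to a bright endpoint
signal.  This module emulates a 20,000-well chip loaded with genomic DNA
from a mosaic tissue: a fraction ``het_cell_fraction`` of cells carry the
activating variant heterozygously, so the mutant *allele* fraction is half
the mutant *cell* fraction.  Mutant copies land in wells as independent
Poisson counts; wells holding at least one copy draw their fluorescence
from a bright component, the rest from the dark baseline.

The generator is the ground-truth oracle for every downstream stage:
partition calling, Poisson quantification and calibrator construction can
all be checked against the parameters that produced a chip.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "HAPLOID_GENOME_MASS_NG",
    "AssayDefinition",
    "ASSAYS",
    "ChipSpec",
    "FluorModel",
    "SimulationParams",
    "WellRecord",
    "ChipData",
    "assay_for",
    "mass_to_copies",
    "expected_mutant_copies",
    "simulate_chip",
    "write_chip_csv",
    "read_chip_csv",
]

#: mass of one haploid human genome, in ng
HAPLOID_GENOME_MASS_NG = 0.0033

# fixed pairing of mutation-detection assays to the coding changes they target,
# and the fluorescence threshold (RFU) above which a well is a positive call
_ASSAY_TABLE = {
    "GNAS_27887_mu": ("c.604C>T", 5000.0),
    "GNAS_27895_mu": ("c.605G>A", 3000.0),
}


@dataclass(frozen=True)
class AssayDefinition:
    """A FAM-labelled mutation-detection assay and its positivity threshold."""

    assay_id: str
    target_variant: str
    rfu_threshold: float

    def __post_init__(self) -> None:
        if self.rfu_threshold <= 0:
            raise ValueError("rfu_threshold must be positive")
        expected = _ASSAY_TABLE.get(self.assay_id)
        if expected is not None and expected[0] != self.target_variant:
            raise ValueError(
                f"assay {self.assay_id} targets {expected[0]}, not {self.target_variant}"
            )


#: the two GNAS Arg202 assays, keyed by target variant
ASSAYS: dict[str, AssayDefinition] = {
    variant: AssayDefinition(assay_id, variant, threshold)
    for assay_id, (variant, threshold) in _ASSAY_TABLE.items()
}


def assay_for(key: str) -> AssayDefinition:
    """Look up an assay by target variant (``c.604C>T``) or assay id."""
    if key in ASSAYS:
        return ASSAYS[key]
    for assay in ASSAYS.values():
        if assay.assay_id == key:
            return assay
    raise KeyError(f"unknown assay or variant: {key!r}")


@dataclass(frozen=True)
class ChipSpec:
    """Geometry of a nanowell chip.

    The default partition volume spreads the 15 µl load evenly over the
    20,000 wells; it is configurable because the instrument's effective
    per-well volume is not a published constant.
    """

    n_partitions: int = 20_000
    partition_volume: float = 7.5e-4  # µl per well
    loaded_volume: float = 15.0  # µl of reaction mix on the chip

    def __post_init__(self) -> None:
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        if self.partition_volume <= 0:
            raise ValueError("partition_volume must be positive")
        if self.n_partitions * self.partition_volume > self.loaded_volume * (1 + 1e-9):
            raise ValueError("total partition volume exceeds loaded volume")


@dataclass(frozen=True)
class FluorModel:
    """Two-component FAM endpoint-fluorescence model.

    Defaults put the dark (no mutant template) and bright (>=1 mutant copy)
    components well either side of both assays' thresholds.
    """

    neg_mean: float = 1000.0
    neg_sd: float = 400.0
    pos_mean: float = 8000.0
    pos_sd: float = 800.0
    quality_low_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.pos_mean <= self.neg_mean:
            raise ValueError("pos_mean must exceed neg_mean")
        if min(self.neg_sd, self.pos_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if not 0 <= self.quality_low_fraction < 1:
            raise ValueError("quality_low_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SimulationParams:
    """Ground truth for one simulated chip.

    ``het_cell_fraction`` is the relative mutation abundance (RMA) as a
    fraction: 1.0 means pure heterozygous-mutant DNA, in which case half the
    alleles are mutant.
    """

    dna_conc: float  # ng/µl of input DNA
    het_cell_fraction: float
    seed: int
    dna_volume: float = 1.0  # µl of DNA added to the 15 µl reaction
    fluor_model: FluorModel = field(default_factory=FluorModel)
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.het_cell_fraction <= 1:
            raise ValueError("het_cell_fraction must be in [0, 1]")
        if self.dna_conc < 0:
            raise ValueError("dna_conc must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class WellRecord:
    """One partition: endpoint FAM fluorescence and a [0, 1] quality score."""

    fam_rfu: float
    quality: float


@dataclass
class ChipData:
    """Per-well records for one sample x assay chip, plus optional truth."""

    assay: AssayDefinition
    spec: ChipSpec
    fam_rfu: np.ndarray
    quality: np.ndarray
    truth: SimulationParams | None = None

    def __post_init__(self) -> None:
        self.fam_rfu = np.asarray(self.fam_rfu, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if len(self.fam_rfu) != self.spec.n_partitions or len(self.quality) != self.spec.n_partitions:
            raise ValueError("well arrays must have spec.n_partitions entries")

    def __len__(self) -> int:
        return self.spec.n_partitions

    @property
    def wells(self) -> Iterator[WellRecord]:
        for rfu, q in zip(self.fam_rfu, self.quality):
            yield WellRecord(float(rfu), float(q))


def mass_to_copies(mass_ng: float) -> float:
    """Convert a DNA mass in ng to haploid genome copies (exact linear map)."""
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    return mass_ng / HAPLOID_GENOME_MASS_NG


def expected_mutant_copies(params: SimulationParams) -> float:
    """Mutant-allele copies loaded on the chip.

    Heterozygous cells carry the variant on one of their two alleles, so the
    mutant copy number is half the genome count times the mutant-cell
    fraction.
    """
    total = mass_to_copies(params.dna_conc * params.dna_volume)
    return total * params.het_cell_fraction * 0.5


def simulate_chip(
    params: SimulationParams,
    assay: AssayDefinition,
    spec: ChipSpec = ChipSpec(),
) -> ChipData:
    """Simulate one chip; bit-identical for identical params and seed.

    Mutant copies are scattered over wells as iid Poisson counts with mean
    ``M * partition_volume / loaded_volume``; occupancy (>=1 copy) selects
    the bright fluorescence component.  Wells flagged as dropout or drawn
    from the low-quality mass get a quality score below 0.6.
    """
    rng = np.random.default_rng(params.seed)
    n = spec.n_partitions
    fm = params.fluor_model

    lam = expected_mutant_copies(params) * spec.partition_volume / spec.loaded_volume
    counts = rng.poisson(lam, size=n)

    neg = rng.normal(fm.neg_mean, fm.neg_sd, size=n)
    pos = rng.normal(fm.pos_mean, fm.pos_sd, size=n)
    fam = np.clip(np.where(counts > 0, pos, neg), 0.0, None)

    dropout = rng.random(n) < params.dropout_rate
    low_quality = dropout | (rng.random(n) < fm.quality_low_fraction)
    q_low = rng.uniform(0.0, 0.6, size=n)
    q_high = rng.uniform(0.6, 1.0, size=n)
    quality = np.where(low_quality, q_low, q_high)

    return ChipData(assay=assay, spec=spec, fam_rfu=fam, quality=quality, truth=params)


def write_chip_csv(chip: ChipData, path: str | Path) -> Path:
    """Write per-well records as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well_index", "fam_rfu", "quality"])
        for i, (rfu, q) in enumerate(zip(chip.fam_rfu, chip.quality)):
            writer.writerow([i, f"{rfu:.3f}", f"{q:.6f}"])
    meta: dict = {
        "assay_id": chip.assay.assay_id,
        "target_variant": chip.assay.target_variant,
        "rfu_threshold": chip.assay.rfu_threshold,
        "n_partitions": chip.spec.n_partitions,
        "partition_volume": chip.spec.partition_volume,
        "loaded_volume": chip.spec.loaded_volume,
    }
    if chip.truth is not None:
        meta["truth"] = asdict(chip.truth)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_chip_csv(path: str | Path, assay: AssayDefinition | None = None) -> ChipData:
    """Read a chip CSV written by :func:`write_chip_csv`.

    Metadata comes from the JSON sidecar when present; otherwise an assay
    must be supplied and the chip geometry defaults to the well count.
    """
    path = Path(path)
    rfu: list[float] = []
    quality: list[float] = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            rfu.append(float(row["fam_rfu"]))
            quality.append(float(row["quality"]))

    sidecar = path.with_suffix(".json")
    truth = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        assay = AssayDefinition(meta["assay_id"], meta["target_variant"], meta["rfu_threshold"])
        spec = ChipSpec(meta["n_partitions"], meta["partition_volume"], meta["loaded_volume"])
        if "truth" in meta:
            t = dict(meta["truth"])
            t["fluor_model"] = FluorModel(**t["fluor_model"])
            truth = SimulationParams(**t)
    else:
        if assay is None:
            raise ValueError(f"no metadata sidecar for {path}; pass an assay")
        spec = ChipSpec(n_partitions=len(rfu), partition_volume=15.0 / len(rfu))
    return ChipData(assay=assay, spec=spec, fam_rfu=np.array(rfu), quality=np.array(quality), truth=truth)
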