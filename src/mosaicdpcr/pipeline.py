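"""End-to-end pipeline: configuration, report bundle and fixture generation.

`run_pipeline` ties the stages together: calibrator curves -> positivity
cutoffs and detection limit -> re-calling of every cohort sample from its
measured cpm -> detection-rate tables, subcohort comparison and
false-negative counts.  Reports embed the full configuration snapshot and a
content hash of every input file, and are byte-identical for identical
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cohort as cohort_mod
from .calibration import (
    CalibratorCurve,
    build_calibrator,
    compute_lod,
    determine_cutoff,
    load_calibrator_replicates,
    reference_curves,
)
from .calling import QcPolicy, call_partitions
from .chips import ASSAYS, ChipSpec, SimulationParams, assay_for, simulate_chip, write_chip_csv
from .quantify import QuantConstants, poisson_cpm
from .calibration import call_sample

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "RMA_GRIDS"]

#: serial-dilution grids of the two reference calibrator series (% RMA)
RMA_GRIDS = {
    "c.604C>T": (0.0, 3.0, 6.0, 12.5, 25.0, 50.0, 100.0),
    "c.605G>A": (0.0, 1.5, 3.0, 6.0, 12.5, 25.0, 100.0),
}


@dataclass
class PipelineConfig:
    """Pipeline settings; every default equals the validated constant."""

    rfu_thresholds: dict = field(
        default_factory=lambda: {"c.604C>T": 5000.0, "c.605G>A": 3000.0}
    )
    min_valid_partitions: int = 10_000
    min_quality: float = 0.6
    genome_mass_ng: float = 0.0033
    dilution_factor: float = 3.34
    n_partitions: int = 20_000
    partition_volume: float = 7.5e-4
    loaded_volume: float = 15.0
    alpha: float = 0.05
    equal_var: bool = True
    calibrator_path: str | None = None  # replicate TSV; None -> packaged summaries
    cohort_path: str | None = None  # None -> packaged cohort sheet
    seed: int = 1
    outdir: str = "results"
    # optional simulation stage: replicate chips along each assay's RMA grid
    simulate: bool = False
    sim_dna_conc: float = 5.0  # ng/µl
    sim_replicates: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def qc_policy(self) -> QcPolicy:
        return QcPolicy(self.min_valid_partitions, self.min_quality)

    def constants(self) -> QuantConstants:
        return QuantConstants(self.genome_mass_ng, self.dilution_factor)

    def chip_spec(self) -> ChipSpec:
        return ChipSpec(self.n_partitions, self.partition_volume, self.loaded_volume)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _curve_payload(curve: CalibratorCurve) -> dict:
    return {
        "assay_id": curve.assay.assay_id,
        "points": [
            {"rma_percent": p.rma_percent, "mean_cpm": p.mean_cpm, "sd_cpm": p.sd_cpm, "n_reps": p.n_reps}
            for p in curve.points
        ],
    }


def _simulated_curves(config: PipelineConfig) -> dict[str, CalibratorCurve]:
    """Simulate replicate chips along each assay's RMA grid and summarize.

    Replicate chips take consecutive seeds (seed + running index) so one
    configuration seed fully determines the stage.
    """
    spec = config.chip_spec()
    policy = config.qc_policy()
    curves = {}
    offset = 0
    for variant, grid in RMA_GRIDS.items():
        assay = ASSAYS[variant]
        reps: dict[float, list[float]] = {}
        for rma in grid:
            values = []
            for _ in range(config.sim_replicates):
                params = SimulationParams(
                    dna_conc=config.sim_dna_conc,
                    het_cell_fraction=rma / 100.0,
                    seed=config.seed + offset,
                )
                offset += 1
                chip = simulate_chip(params, assay, spec)
                values.append(poisson_cpm(call_partitions(chip, policy), spec))
            reps[rma] = values
        curves[variant] = build_calibrator(reps, assay)
    return curves


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Writes ``report.json``, ``detection_tables.tsv`` and a plain-text table
    rendering into ``config.outdir``; returns the report as a dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    # calibrators and cutoffs
    if config.calibrator_path:
        cal_path = Path(config.calibrator_path)
        if not cal_path.exists():
            raise FileNotFoundError(f"calibrator file not found: {cal_path}")
        curves = load_calibrator_replicates(cal_path)
        inputs["calibrators"] = _sha256(cal_path)
    else:
        curves = reference_curves()
    cutoffs = {
        v: determine_cutoff(c, alpha=config.alpha, equal_var=config.equal_var)
        for v, c in curves.items()
    }
    lod = {v: compute_lod(cut, config.constants()) for v, cut in cutoffs.items()}

    # cohort tabulation
    cohort_path = (
        Path(config.cohort_path) if config.cohort_path else cohort_mod.packaged_cohort_path()
    )
    if not cohort_path.exists():
        raise FileNotFoundError(f"cohort sheet not found: {cohort_path}")
    records = cohort_mod.load_cohort(cohort_path)
    inputs["cohort"] = _sha256(cohort_path)

    tables = {m: cohort_mod.detection_table(records, m) for m in cohort_mod.METHODS}
    sub_tables = cohort_mod.subcohort_comparison(records)

    # re-call every sample from its measured cpm against the inferred cutoffs
    recall = {"concordant": 0, "compared": 0, "discordant": []}
    for rec in records:
        for variant, cpm in rec.dpcr_cpm.items():
            if cpm is None or variant not in cutoffs:
                continue
            derived = call_sample(cpm, cutoffs[variant])
            printed = rec.calls[("DPCR", variant)]
            if printed == "ND":
                continue
            recall["compared"] += 1
            if derived == printed:
                recall["concordant"] += 1
            else:
                recall["discordant"].append(
                    {"patient": rec.patient_id, "tissue": rec.tissue_label,
                     "variant": variant, "cpm": cpm, "derived": derived, "printed": printed}
                )

    report = {
        "config": asdict(config),
        "inputs_sha256": inputs,
        "calibrators": {v: _curve_payload(c) for v, c in curves.items()},
        "cutoffs": {
            v: {"cpm_mean": c.cpm_mean, "cpm_sd": c.cpm_sd,
                "rma_percent": c.rma_percent, "p_value": c.p_value}
            for v, c in cutoffs.items()
        },
        "lod_ng_per_ul": lod,
        "sample_recall": recall,
        "detection": {
            m: {
                "by_class": {k: list(cell) for k, cell in t.by_class.items()},
                "samples": list(t.samples),
                "patients": list(t.patients),
                "patient_rate_percent": t.patient_rate,
            }
            for m, t in tables.items()
        },
        "subcohort": {
            m: {
                "by_class": {k: list(cell) for k, cell in t.by_class.items()},
                "patients": list(t.patients),
                "patient_rate_percent": t.patient_rate,
            }
            for m, t in sub_tables.items()
        },
        "false_negatives_vs_dpcr": {
            m: cohort_mod.false_negative_count(records, m) for m in ("SANGER", "ASPCR", "COLD")
        },
    }

    if config.simulate:
        sim_curves = _simulated_curves(config)
        report["simulation"] = {
            "curves": {v: _curve_payload(c) for v, c in sim_curves.items()},
            "cutoffs": {
                v: {
                    "cpm_mean": cut.cpm_mean,
                    "rma_percent": cut.rma_percent,
                    "p_value": cut.p_value,
                }
                for v, cut in (
                    (v, determine_cutoff(c, config.alpha, config.equal_var))
                    for v, c in sim_curves.items()
                )
            },
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    rows = []
    for m, t in tables.items():
        for label, cell in t.by_class.items():
            rows.append(
                f"{m}\t{label}\t{cell.positive}\t{cell.tested}\t{t.rate(label):g}"
            )
        rows.append(
            f"{m}\tPATIENTS\t{t.patients.positive}\t{t.patients.tested}\t{t.patient_rate:g}"
        )
    (outdir / "detection_tables.tsv").write_text(
        "method\ttissue_class\tpositive\ttested\trate_percent\n" + "\n".join(rows) + "\n"
    )
    (outdir / "detection_tables.txt").write_text(
        "All samples\n" + cohort_mod.render_table(tables)
        + "\n\nSubcohort tested by all methods\n" + cohort_mod.render_table(sub_tables) + "\n"
    )
    return report


def make_fixtures(outdir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Write the cohort sheet, calibrator replicate TSV and simulated chips.

    The cohort sheet is the packaged transcription (data, independent of the
    seed).  Calibrator replicates are reconstructed deterministically from
    the reference summaries as {mean − SD, mean, mean + SD}, which restores
    each point's mean and sample SD exactly.  Chip CSVs span the c.605G>A
    RMA grid at the default loading, one chip per level, seeded from `seed`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    cohort_path = outdir / "cohort_table1.tsv"
    cohort_path.write_text(cohort_mod.packaged_cohort_path().read_text())
    written["cohort"] = cohort_path

    lines = ["assay_id\trma_percent\treplicate\tcpm"]
    for variant, curve in reference_curves().items():
        for point in curve.points:
            for i, value in enumerate(
                (point.mean_cpm - point.sd_cpm, point.mean_cpm, point.mean_cpm + point.sd_cpm)
            ):
                lines.append(
                    f"{curve.assay.assay_id}\t{point.rma_percent:g}\t{i + 1}\t{value:.6f}"
                )
    cal_path = outdir / "calibrator_replicates.tsv"
    cal_path.write_text("\n".join(lines) + "\n")
    written["calibrators"] = cal_path

    chips_dir = outdir / "chips"
    chips_dir.mkdir(exist_ok=True)
    assay = ASSAYS["c.605G>A"]
    for i, rma in enumerate(RMA_GRIDS["c.605G>A"]):
        params = SimulationParams(dna_conc=5.0, het_cell_fraction=rma / 100.0, seed=seed + i)
        chip = simulate_chip(params, assay, ChipSpec())
        path = chips_dir / f"chip_rma{rma:g}.csv"
        write_chip_csv(chip, path)
        written[f"chip_rma{rma:g}"] = path
    return written
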