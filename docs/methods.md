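# Methods

## Chip model

A digital-PCR chip partitions a 15 µl reaction over 20,000 nanowells. The
simulator's ground truth is the loaded DNA: `dna_conc × dna_volume` ng of
genomic DNA converts to haploid genome copies at 0.0033 ng per genome. A
mosaic sample is parameterized by its relative mutation abundance (RMA)
expressed as the fraction of genomes from heterozygous-mutant cells: 100%
RMA means pure heterozygous DNA, so mutant-allele copies are

    M = (mass / 0.0033) × het_cell_fraction × 0.5,

the factor 0.5 because heterozygous cells carry the variant on one of two
alleles. Mutant copies land in wells as independent Poisson counts with
per-well mean λ = M × partition_volume / loaded_volume. The per-well
volume is not a published instrument constant; the default 7.5 × 10⁻⁴ µl
spreads the 15 µl load evenly over the 20K wells and is configurable.

Endpoint FAM fluorescence is a two-component Gaussian mixture: wells with
≥ 1 mutant copy draw from the bright component (default 8,000 ± 800 RFU),
empty wells from the dark baseline (1,000 ± 400 RFU). The defaults place
both published thresholds (3,000 RFU for the c.605 assay, 5,000 for c.604)
cleanly between the components. Wild-type template occupancy is not
modeled per well: the mutation-detection assay reports mutant FAM signal
only, and wild-type molecules leave no trace in that channel. Per-well
quality scores put a configurable mass (default 5%) below the 0.6 QC
floor; a separate dropout rate models loading failures. One integer seed
fully determines a chip; replicate chips use consecutive seeds.

What the simulator does **not** emulate: reference-dye (VIC) channels and
2-D cluster geometry, optical crosstalk, spatial well effects, rain
(intermediate-intensity wells), and false-positive chemistry in the dark
component. Consequently a simulated 0% RMA control yields cpm ≈ 0 exactly,
whereas real wild-type controls show a small nonspecific background (the
reference series has 0.068–0.102 cpm at 0%). Passing tests therefore
demonstrate correctness of the counting statistics and decision rules, not
robustness to instrument artifacts.

## Partition calling and QC

Wells with quality strictly above 0.6 are valid; valid wells with FAM RFU
strictly above the assay threshold are positive. Both inequalities are
strict — a value exactly at a threshold is excluded. A chip passes QC when
at least 10,000 valid data points remain; a failing chip is still counted
and quantified but flagged non-reportable, mirroring analyst review rather
than hard failure. The quality threshold is applied per well with a
per-chip count floor.

## Quantification

With positive fraction p = n_positive / n_valid, the Poisson correction
λ = −ln(1 − p) removes the multiple-occupancy bias, and cpm = λ /
partition_volume is the mutant concentration in the reaction mix. At the
occupancies relevant here (p ≤ 0.2%) the correction changes cpm by less
than 0.1%, so it does not disturb reproduction of reported values; it is
applied regardless because it is the standard digital-PCR estimator. A
saturated chip (every valid well positive) has no finite estimate and
raises an error.

Mass concentration uses the instrument's absolute-quantification rule,
ng/µl = cpm × 0.0033 × 3.34. The 3.34 dilution factor is an opaque
printed constant for the 15 µl reaction; it does not follow from the
stated volumes by simple arithmetic and is deliberately not rederived.
Reporting conventions: cpm to 3 decimals, ng/µl to 2, rounding half away
from zero (hence 32.654 cpm → 0.36 ng/µl).

## Calibration and cutoffs

A calibrator series dilutes a 100% RMA heterozygous-mutant control into
wild-type DNA (c.604: 3–50% plus the undiluted control; c.605: 1.5–25%
plus control), each level in triplicate, alongside a 0% wild-type-only
point that measures the false-positive background. Points are summarized
as mean, sample SD (n − 1) and n.

Each nonzero point is compared with the 0% point by a two-sided
two-sample t-test computed from the summaries. The default is the
pooled-variance Student test (df = n₁ + n₂ − 2), which reproduces the
reference p-values of the validated assays (0.0028 at the c.604 3% point,
0.0004 at the c.605 1.5% point); Welch's unequal-variance flavor is
available via `equal_var=False` and selects the same cutoff points. When
both groups have zero variance the comparison degenerates and is resolved
by the means alone. The **cutoff** is the lowest-RMA point with p < 0.05
and mean above background: 0.391 cpm (3%) for c.604 and 0.464 cpm (1.5%)
for c.605.

A sample is called MUT when its cpm reaches the cutoff mean. This
deterministic point-cutoff rule replaces the partly manual
error-bar/scatterplot examination used in practice; on the packaged
79-sample cohort it reproduces 157 of 158 per-variant calls, the single
discordance being a borderline ovarian-cyst sample (0.412 cpm against the
0.391 cutoff) that manual review had called wild type. No single
threshold rule can reproduce both that call and the borderline blood
sample accepted at 0.465 cpm; the rule keeps the latter.

RMA category labels anchor a MUT sample to the nearest calibrator level in
log-cpm; within 2 SD of the anchor mean the label is "= level", otherwise
"> level" or "< level", saturating at the top of the ladder ("100"). The
subcluster attribution procedure behind the reference labels is not fully
specified, and the printed label-to-assay pairing is internally ambiguous,
so these labels are semi-quantitative output, not a validated quantity.

The limit of detection converts the cutoff cpm to mass and rounds
**upward** to 2 decimals — the only rounding under which both assays give
the single published LOD of 0.01 ng/µl — making the LOD the smallest
reportable concentration distinguishable from wild type.

## Cohort tabulation

The packaged sheet transcribes the 79-sample, 54-patient cohort: per
sample, per variant, the calls of Sanger sequencing, allele-specific PCR,
COLD-MAMA PCR and dPCR, plus dPCR cpm and RMA labels. Blank or "nd" cells
mean not tested (ND). A sample is positive for a method when either
variant is MUT (counted once), and tested when at least one variant has a
non-ND call; a patient is positive/tested when any of their samples is.
Tissue codes reduce to four classes: bone (BO), cutis/fibroblasts (CB/FB),
ovarian cyst/cyst liquid/tissue (OC/OCL/OT), and blood (BL). Rates are
percentages to 1 decimal, half-up by default with truncation-toward-zero
available for rendering repeating decimals (10/15 as 66.6).

The cross-method comparison restricts to the subcohort with a non-ND
result for all four methods (26 samples from 14 patients), on which the
ordering dPCR ≥ COLD-MAMA ≥ AS-PCR ≥ Sanger holds; false negatives count
patients positive by dPCR, tested but negative by the other method.

Known transcription-level discrepancies in the source tables are kept as
transcribed rather than silently harmonized; the per-tissue positive
counts computed from the sheet are the authoritative totals here (the
dPCR per-tissue cells sum to 37 positive samples).

## Problem sizes and numerical choices

Stochastic tests run at the study's native scale — 20,000-well chips, 5
ng/µl loading, triplicate dilution series — with 40–200 seeds per
property, chosen so that three-standard-error acceptance bands make seed
flakiness negligible while the whole suite runs in seconds. Monotone
violations in calibrator means warn rather than fail; ties at thresholds
are excluded by strict comparison; all reported rounding goes through
decimal arithmetic to avoid banker's rounding surprises.
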