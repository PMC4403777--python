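# Methods

`methpanel` implements the quantitative analysis layer of a multi-assay
promoter-methylation study: the same CpG island is interrogated by clonal
bisulfite sequencing, methylation-specific real-time PCR (MethyLight),
Infinium-style methylation arrays, and methylation-specific melting curve
analysis (MS-MCA), and the resulting methylation calls are integrated with
expression and clinical annotation. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Bisulfite clone calling

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
and leaves 5-methyl-cytosine intact. A cloned amplicon read therefore
encodes one allele's methylation pattern: at each CpG position, C is
called methylated, T unmethylated, and any other base missing. The
bisulfite conversion rate is estimated from non-CpG cytosines, which
should always read T; the denominator counts only non-CpG C positions
read as C or T, since other bases carry no conversion information. CpG
positions are deliberately excluded from the rate (their C/T state is the
biology being measured, not a conversion readout).

Two QC filters follow standard practice: clones with conversion rate
below 0.95 are removed (strict inequality — a clone at exactly the
threshold is kept), and clones whose full nucleotide sequence is
identical to an earlier clone are flagged as presumed PCR duplicates.
Dedup keys on the sequence, not the call pattern, because two independent
alleles can share a pattern while differing in conversion errors.

No gapped alignment is performed: clones must match the reference length.
The amplicon is fixed and the simulator introduces no indels; a mismatched
base at a CpG becomes a missing call rather than an alignment problem.
Coordinates are 0-based; a CpG site is identified by the C position on the
top strand (the assays target a single amplicon, so only the top strand is
modeled).

The summary is a per-site methylated fraction over non-missing calls and a
sample mean over sites with at least one informative call. Zero retained
clones yields an explicit no-data result (NaN fractions, flagged), never a
silent zero. Dedup is exposed as a switch on the pipeline: in a noise-free
simulation with conversion rate 1, clones drawn from the same epiallele
pattern are bitwise identical, so sequence-keyed dedup would delete real
alleles; exact truth-recovery checks therefore run with dedup off, while
realistic (noisy) runs keep it on.

## MethyLight PMR

MethyLight amplifies only fully methylated bisulfite-converted alleles.
Quantification uses the standard-curve model Ct = b + m·log10(q) with
m ≈ −3.32 per decade at 100% efficiency; the curve is fitted by least
squares to the in-vitro-methylated (IVM) dilution series run with each
reaction. Quantities invert the curve, q = 10^((Ct−b)/m); a censored
reaction (Ct at or above 40 cycles) maps to quantity 0. Replicates are
averaged on the concentration scale, after inversion. The report is

    PMR = ((target_sample / ALU_sample) / (target_IVM / ALU_IVM)) × 100

with the ALU repeat reaction controlling for input DNA. PMR below 1 is
classified as an unmethylated promoter (threshold configurable). PMR is
not capped: values above 100 (sampling noise around a fully methylated
sample) are reported with a warning. A failed ALU control or a failed IVM
reference raises an error instead of producing a spurious 0 or infinity.

Per-target standard curves are the default; a target lacking its own
dilution series borrows the other target's slope, anchored at its highest
standard. Reference concentrations are taken from the measured undiluted
IVM wells, so PMR(IVM vs itself) is exactly 100 and PMR is invariant to
rescaling the input DNA.

## Array beta values and peak-based correction

Beta = M/(M+U) from the methylated/unmethylated intensities; M+U = 0 is a
missing value. Measurements with detection p-value > 0.05 or fewer than 3
beads are masked (strict inequalities: p = 0.05 with 3 beads is kept).

Because Infinium type I and type II chemistries compress the beta scale
differently, each sample is corrected per assay type. The beta density of
all non-missing probes of the stratum — correction is a global
distributional operation, not a promoter-probe operation — is estimated
with an Epanechnikov kernel, K(u) = 0.75(1−u²) on |u| ≤ 1, on a 512-point
grid over [0, 1]. The bandwidth is Silverman's rule rescaled to the
Epanechnikov kernel, h = 2.34·min(sd, IQR/1.34)·n^(−1/5), floored at 0.02
so a tight stratum still yields a usable density. The unmethylated peak is
the highest local density maximum below beta 0.5, the methylated peak the
highest at or above it (boundary configurable; grid endpoints count as
maxima so an already-anchored distribution is recognized). Correction maps
peak_u → 0 and peak_m → 1 linearly and clips to [0, 1]; missing values
stay missing, and within-stratum ordering is preserved. A stratum whose
density has no maximum on one side (not bimodal) is passed through
uncorrected and flagged in the peak report — correction on such data would
be arbitrary.

The corrector is a per-sample normalisation exposed as a fit/transform
estimator: fit() estimates one (peak_u, peak_m) pair per sample per assay
type, transform() applies them. The kernel density is implemented directly
(it is the core primitive of the correction) and is cross-checked in the
test suite against an independent KDE implementation.

## MS-MCA classification

Methylated epialleles retain CpG cytosines after bisulfite conversion and
so melt at a higher temperature than converted, unmethylated epialleles.
Profiles are smoothed with a centred moving average (default 11 grid
points ≈ 2.2 °C at a 0.2 °C step) and differenced to −dF/dT; peaks are
local maxima reaching 20% of the global maximum in both height and
topographic prominence, separated by at least 1 °C, with sub-grid Tm by
parabolic interpolation. The prominence requirement is a deliberate
addition to the height rule: at a few percent fluorescence noise, wiggles
riding on the flank of a genuine peak otherwise qualify as separate local
maxima and corrupt the call.

Classification is relative to two controls carried on each run:
whole-genome-amplified DNA (WGA, fully unmethylated, low Tm) and IVM
(fully methylated, high Tm), matched within a ±1.0 °C tolerance. A single
peak at the WGA (IVM) Tm is unmethylated (methylated); peaks at both are
mixed — the signature of monoallelic methylation; any peak matching
neither control forces the intermediate class, which covers partially
methylated epialleles and heteroduplexes; no peak above threshold is a
no-call (no amplification). The classifier is deterministic and invariant
to uniform fluorescence scaling.

## Integration statistics

RT-qPCR expression is 2^−ΔCt against GAPDH, with target Ct above 35
treated as below the detection limit and set to zero. RNA-seq-style
counts are transformed as log2(count + 1).

Spearman correlation uses average ranks for ties; its p-value is an exact
permutation probability for n ≤ 9 and the t approximation beyond. The
ER-positive/ER-negative comparison uses the unpaired two-sided Wilcoxon
rank-sum (Mann–Whitney) form — the groups are distinct tumors. Its p-value
is computed by exact enumeration of all rank partitions when the pooled
size is at most 12 (ties handled exactly through average ranks), and by
the normal approximation with tie correction and continuity correction
otherwise; both routes are validated against brute-force enumeration and
against an independent library implementation. All values tied across
both groups gives p = 1, flagged.

Per-CpG Pearson correlations against expression use pairwise deletion of
missing betas; sites with fewer than 3 complete pairs are skipped and
logged. The output table carries each site's r and methylation standard
deviation plus one overall expression standard deviation. No
multiple-testing correction is applied across promoter sites by default
(per-site values are conventionally reported raw); a Bonferroni column is
available on request.

ChIP-qPCR enrichment is gated by controls: background is the largest
observed GAPDH (negative control) signal; if the TSH2B positive control
does not exceed background the run is uninterpretable; otherwise the
target is enriched only when strictly above background.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes with recorded
truth. Defaults encode the study conditions the analyses are sized for:
a 273 bp promoter region with 28 CpG sites; 15 clones per sample (the
practical 10–20 range); qPCR slope −3.32 with Ct noise sd 0.2 and
censoring at cycle 40; beta-density modes 0.15/0.85 (type I) and
0.25/0.75 (type II) drawn from Beta-distribution components of
concentration 50; a 599-tumor ER-stratified cohort (460 positive / 139
negative); an expression scale with standard deviation 2.42 on the
log2(count+1) axis; control melting temperatures 78 °C (WGA) and 83 °C
(IVM) with logistic transitions of scale 0.5 °C on a 65–95 °C grid at
0.2 °C steps.

Methylation–expression coupling uses a Gaussian copula on ranks: latent
bivariate-normal variables with Pearson correlation 2·sin(π·ρ/6) yield the
target Spearman ρ between promoter methylation and expression; ER-positive
samples additionally receive an additive promoter beta shift (default
0.3), clipped to [0, 1]. Clone generation supports exact epiallele
proportions (largest-remainder apportionment) so noise-free runs recover
mixture fractions exactly, and retries base-clone draws so seeded PCR
duplicates are the only sequence-identical clones whenever conversion
noise permits.

Deliberate simplifications: no indels or sequencing errors beyond
conversion failure, no PCR amplification bias, no array dye bias or batch
structure, no heteroduplex melt physics (the intermediate class is
exercised by construction, not by thermodynamics), and single-strand
clones. Passing tests therefore establish the correctness of the
computations and their behavior under the modeled noise; they do not
establish robustness to artifacts the generators omit (alignment error,
probe cross-hybridisation, bisulfite degradation).

## Problem sizes and verification

The end-to-end checks run at the cohort shapes above: peak-based
correction on 20 samples × 5,000 probes per assay type (anchored modes
within ±0.03 of 0 and 1 in ≥95% of strata); PMR recovery over 200
independent runs per truth level, each with its own dilution series —
standard-curve noise is shared within a run, so per-run standards (as the
assay prescribes) are what make the mean converge; statistic oracles by
exhaustive enumeration up to pooled n = 10 and 10,000 null replicates for
type-I calibration; a 19-sample methylation–expression panel over 200
seeds (mean pipeline Spearman ≈ −0.65 at truth −0.7, the residual gap
being rank noise from Ct-level error at low PMR); the 599-tumor ER
comparison with 200 background probes per cohort, which keeps 40 null
replicates of the full corrected-beta pipeline fast while leaving the
test statistics unchanged; and 200 melt curves per class at 2% noise
(100% accuracy, zero measurable Tm bias on noise-free curves).
`scripts/acceptance.py` recomputes all of these from scratch under a
single seed.
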