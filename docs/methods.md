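# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions behind `methcompare`.

## The problem

When a cohort's DNAm is measured on successive Illumina array generations
(450K → EPICv1 → EPICv2), three distinct technical questions arise:
which CpGs are even comparable (probe content and design changed), how
reliable each probe is (duplicate agreement and between-person spread),
and how much of an apparent difference between time points is array
rather than biology (per-probe array offsets, missing clock CpGs,
redesigned SNP fingerprints). Each module addresses one of these with a
standard, explicitly stated statistical model.

## Probe harmonization

Probes are joined across arrays on their *base id*: the probe id with one
trailing underscore-delimited token stripped (`cg00000029_BC11` →
`cg00000029`), because the newest generation carries multiple physical
probes per CpG locus. Joins must be on the locus, not the physical probe.
Replicate probes are collapsed by averaging by default (`first` and
`best_detection` policies are available).

The detection filter removes a probe iff the fraction of samples failing
(detection p > 0.01 OR bead count < 3) is **strictly greater** than 0.20;
a probe failing in exactly 20% of samples is retained, reading "more than
20%" strictly.

SNP-probe mismatch detection compares each rs probe's sequence, color
channel and next base on the newest array against the older arrays'
consensus. When the older arrays disagree among themselves, or the probe
is absent from all older arrays, it is reported as *not comparable*
rather than bad — only a clean newest-vs-consensus disagreement sets
`bad_metric`. Only these three attributes are compared; coordinates are
1-based and never lifted over.

## Reliability

ICC(1), the one-way random-effects intraclass correlation, is computed
from the balanced subjects × replicates ANOVA decomposition:

    ICC(1) = (MSB − MSW) / (MSB + (k − 1)·MSW)

Subjects are random, replicates exchangeable (they are unordered
duplicates of the same DNA); two-way models are out of scope. Negative
ICCs are reported unclipped so the empirical ICC distribution is
faithful; the informative rule (ICC > 0.5) is unaffected. The ICC is
undefined (NaN) when MSB + (k−1)·MSW = 0, i.e. a constant probe.
Unbalanced replicate sets are rejected rather than approximated.

IQR is Q3 − Q1 with type-7 (linear-interpolation) quantiles — the common
default, recorded here because conventions differ. Replicate samples are
excluded from the IQR by construction. Betas are used directly (no
M-value transform) because the informative threshold is a beta-scale
quantity (a 1% spread).

A probe is *informative* iff ICC > 0.5 AND IQR > 0.01, both strict.

## Array-level bias

Per probe, a two-factor additive fixed-effects ANOVA `beta ~ array +
donor` is fit; donor is a fixed factor (mirroring R's `aov` semantics for
this formula), not a random effect. In the balanced complete design the
array F statistic uses the residual mean square with (a−1)(n−1) degrees
of freedom; incomplete designs fall back to type-II sums of squares with
a warning (the balanced path is the tested fast path). When the array
sum of squares is at rounding-error level relative to the total, F is
reported as exactly 0 (p = 1) rather than 0/0.

Tukey HSD pairwise differences use the same residual MS:
q = |mean_i − mean_j| / sqrt(MSE/n), with the adjusted p from the
studentized-range distribution with k = a and the ANOVA residual df.
The survival function of the studentized range is evaluated by
fixed-node Gauss–Legendre quadrature of the classical double integral
(120 nodes in the normal dimension over ±9, 100 nodes over the scaled-chi
dimension within ±12 SD of 1), vectorized over q; the test suite checks
agreement with an independent reference implementation to well below
1e-6. "Difference between at least two arrays" is operationalized as
`max_abs_diff`, the largest absolute pairwise Tukey difference.

Benjamini–Hochberg FDR is applied across probes to the ANOVA p-values
(not to the Tukey-adjusted p), implemented as the step-up procedure with
monotonicity enforcement and capped at 1. Summary percentages are
beta × 100 (a difference of 0.01 beta is "1%").

## Sample matching

Genotypes are called from rs-probe betas at thresholds 0.25/0.75 (beta
< 0.25 → 0 copies, > 0.75 → 2, otherwise heterozygote; boundaries call
heterozygote, the conservative choice). Matching uses **call
concordance** — the fraction of co-called shared probes with identical
calls — rather than beta correlation, because call concordance is robust
to array-level intensity shifts, which is the failure mode under study.

For each newest-array sample the older-array sample of maximal
concordance is the candidate match; ties leave the sample unmatched with
a warning, and a match is *accepted* only when its concordance reaches a
minimum threshold (default 0.8), mirroring standard identity-QC
practice. This acceptance threshold is what makes corrupted fingerprints
visible: with 21 of 57 probes carrying no genotype signal, the true
donor's concordance sits near 0.75 and verification fails, while after
excluding the flagged probes it returns to 1.0. The accuracy helper
counts a tie as correct only when every tied candidate is a position of
the true donor (duplicate positions of one donor are consistent, not
ambiguous).

Clustering uses average linkage on distance 1 − concordance over all
samples of all arrays, exported as Newick.

## EWAS concordance

Each probe is fit by plain OLS of beta on the binary trait plus
covariates; the effect is the trait coefficient (Δbeta), with sign
convention mean(group 1) − mean(group 0) and explicit group levels.
Empirical-Bayes variance moderation is deliberately not used: the
subject of this package is the concordance logic, which is unchanged by
moderation at these thresholds; output metadata records the method as
OLS. Probes with zero residual variance get p = 1 when the effect is 0
(no evidence) and the smallest positive float when nonzero (an exact
fit). Collinear designs fail with the offending columns named.

Cross-array overlap is reported at FDR < 0.05 and p < 1e-8 on the
intersection probe set. The denominator for "stable across all arrays"
is the union of probes significant on at least one array, reproducing
the Venn framing; this convention is recorded in the report. Effect
correlation and sign-discordance are computed over the probes passing
the stringent threshold on any array; zero effects cannot flip sign and
are excluded from discordance counting.

## Epigenetic clocks

A clock is `estimate = transform(intercept + Σ wᵢ βᵢ)` with transform
`identity` or `horvath-age` (x < 0 → (1+a)eˣ − 1, else (1+a)x + a,
knot a = 20 years by default, following the original adult-age
convention; configurable).

Missing-weight accounting normalizes the **absolute** coefficient
magnitudes to sum to 100% and reports the share carried by CpGs absent
from the array. Signed weights cannot yield shares that stay in
[0, 100] and sum correctly, so the absolute convention is used and
recorded; the companion number, % missing probes, is convention-free.
Both are invariant to rescaling all weights by a positive constant.

Missing probes are handled by an explicit imputation policy:
`cohort_mean` (default when training means are unavailable — the mean
beta of that probe over the supplied samples; rows absent from the
matrix entirely contribute nothing), `training_mean` (stored means;
required to cover all missing probes), `zero`, or `drop`. With
`training_mean` and every probe missing, the estimate degenerates to
the closed form transform(intercept + Σ wᵢ·imputeᵢ).

Cross-array comparison reports Pearson correlation over shared donors
and the difference score *earlier-generation estimate minus
later-generation estimate*, so a later array that overestimates age
produces negative mean differences.

Published clock coefficient sets are not bundled; the engine reads any
coefficient CSV (`#name/#intercept/#transform/#adult_age` header lines
plus probe_id,weight rows).

## mQTL classification

A SNP–CpG pair is *cis* iff same chromosome, distance strictly < 1 Mb
and p < 1e-8; *trans* iff different chromosome or distance strictly
> 1 Mb and p < 1e-14. A distance of exactly 1 Mb satisfies neither (the
definitions are strict on both sides); such pairs are logged. Distance
is position-to-position, 1-based, strand ignored (array betas are
strand-symmetrized). A CpG's class is the union over its pairs
(cis + trans → both). Malformed rows are skipped with a logged count.
The mQTL database itself is user-supplied, never bundled.

## Synthetic-data generator

The generator emulates the study design the package targets: 30 donors
(15 F / 15 M, ages centered at 5.06 years), three arrays, two donors
duplicated as technical replicates on every array, 57 SNP fingerprints
with 21 corrupted on the newest array, and an 80% three-way CpG overlap
with array-exclusive remainders. All randomness flows from a single
`numpy` generator stream seeded by `SimulationConfig.seed`, so a fixed
seed reproduces the dataset byte for byte.

Per-probe mean methylation follows the bimodal mixture arrays exhibit:
40% Beta(1,10), 40% Beta(10,1), 20% Beta(2,2), with person-to-person
variation as logit-normal jitter (SD 0.5 on the logit scale). Measured
beta is clip(true + array offset + noise, 0, 1). Clipping biases
recovery at extreme probes, so recovery experiments use configurations
whose probe means stay in the interior (an all-intermediate Beta(8,8)
mixture) and tests restrict accordingly.

Array offsets are Gaussian per probe per array with SD 0.015, chosen
once so the median |offset| (0.6745 × SD) is ≈ 0.01 — about a 1% median
between-array shift, a realistic magnitude for between-generation bias;
`fixed_array_offsets` replaces them with per-array constants for
controlled experiments. Technical noise is Gaussian, SD 0.01 by default.

Sex-effect CpGs are drawn from the shared set; their base betas are
squashed into (0.2, 0.7) and the male/female group means are balanced
exactly before the configured Δbeta (default 0.05) is added to females,
so the ground-truth group difference equals the configured effect to
machine precision and no clipping can occur — this is what makes exact
noise-free EWAS recovery a meaningful test.

SNP fingerprints have minor-allele frequencies uniform on (0.2, 0.5),
Hardy–Weinberg genotypes, and expected betas of 0, 0.5, 1 by genotype
copy number. Corrupted probes on the newest array get altered manifest
attributes (a random non-empty subset of sequence/channel/next base)
and betas drawn uniform on (0, 1), independent of genotype — a probe
reading a mixture of wrong signals carries no identity information.

Ages are defined as an exact linear function of ten designated "aging"
CpGs (affinely scaled to mean 5.06, SD 0.5 years), so a toy clock fit by
least squares on any probe superset reproduces ages exactly under the
identity transform; under the nonlinear age transform the fit is a
least-squares approximation whose maximum training residual is stored
on the clock.

What the generator does **not** emulate: IDAT-level signals, dye bias
and type I/II chemistry differences, cell-type heterogeneity,
normalization artifacts, and spatial chip effects. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated generative model, not robustness to every real-data pathology.

## Problem sizes and calibration checks

The test suite and the acceptance script use scaled designs chosen to
make each check statistically decisive: 1,000 probes for Tukey offset
recovery (the mean recovered difference must sit within 3 standard
errors of truth), 8,000 null probes for ANOVA type-I calibration (the
binomial SD of the rejection rate is then 0.24 percentage points, so
the [4%, 6%] band is a ~4-sigma check), 1,000 random balanced instances
for the ICC closed-form-vs-oracle comparison at 1e-10, and 20
independent simulated cohorts for the SNP mismatch/matching experiment.

## Known limitations

- The ICC is ICC(1) only; two-way and mixed-effects variants are not
  provided, and confidence intervals are not computed.
- The unbalanced ANOVA fallback uses type-II sums of squares; REML
  mixed models are out of scope.
- EWAS covariates must be numeric or binary; cell-type proportions are
  accepted as pre-computed columns (no deconvolution).
- Principal-component clocks and proprietary clock internals are out of
  scope; the engine evaluates any linear coefficient set it is given.
- The manifest reader handles the documented eight columns, not
  full-size vendor manifests.
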