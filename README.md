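# methcompare

Cross-generation comparison of Illumina DNA methylation arrays.

Longitudinal and clinical cohorts increasingly carry DNA methylation (DNAm)
measured on different generations of the Illumina BeadChip (450K, EPICv1,
EPICv2). Probe content, probe design and per-probe behavior all change
between generations, so apparent longitudinal change can be technical
artifact. `methcompare` provides the analyses a study needs to separate the
two, for anyone harmonizing beta-value matrices across array versions:

- **Manifest harmonization** — probe-overlap Venn partitions on the CpG
  locus (replicate-probe suffixes stripped), detection-based probe
  filtering (removal when detection p > 0.01 or bead count < 3 in strictly
  more than 20% of samples), and collapsing of duplicated probes.
- **SNP-fingerprint QC** — detection of SNP (rs) probes whose probe
  sequence, color channel or next base changed on the newest array, and
  genotype-concordance sample matching that shows why such probes must be
  excluded before cross-array identity checks.
- **Per-probe reliability** — one-way random-effects intraclass
  correlation from technical replicates,
  ICC(1) = (MSB − MSW) / (MSB + (k−1)·MSW), between-person variability as
  the type-7 interquartile range, and the joint *informative* criterion
  (ICC > 0.5 and IQR > 0.01).
- **Array-level bias** — per-CpG repeated-measures ANOVA
  (beta ~ array + donor), Tukey HSD pairwise mean differences via the
  studentized-range distribution, and Benjamini–Hochberg FDR across
  probes.
- **EWAS concordance** — per-array OLS of beta on a binary trait plus
  covariates (Δbeta effect scale), with cross-array overlap at FDR and
  stringent-p thresholds, effect-estimate correlation, and
  sign-discordance counting.
- **Epigenetic clocks** — a generic linear clock engine
  (estimate = transform(intercept + Σ wᵢ·βᵢ), including the piecewise
  exponential/linear age transform), with *missing-weight accounting*: the
  percentage of a clock's CpGs, and of its absolute coefficient mass,
  absent from a given array.
- **Synthetic data** — a generator emulating 30 donors measured on three
  array generations with shared technical replicates, per-probe array
  offsets, sex-effect CpGs, 57 SNP fingerprints (21 corrupted on the
  newest array) and toy clocks, providing exact ground truth for every
  stage.

## Worked example

```python
import methcompare as mc
from methcompare.pipeline import _primary_beta
from methcompare.array_bias import array_bias_table, summarize_bias

ds = mc.generate_dataset(mc.SimulationConfig(n_cpg=1000, seed=11))

report = mc.detect_snp_mismatches(ds.manifests)
print("flagged SNP probes:", int(report["bad_metric"].sum()), "of", len(report))

betas = {a: _primary_beta(ds, a) for a in ds.betas}
tab = array_bias_table(betas, ds.samples, probes=ds.truth.shared_probes)
s = summarize_bias(tab)
print("probes with array bias at FDR<0.05: %d of %d (%.1f%%)"
      % (s["n_significant"], s["n_probes"], s["pct_significant"]))
print("median |between-array difference|: %.2f%%" % s["median_pct_diff"])

rel = mc.reliability_table(ds.betas["450K"], ds.samples["450K"])
print("informative probes on 450K:", int(rel["informative"].sum()), "of", len(rel))
```

prints

```
flagged SNP probes: 21 of 57
probes with array bias at FDR<0.05: 759 of 800 (94.9%)
median |between-array difference|: 2.36%
informative probes on 450K: 640 of 924
```

The 21 flagged fingerprints are exactly the probes the generator corrupted
on the newest array. Of the 800 CpGs shared by all three simulated arrays,
94.9% show a detectable array effect under the default offset scale
(Gaussian per-probe offsets, SD 0.015 beta units), and the median largest
pairwise between-array difference is 2.36 percentage points of
methylation. The informative count combines replicate agreement
(ICC > 0.5) with measurable between-person spread (IQR > 0.01).

A thin CLI mirrors the library (`methcompare simulate | annotate |
reliability | bias | match | ewas | concord | clock | clock-compare |
mqtl | report | run`); `methcompare run --config pipeline.yaml` executes
the configured stages end to end.

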