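# Methods

## The exon-skipping index

A short-oligo expression probeset whose probes tile several consecutive
exons can detect exon-specific loss of signal without exon arrays or
RNA-seq.  For a probeset with probes on a *target* exon (here CD22 exon 12;
probes `_5`, `_6`, `_7` of 217422_s_at) and on *flanking* exons (exons
10–11 and 13–14; seven probes), the per-sample index is

```
index(s) = mean_{p in target} c_p(s) − mean_{p in flanking} c_p(s)
c_p(s)   = log2 x_p(s) − median_{p' in probeset} log2 x_{p'}(s)
```

where `x_p(s)` is the normalized probe-level intensity.  The per-sample
median centering absorbs any per-array additive (log-scale) effect, so the
index is exactly invariant to per-sample shifts; because the same median is
subtracted from both groups, the index equals the difference of the
uncentered group means.  Probes that belong to the probeset but have no
exon assignment participate in the centering only.  A transcript lacking
the target exon loses signal only on the target-exon probes, driving the
index negative.

Group aggregation of the centered probe values uses the arithmetic mean
(the median is available via `aggregator="median"`).

## Normalization stack

Probe intensities are modelled as `X = B + S` with background
`B ~ Normal(mu, sigma^2)` and signal `S ~ Exponential(alpha)` (means in raw
intensity units).  Per array:

1. **Norm-exp fit** — maximum likelihood in `(mu, log sigma, log alpha)`
   by L-BFGS-B with moment starting values (`2 alpha^3` is the third
   central moment of the convolution); method-of-moments fallback if the
   optimizer fails.  Needs ≥ 10 finite values and a non-constant column.
2. **Correction** — each value is replaced by the posterior mean
   `E[S | X = x]`, computed stably through `log Φ`; output is strictly
   positive and monotone in `x`.
3. **Quantile normalization** — the target distribution is the row mean of
   the column-sorted matrix; every column is mapped onto it, ties receiving
   the average of the target values over their rank span.  Single-column
   input is returned unchanged; the operation is idempotent.
4. **log2**, then optional **median-polish summarization** per probeset
   (Tukey sweeps, max 50 iterations, convergence when the change in the sum
   of absolute residuals drops below `1e-10 × size`; non-convergence —
   typically rank-cycling on even-sized matrices — returns the last iterate
   with a warning).  The index consumes the *unsummarized* probe-level
   values; both outputs are exposed.

Two arrays differing only by a multiplicative scale factor produce
identical ranks after this stack, and identical values *up to the shared
quantile target*, which is itself estimated from the data: bulk log2 values
agree to a few hundredths, the near-zero tail more loosely.  Exact
value-level invariance is not attainable when the target is data-driven.

## Incidence calling

The reference interval is the t-based confidence interval of the
reference-group mean, `mean ± t_{(1+γ)/2, n−1}·SE` (γ = 0.95 by default).
Published cohort summaries quote `mean ± SE`, and the pediatric interval
0.394–0.655 matches `0.52 ± 1.96·0.07`, which is why the ± values are read
as standard errors and the interval as a CI on the mean rather than a
tolerance interval.  A case sample is called positive when its index falls
*strictly below* the lower bound.  Incidence is reported with a
Clopper–Pearson exact binomial CI; samples with an undefined index are
excluded and counted.

Group location is tested with one-way ANOVA; many-to-one comparisons use
Dunnett's method with the family-wise adjusted P estimated by Monte Carlo:
group means are drawn as independent normals scaled by `1/sqrt(n_i)` and
the pooled variance as `chi2(df)/df`, giving the equicorrelated
multivariate-t law of the max-|t| statistic.  The MC standard error
`sqrt(p(1−p)/n_mc)` is reported; requests below `n_mc = 1000` are refused,
and the default `1e5` gives SE ≤ 0.0016.  With two groups the adjusted P
reduces to the pooled two-sample t-test P.

## Signature statistics

Cross-cohort signature scoring mean-centers log2 expression to the
reference samples, then fits the two-factor mixed model

```
value ~ probeset * group + (1 | sample)
```

restricted to the balanced case (every sample measured on every probeset,
each sample in one group).  In the cell-means parameterization the GLS
fixed-effect estimates equal the per-cell sample means for **every** value
of the variance ratio `lambda = sigma2_sample / sigma2_resid` — the
estimator `(X'V⁻¹X)⁻¹X'V⁻¹y` collapses to the cell averages because
`V⁻¹` acts block-wise per sample and each sample loads every probeset cell
of its own group equally.  REML therefore reduces to a one-dimensional
profile,

```
−2·REML(λ) = (n−p)·log(SSR − c·Q) + (S−G)·log(1 + λP) + const,
c = λ/(1+λP),
```

with `SSR` the within-cell residual sum of squares, `Q` the sum of squared
per-sample residual totals, `S` samples, `G` groups, `P` probesets,
optimized over `log λ` (bounded scalar minimization; the λ = 0 boundary is
checked explicitly).  The fit matches a general REML mixed-model
implementation to the displayed precision on test instances.

LS-mean SEs use `sqrt((sigma2_resid + sigma2_sample)/n_g)`; the group
effect F uses the whole-plot variance `(sigma2_resid + P·sigma2_sample)/P`
with the between-sample denominator degrees of freedom `S − G` (e.g.
`F(1, 148)` for 76 + 74 samples), the standard choice for a between-sample
factor in this design.  Per-probeset contrasts report `2^(LS-mean
difference)` as the linear fold with the same denominator df — a
conservative choice; a between-group cell difference mixes whole-plot and
residual error, and Satterthwaite blending is not attempted.  Contrast
P-values are not multiplicity-adjusted by default (raw `P < 0.05` is the
filter); Benjamini–Hochberg adjustment is available.

Correlation tests report Pearson r with `F = r²(n−2)/(1−r²)` on
`(1, n−2)` df, the regression-ANOVA identity.

## Antibody-array pipeline

Per array: mean blank subtraction (clipped at a configurable strictly
positive floor, default 1 intensity unit, since the platform leaves the
handling of non-positive differences unspecified), replicate-spot
averaging per antibody, division by the array median over all antibodies
(so the per-array median of normalized values is exactly 1), log10.
Differential testing uses Welch's t with Satterthwaite df; hits must pass
both `P < 0.02` and linear fold `> 1.1`, the fold being
`max(ratio, 1/ratio)` of the unlogged normalized group means.  The naive
FDR estimate is `100·m·alpha/k` percent, truncated to an integer and
capped at 100 (with 1318 tests, alpha 0.02 and 142 hits this prints 18%
from a raw 18.56%); the raw value is always retained.

## Synthetic cohorts

The probe-level generator draws
`I(p,s) = scale_s · [Normal(mu_b, sigma_b²) + Exp(mean = theta·phi_p·a(p,s))]`
with `a(p,s) = 1 − psi_s` on target-exon probes and 1 elsewhere, clipped at
zero; skipping attenuates the exponential signal mean only, never the
background, which is probe-sequence independent.  Independent child RNG
streams are spawned per component (psi, background, signal) so adding a
stage never perturbs another stage's draws; identical specs give identical
datasets.

**Calibrated preset** (`default_cohort_spec`): the chip carries the ten
aligned CD22 probes plus one unaligned eleventh probeset member (the
centering runs over 11 probes) and 40 background probesets of ten probes
with log-normal affinities; `mu_b = 100`, `sigma_b = 10`, `theta = 1000`.
On the log2 scale the expected index of a sample with skipping fraction psi
is `mean(log2 phi_target) − mean(log2 phi_flank) + log2(1−psi)`, so target
affinities of `2^0.52` (flanking 1) put the no-skipping reference mean at
0.52 and a case psi of `1 − 2^(−0.67) = 0.372` (Beta, concentration 200)
puts the case mean at −0.15 — the published group means.  A large-sample
run through the full stack confirms the calibration (0.54 / −0.14 at 1500
samples per group).  Default cohort sizes are the published 74 reference /
279 case.

The generator's per-sample index spread is dominated by the exponential
probe noise: `sd(log2 Exp) = sqrt(pi²/6)/ln 2 ≈ 1.85`, giving an index SD
of `1.85·sqrt(1/3 + 1/7) ≈ 1.28` — considerably wider than the published
cohorts' sample-level spread (0.60 / 0.50).  Consequently the
*mechanistic* cohort understates the published incidence (≈ 56% of cases
below the reference CI), and separation at `psi = 0.7` tops out near AUC
0.84 (0.91 at `psi = 0.8`); real arrays average many more effective
measurements per exon than three probes.  The published 87% figure is
therefore reproduced from the *summary-calibrated* generator
(`simulate_index_cohort`), which draws group values as
`Normal(mean, (SE·sqrt(n))²)` directly from the published means and SEs:
74 reference at 0.52 ± 0.07 and 279 cases at −0.15 ± 0.03 yield 85–86%
below the reference lower CI over 250 replicates, within the printed 87%
to the tolerance such a stochastic summary supports.  Cohort normality is
an assumption of this calibration, not a claim about the source data.

The antibody-array generator emulates duplicate spots, 4 blanks, 4
negative controls and 2 positive markers per array over 1318 antibodies,
per-array scale factors (log10-normal, sd 0.1) and log10-normal spot
noise; injected group effects are exact on noiseless data, so pipeline
inversion recovers them to machine precision.

What the synthetic cohorts do **not** model: scanner/spatial artifacts,
probe-sequence (GC) effects, cross-hybridization, correlated probe noise,
batch structure across merged studies, and any non-normal shape of the
case index distribution.  Passing tests demonstrate the statistics are
computed correctly under the stated noise model, not that the biological
conclusions transfer to any particular real dataset.

## Sequence arithmetic

cDNA coordinates are 1-based inclusive with c.1 at the A of the start
codon, so codon `k` spans `c.(3k−2)…c.(3k)` and the codon containing a
deletion start `d` is `ceil(d/3)` — removing exon 12 (c.2208–c.2327, 120
bases, not a multiple of 3) shifts the frame from residue 736.  The
arithmetic mutant P7 product is 182 − 120 = 62 bp; the published gel
legend says 63 bp, a one-base discrepancy the package surfaces rather than
hides (`PRINTED_MUTANT_P7_PRODUCT_BP`).

siRNA design: the sense strand is the RNA transliteration of the 19-mer
DNA target, the antisense strand that of its reverse complement; both get
phosphorothioate marks (`*`) on the first and last three linkages of the
19-nt core and a DNA `TT` 3' overhang.  Duplex molecular weight is not
computed: the mass convention (free acid vs salt, 5'-OH vs phosphate) of
the published figure is unstated.

## Numerical conventions and edge cases

- Zero-variance reference group → degenerate interval `(mean, mean)` with
  a warning; zero-variance Welch inputs → P = 1 (equal means) or a flagged
  P → 0; one-way ANOVA with zero within-group variance and equal means →
  F undefined, flagged.
- Norm-exp correction output is floored at `1e-10` so the log2 stage is
  always defined; with `sigma = 0` the correction is `max(x − mu, floor)`.
- Quantile normalization refuses missing values; upstream policy drops a
  feature missing in most samples before normalization.
- All stochastic stages take explicit seeds; the end-to-end pipeline is
  byte-deterministic under a fixed configuration.

## Problem sizes used by the shipped analyses

The analysis scripts simulate at the published design sizes (74/279
samples, 411 probes, 1318 antibodies × 8 arrays, 25 probesets × 150
samples); verification tests use smaller cohorts (120–400 samples per
group) chosen so that Monte-Carlo standard errors are small against the
tolerances being asserted.
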