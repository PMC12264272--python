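# Methods

## Scoring model

Expression is a genes × samples matrix on any monotone normalized scale;
log2(TPM+1) is recommended because the combined score takes a median
*across* genes and therefore mixes gene magnitudes. For a risk-up gene
with cohort minimum `min` and maximum `max`, the reflection

    reflected(x) = min + (max − min)(max − x)/(max − min) = min + max − x

maps min↔max and exactly reverses the ranking. When `max = min` the
printed form is 0/0; we use the algebraic simplification `min + max − x`,
whose continuous limit returns a constant gene unchanged. Reflection is
an involution and the combined score is equivariant under adding a
constant to the whole matrix; it is *not* invariant to per-gene
rescaling (the median mixes gene scales — hence the log-scale
recommendation).

The combined RESIST-M score of a sample is the median of its two
reflected risk-up genes and seven untransformed protective genes; its
polarity is therefore "lower = higher risk" and is carried on the
`ScoreVector` rather than silently flipped. Single-arm and comparator
scores are plain means ("higher = higher expression"). Median-split
status uses the cohort median of the score as threshold with the
strictly-above rule ("high" iff score > median), so with distinct scores
a cohort of n samples splits ⌊n/2⌋ high / ⌈n/2⌉ low; an all-constant
score vector degenerates to all-low with a warning. `assign_risk`
resolves polarity into a 1 = higher-risk group: the at-or-below-median
half for reflected-median scores, the above-median half for mean scores.
Missing signature genes warn and score on the intersection by default
(the seven-of-twelve RCC usage is precedent for subsetting); a strict
mode raises instead.

## Survival analysis

Kaplan–Meier estimation and the unweighted Mantel–Haenszel log-rank test
are computed with lifelines; KM confidence intervals are Greenwood
intervals on the log(−log S) scale (lifelines' exponential-Greenwood
formula, the "log-log" interval type). The Cox model for the binary
status covariate is fit in-package by Newton–Raphson on the partial
likelihood with **Breslow** tie handling (Efron is a possible
extension); for a scalar binary covariate the score and information have
closed forms per distinct event time, and iteration runs to
|score| < 1e−8 or 50 steps. Subjects censored exactly at an event time
remain in that time's risk set. Monotone likelihoods (e.g. all events in
one group) are reported via `converged=False` with the last bounded
estimate instead of a spurious finite HR. Wald 95% intervals and p-values
are reported; p < 0.05 is the significance convention throughout.

## Subtype comparisons and enrichment

Score differences between CMS classes use the two-sided Wilcoxon
rank-sum test: exact by enumeration when both groups have ≤ 12
observations without ties, otherwise the normal approximation with
midrank tie correction and continuity correction (the method used is
recorded). CMS4 is compared with each other subtype and with the pooled
rest; raw p-values are primary and Benjamini–Hochberg adjusted values
are always included. The heatmap table z-scores each signature-gene row
(n−1 denominator; constant rows become zeros with a warning) in fixed
block order (RESIST-M, Lin, Yin, RCC7, RPS) and sorts columns by
(CMS, iCMS, fibrosis, combined score), with CMS1 < CMS2 < CMS3 < CMS4
as the display order.

Enrichment of the risk-high group in a target subtype (default
predicate: CMS4 ∧ fibrotic) is a Fisher exact test on the 2×2 table with
the sample (cross-product) odds ratio, using the infinity convention for
zero cells. This test is a quantitative formalization of an association
that is conventionally shown only as a heatmap annotation; it is an
extension of this package, not a re-implementation of a published test.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume,
not any real cohort. Expression is simulated directly in log2 space
(shifts are additive and scoring is monotone-equivalent): gene baselines
`mu_g ~ Normal(baseline_mean, baseline_sd)` drawn once per gene,
i.i.d. Normal(0, noise_sd) noise per cell, and additive shifts in the
latent risk samples (+m1_shift on RESIST-M1 genes, −m2_shift on
RESIST-M2 genes, optional stromal-up/cell-cycle-down comparator shifts).
Survival is exponential proportional hazards — hazard
`baseline_hazard · planted_hr^risk` — with independent exponential
censoring; the observed time is the minimum of the two clocks. One
seeded generator is threaded through a fixed draw order (gene means →
labels → expression noise → survival → censoring), so equal seeds give
bit-identical cohorts.

Defaults are fixed study conditions: n = 400 samples (the scale of
public CRC cohorts with CMS annotations), CMS proportions
{CMS1 0.15, CMS2 0.35, CMS3 0.15, CMS4 0.25, unlabeled 0.10} with 80% of
CMS4 fibrotic (risk stratum = CMS4 ∧ fibrotic ≈ 20% of the cohort),
shifts of 2 log2 units against unit noise SD, baseline hazard
0.02/month with censoring rate 0.015/month (≈ 57% event fraction), and
planted HR 2.5. 200 filler genes follow the baseline law with no planted
effect. iCMS and MSI labels are a deterministic map from CMS
(CMS1 → iCMS3/MSI, CMS2/3 → iCMS2/MSS, CMS4 → iCMS3/MSS) — a
simplification; real cohorts have a noisier joint distribution. Not
modeled at all: count-level (negative-binomial) noise, gene–gene
correlation, batch effects, and label misclassification. Passing tests
therefore demonstrate correctness of the statistical machinery under a
clean generative model, not robustness to the full messiness of real
cohort data.

## Calibration experiments and problem sizes

The replicated studies in `resistm.experiments` use these designs:

* **Type-I error** — 500 null cohorts (no shifts, planted HR 1, n=200);
  the median-split log-rank rejection rate at α=0.05 is ≈ 0.05–0.06.
* **HR recovery** — 500 cohorts, n=500, planted HR 2.5, with a
  *balanced* risk stratum (CMS4 proportion 0.5, all fibrotic). The
  balance is essential: a forced 50/50 median split can only align with
  a latent stratum that is about half the cohort. With a 20% stratum
  the split's group-level hazard ratio is attenuated to ≈ 1.5 by
  construction — visible in the demo run — and no estimator could
  recover 2.5 through it. The mean stratified HR is ≈ 2.3 (residual
  attenuation from boundary misclassification); Cox fits on the latent
  truth groups average ≈ 2.51.
* **CI coverage** — coverage is a property of the Cox estimator, so it
  is evaluated on the latent truth groups (two-group exponential data),
  where 95% Wald intervals cover the planted log-HR ≈ 94–95% of the
  time. Through the median split the estimand is the attenuated group
  log-HR, so coverage of the *planted* value is structurally below
  nominal there.
* **Enrichment** — 50 planted cohorts (default generator) for the
  detection rate of OR > 5 with p < 1e−6 (≈ 1.0), and 200 null cohorts
  for the median odds ratio (≈ 1.0).

Replicate counts were chosen to make the binomial uncertainty of each
estimated rate small relative to its test band while keeping the full
suite fast on a single CPU; every replicate derives its seed
deterministically from the experiment's base seed.

## Design choices on open points

* **Polarity of the combined score**: reflecting the M1 arm makes *low*
  combined scores mark the M1-high/M2-low poor-prognosis phenotype.
  Which arm of a published KM pair is "high" is convention-dependent, so
  the polarity is recorded on every `ScoreVector` and `assign_risk` is
  the single place it is resolved.
* **Tie at the median**: strictly-greater ⇒ high, the one rule stated
  for mean scores, applied uniformly.
* **min/max scope**: per gene over the cohort being scored; scores are
  cohort-relative and not transferable across cohorts.
* **RCC7 direction split**: stromal genes and GADD45B risk-up,
  cell-cycle genes down, an interpretive reading of the recurrence-score
  phenotype; the undirected 7-gene mean is what the stratification
  drivers use for the comparator, matching how such scores are usually
  summarized.
* **Gene identifiers** are plain symbols; no cross-annotation mapping
  layer is provided.

## Known limitations

Cox fitting is limited to a single binary covariate (multivariable and
continuous-covariate models, time-varying effects and competing risks
are out of scope); relapse-free survival is handled by relabeling the
endpoint, with no RFS-specific modeling; the generator's independence
assumptions understate real-data correlation, so power estimates from it
are optimistic; scores are not calibrated across cohorts.
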