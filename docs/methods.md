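# Methods

`mirprog` implements the computational core of a miRNA prognostication
analysis in breast cancer: per-sample normalization of spotted miRNA
arrays, supervised differential expression, sign-weighted gene-signature
scoring with a genomic-grade cutoff, survival evaluation of a candidate
marker, permutation gene-set enrichment, and unsupervised clustering.
This note records the models, the conventions chosen where more than one
reading was defensible, and what the synthetic cohorts do and do not
emulate.

## Array normalization

The platform prints each probe on replicate spots together with empty
(negative-control) spots. Per hybridization:

1. **Spot summary.** Intensity = mean signal − local background, clamped
   at 0 (a negative net signal carries no information and would break the
   log step), then averaged over a probe's replicate spots. Empty spots
   are averaged separately.
2. **Thresholding.** The detection threshold is τ = 2 × (mean empty-spot
   signal); intensities below τ are set to the floor 1. The empty-spot
   signal is background-subtracted before the multiplication (the
   alternative — raw empty signal — is not exposed because the clamp
   makes the two nearly identical on realistic arrays).
3. **Rank scaling.** Every post-threshold intensity is divided by the
   sample's 30th **largest** post-threshold intensity. Counting from the
   top makes the calibration depend on the bright, reliably measured
   spots and is invariant to array size; counting from the bottom is
   selectable (`rank_from_top=False`) but not the default. Ties at the
   rank do not affect the divisor value. The probe holding the divisor
   maps to log2 value 0.
4. **log2 transform.**

Detection (`value ≥ τ` before flooring) is recorded per spot and drives
the ≥90% ("detected") and ≥20% ("expressed") filters, so the biological
detection call is independent of the floored sentinel value.

**A note on scale equivariance.** Multiplying all intensities of a
sample (and its empty spots) by c > 0 leaves every *detected* entry of
the normalized vector unchanged. Floored entries do move: the floor is
the absolute constant 1, so a floored entry maps to −log2(divisor),
which scales with c. This is inherent to the procedure, not an
implementation artifact; floored values are sentinels, and every
downstream analysis either uses detected entries or treats floored
values as "absent".

## qPCR quantification

Relative abundance is 2^−ΔCt with ΔCt = mean(target triplicate Ct) −
mean of the two reference assays' mean Cts (RNU44 and RNU48, equal
weight; the combination is not dictated by the ΔCt method itself).
Group fold changes on the qPCR scale are ratios of group summaries; the
summary (mean or median) is configurable and recorded, defaulting to the
mean. No amplification-efficiency correction is applied.

## Differential expression

Two-class comparisons use the pooled-variance Student t test on log2
values, two-tailed, with Welch available as an option. Fold changes for
result tables are ratios of **group medians of linear normalized
intensities** — the only convention consistent with printing both group
medians and their ratio in one row. Gene-level fold-change calls
(mRNA-style "FC > 2" lists) use ratios of class means on the linear
scale with a strict inequality. BH FDR is the step-up adjustment
computed over the features passing the 20% expression filter (the tested
family); significance gating in the pipeline is at nominal p < 0.05 with
FDR reported alongside. Three-level comparisons use classical one-way
ANOVA.

## Signature scores and risk groups

A signature is a gene list with weights w_i ∈ {+1, −1} (only the sign of
any supplied weight is used). The score of a sample is the sign-weighted
**mean** of the log2 expression of the signature genes present on the
platform; genes absent from the platform are skipped and counted. The
mean (rather than the raw sum) makes scores comparable across platforms
with different coverage; since robust scaling follows, the choice is
inconsequential downstream, and the unnormalized sum is available.

Robust scaling maps scores to median 0 and IQR 1 within a dataset
(quartiles by linear interpolation of order statistics — the convention
matters for small cohorts and is fixed here). The genomic-grade cutoff
is the midpoint between the mean scores of histological grade 1 and
grade 3 tumors; samples above it are genomic-grade High. The
classification is invariant to affine transforms of the scores, so it
does not matter whether raw or scaled scores are thresholded; both are
emitted.

Risk groups come from a median split: values strictly above the median
are high-risk (ties go low). The cutoff is exported in a checksummed
JSON sidecar and reused unchanged on validation cohorts to avoid
refitting optimism.

## Survival analysis

Follow-up is administratively censored at 10 years. Kaplan–Meier curves
are product-limit estimates (lifelines). Cox proportional-hazards models
are fit by partial likelihood with Efron tie handling, reporting β,
HR = exp(β), Wald 95% CIs and p-values; markers can be standardized to
unit variance so hazard ratios of different signatures are comparable.

The time-dependent ROC at horizon t is the cumulative-case /
dynamic-control estimator of Heagerty, Lumley and Pepe: cases are
subjects with events by t, controls those event-free past t, and for
each marker cutoff c

    sens(c, t) = [1 − S(t | X > c)] · P(X > c) / [1 − S(t)]
    spec(c, t) = S(t | X ≤ c) · P(X ≤ c) / S(t)

with stratum survival S(· | ·) estimated by Kaplan–Meier. The curve is
swept in descending-cutoff order; because the KM-based estimator is not
guaranteed monotone under censoring, a running maximum enforces a
non-decreasing curve before trapezoidal integration (a no-op without
censoring, where the estimator reduces to the empirical ROC and the AUC
equals pairwise concordance). The nearest-neighbour-smoothed variant is
out of scope.

Marker comparison ("which variable predicts survival better?") is a
subject-level bootstrap: each resample yields a paired standardized
log-HR and tdROC AUC per marker, and marker pairs are contrasted with a
paired Student t test across resamples. Resamples with no events before
the horizon are redrawn and counted. This is an explicit interpretation
of "comparing hazard ratios by a paired t test", which does not define
what constitutes a pair; the output metadata records the construction.

## Enrichment

Genes are ranked by the two-class t statistic (descending; the ranking
statistic is configurable). The enrichment score of a gene set is the
maximum of the classic unweighted KS running sum: +√((N−G)/G) at set
members, −√(G/(N−G)) elsewhere (N list length, G overlap), so the walk
ends exactly at 0. ES is the signed maximum, matching the one-sided
question (targets concentrated at the top). The null distribution comes
from permuting class labels and re-ranking each time — not from
shuffling ranks — and p = (1 + #{ES_perm ≥ ES_obs}) / (1 + n_perm).
When the number of distinct label assignments is at most n_perm, all
assignments are enumerated and the p-value is the exact fraction (the
observed assignment is part of the enumeration, so p > 0 without the
add-one term).

The LS test scores a gene category by the mean of −ln(p) over member
genes (expectation 1 under uniform null p-values, since −ln U ~ Exp(1))
against random same-size categories drawn from the tested universe,
with the add-one convention.

## Clustering

Sample (or feature) profiles are compared by uncentered correlation —
cosine similarity without mean-centering — and agglomerated with average
linkage (UPGMA) on dissimilarity 1 − r. The implementation uses scipy's
linkage; a brute-force O(n³) agglomeration oracle in the test suite
verifies merge heights. Ties in merge order are broken by lowest node
index (deterministic; ties have measure zero on continuous data).
Partitions from cutting the tree at k groups are compared with the
adjusted Rand index, which quantifies the qualitative
"poor concordance" question between miRNA- and mRNA-based groupings.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
matching the targeted study design:

| parameter | default | rationale |
|---|---|---|
| n_samples | 73 | discovery cohort size |
| n_mirnas / n_expressed | 328 / 108 | probes on the array / typically detected |
| n_replicates_per_spot | 2 | duplicate spotting |
| baseline_log2_mean / sd | 8.0 / 1.25 | clearly-expressed probes vs background; within-sample biological + technical spread typical of arrays |
| feature_mean_spread | 0.75 | per-probe abundance differences |
| background_mean / sd | 60 / 10 | scanner counts of local background |
| empty_signal_mean | 4.0 | net empty-spot signal (exponential); sets τ ≈ 8 |
| group_fold_change | 3.43 | planted marker effect between genomic-grade groups |
| group_fraction_high | 0.49 | observed genomic-grade balance |
| baseline_hazard | 0.04 /y | ~30 relapses in 73 patients within 10 y |
| log_hazard_ratio | ln 4.43 | planted group effect on relapse hazard |
| censoring_rate | 0.075 /y | exponential censoring, ~9 y median follow-up |

Spot intensities are log-normal (2^N(μ, σ)) over an additive Gaussian
local background; unexpressed probes and empty spots carry
exponentially distributed net signal only. The prognostic probe's log2
mean is shifted by log2(FC) in the planted high group, so its linear
mean and median differ between groups by exactly FC in expectation.
Survival is exponential with hazard h₀·exp(β·g) for group g, censored
by an independent exponential capped at the follow-up horizon.
Histological grade is drawn conditionally on the group so grade-2
tumors are a genuine mixture of the two latent classes. Everything is
driven by one integer seed, bit-for-bit reproducibly.

qPCR readings are triplicates with Ct = intercept − slope·log2(expr) +
noise and constant-expectation reference assays — a deliberately clean
linear model; it emulates assay concordance, not amplification
chemistry.

**What the generator does not emulate:** probe sequences and
cross-hybridization, spatial array artifacts, inter-array batch
effects, non-proportional hazards, informative censoring, and
correlation structure between miRNAs. Passing tests therefore establish
the correctness and calibration of the estimators under the assumed
generative model, not robustness to those real-data complications.

**Power at the planted regime.** With within-group log2 SD 1.25 and a
planted fold change of 3.43, a median split of the *measured* marker
misclassifies roughly a quarter of samples, attenuating the planted
group hazard ratio of 4.43 to an observed split HR near 2 and leaving
limited power at 73 patients (~30 events). The analysis scripts report
this honestly; parameter-recovery checks use larger n, and the
end-to-end pipeline check plants a stronger (6-fold) marker so the test
exercises signal propagation rather than statistical power.

## Numerical choices and degenerate inputs

- Zero pooled variance in a t test → t = 0, p = 1 with a `degenerate`
  flag (and mean-difference fallback inside the enrichment ranking).
- Zero IQR, constant covariates, zero-norm profiles, empty overlaps and
  missing grade-1/3 strata are rejected with explicit errors rather
  than silently propagated.
- The scaling divisor equal to the floor value triggers a warning and is
  used as-is.
- Permutation p-values use the add-one convention (sampled null) or the
  exact fraction (exhaustive null); seeds and n_perm are recorded in
  every result object.
- Problem sizes in the test and acceptance suites (e.g. 2000 subjects ×
  100–400 replicates for Cox recovery/coverage, 200 runs × 199
  permutations for enrichment calibration) were chosen so Monte-Carlo
  error is small relative to the property being checked.

## Known limitations

- The bootstrap interpretation of the paired marker comparison is one of
  several defensible constructions; its p-values should be read as
  descriptive.
- The KM-based tdROC estimator can exceed [0, 1] under heavy censoring
  before clipping; the monotone correction makes the reported AUC
  slightly conservative-to-optimistic depending on the direction of the
  violations.
- FDR values depend on the size of the tested family; the pipeline
  defines the family as the ≥20%-expressed features, which is a choice,
  not a universal convention.
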