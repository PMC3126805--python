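# mirprog

Prognostic evaluation of miRNA expression in breast cancer cohorts:
bespoke miRNA-array normalization, differential expression with median
fold changes, sign-weighted gene-signature scoring, survival analysis
with median-split risk groups and time-dependent ROC, and
permutation-based target-set enrichment — all exercisable end to end on
synthetic cohorts.

## The problem

Histological grade separates indolent (grade 1) from aggressive
(grade 3) breast tumors, but the large grade-2 group is clinically
ambiguous. A sign-weighted gene-expression score (the genomic grade
index) resolves that ambiguity, and individual miRNAs — miR-210 in
particular — track the same axis and carry prognostic information of
their own. Evaluating such a marker requires a chain of specialised
steps, each with conventions that matter:

- **Array normalization.** Spotted miRNA arrays are normalized per
  sample: spot signal = mean − local background (clamped at 0),
  replicate spots averaged, intensities below 2× the empty-spot signal
  floored to 1, everything divided by the sample's 30th-largest
  intensity, then log2. Detection calls (pre-flooring) drive the ≥90%
  "detected" and ≥20% "expressed" filters.
- **Differential expression.** Pooled-variance t tests on log2 values;
  fold changes reported as ratios of group medians on the linear scale;
  Benjamini–Hochberg FDR.
- **Signature scores.** S = (1/n) Σᵢ wᵢ·xᵢ with wᵢ ∈ {+1, −1} over
  platform-present genes, robust-scaled to median 0 / IQR 1; the
  genomic-grade cutoff is the midpoint between mean scores of
  histological grades 1 and 3.
- **Survival.** Kaplan–Meier, Cox proportional hazards (Efron ties),
  10-year censoring, median-split risk groups whose cutoff transfers
  unchanged to validation cohorts, and the cumulative/dynamic
  time-dependent ROC of Heagerty–Lumley–Pepe.
- **Enrichment.** Classic (unweighted) KS running-sum enrichment score
  of a target-gene set over a t-statistic ranking, with significance
  from label permutations re-ranked each time; LS permutation tests for
  gene categories.

`docs/methods.md` documents each model, its assumptions and the
conventions adopted where the procedure is underspecified.

## Worked example

The analysis is organised as numbered scripts over the library:

```
python analysis/01_simulate_cohorts.py      # synthetic discovery + validation cohorts
python analysis/02_discovery_analysis.py    # normalize, filter, DE, survival screen
python analysis/03_validation_analysis.py   # training cutoff applied to cohort 2
python analysis/04_qpcr_concordance.py      # 2^-dCt vs array concordance
python analysis/05_enrichment.py            # KS permutation enrichment + LS test
python analysis/06_clustering_concordance.py
```

Output of the discovery and validation runs (cohorts of 73 and 89
samples with a 3.43-fold planted marker effect and a planted group
hazard ratio of 4.43):

```
detected in >=90% of samples: 108 of 328 probes
features in the 20%-expression analysis set: 113
survival screen flagged 9 miRNAs at p<0.05: hsa_miR_038, hsa_miR_051, ...
marker hsa_miR_210: median-split HR = 1.65 (95% CI 0.70-3.93), p = 0.25,
10-year tdROC AUC = 0.63

training cutoff 1.012 assigns 43/89 (48%) of validation patients to the
low-risk group
validation HR = 2.10 (95% CI 0.85-5.21), p = 0.11
```

Reading these numbers: the detection filter recovers exactly the 108
probes planted as expressed; the marker's median-split hazard ratio is
attenuated relative to the planted group effect because the measured
expression is a noisy proxy for the latent group (a ~25%
misclassification at this fold change), so at ~30 events the interval
is wide — the risk-group *direction* reproduces in both cohorts, and
parameter-recovery checks at larger n (see the test suite) confirm the
estimators themselves are unbiased. The enrichment script reports a
planted target set at ES = 131.8 with permutation p ≈ 0.001 on 1000
permutations while an unrelated set sits at p = 0.79.

A single-command CLI wraps the same stages
(`mirprog simulate|normalize|run-discovery|run-validation`).

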