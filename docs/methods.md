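# Methods

`motifscreen` implements a multi-analyte early-detection analysis for
esophageal squamous cell carcinoma (ESCC) and its precancerous lesions
(ESPL: low- and high-grade intraepithelial neoplasia). Two plasma analyte
layers feed three random-forest classifiers: the 4-mer end-motif profile of
cell-free DNA (cfDNA) fragments, and a nine-marker tumour-protein panel.
This note records the model, the defaults, the numerical choices, and what
the synthetic data generator does and does not establish.

## End-motif profiling

A cfDNA fragment aligned to reference interval [s, e) contributes, under the
default `five_prime_both_ends` convention, the reference 4-mer `ref[s:s+4]`
(left terminus, forward strand) and the reverse complement of `ref[e-4:e]`
(the 5' terminal 4-mer of the reverse strand). Both fragment ends are
counted because both are products of the same nuclease cleavage biology and
counting both doubles the usable signal; `five_prime_left_only` and
`three_prime_both_ends` are available because the literature is not uniform
about the convention, and none of the three is claimed to match any
particular study. Motifs are read from the reference, not the read bases, so
sequencing errors cannot shift the profile; an end whose alignment is
soft-clipped is disqualified (the clip means the alignment boundary is not
the fragment boundary), and terminal windows containing N are skipped.

Fragment filters: properly paired, primary, non-duplicate, MAPQ >= 30,
inferred fragment length in [50, 500] bp (mono- to tri-nucleosomal cfDNA).
A sample with fewer than 1,000 usable fragments is flagged unusable rather
than silently normalised.

Counts are normalised per sample to ratio-to-average values, r_m = 256 ·
c_m / Σc, so every row has mean 1 independent of sequencing depth, then
z-scaled per motif. The z-statistics (mean, sd with n−1 denominator) are
fitted on the **training split only** and frozen; fitting on all samples
would leak test information into the transform. A motif constant on the
fitting set maps to z = 0 and is flagged instead of dropped, keeping the
256-column geometry fixed for PCA. (`fit_zscore` accepts any fitting subset,
so the literal fit-on-everything reading remains reproducible if wanted.)

## Differential selection and dimensionality reduction

Per-motif two-sample t-tests compare cases (ESCC + ESPL) against controls
on the z-scaled training rows. The default is Student's pooled-variance
test (Welch by flag) at raw two-sided p < 0.05 with **no multiplicity
correction** — the screening analysis this package models filters on raw p,
treating the filter as feature pre-selection for a classifier rather than
as inference; a Benjamini–Hochberg mode exists but is off by default.
Direction (up/down by the sign of the case−control mean difference) is kept
for every selected motif. Features constant in both classes have an
undefined statistic and are reported t = 0, p = 1, flagged, never selected.

Selected motifs are reduced by PCA to 30 components (fewer if the selection
or the training size cannot support 30). PCA input is already
variance-standardised by the z-scaling, so components are computed on the
train-centred covariance without rescaling. Each loading vector's sign is
fixed so its largest-magnitude entry is positive, making fits bit-stable
across runs; the full SVD solver is used so no solver randomness enters.

## Models

Three recipes, all fitted on the training split only:

* **motif**: z-scale → t-filter → PCA(30) → RF-RFE over components →
  random forest;
* **protein**: RF-RFE over the ten markers (AFP, CA19-9, CA24-2, CA72-4,
  CEA, Cyfra21-1, SCC, PG I, PG II, and the derived ratio PGR =
  PG I / PG II) → random forest — markers enter untransformed because
  trees are invariant to monotone transforms;
* **combined**: the motif branch's components joined with the ten markers,
  RF-RFE over the union → random forest.

RF-RFE removes the lowest-importance feature (impurity importance of a
forest fitted on all training rows) one per iteration and records the mean
stratified 10-fold cross-validated AUC at every subset size. Folds are
drawn once per run and shared across subset sizes and the hyperparameter
grid so scores are comparable. The chosen size is the argmax of the CV
curve, ties broken toward the smaller subset. AUC is the selection metric
because it is the evaluation currency of the whole analysis. Internally the
feature columns are put in a canonical sorted order, which makes the whole
procedure invariant to the caller's column ordering.

Forest defaults: 500 trees, sqrt(p) features per split, unlimited depth, no
class weighting; an optional grid (e.g. {250, 500, 1000} trees) is scored
by the same shared folds. The selected-feature counts are data outcomes —
the counts the modelled study arrived at (16 components; 8 proteins; 20
components + 6 proteins) are carried only as `published_counts_`
metadata for report annotation and are never enforced.

## Evaluation

* **AUC** is computed from midranks (exactly the Mann–Whitney pair-winning
  probability, ties ½).
* **DeLong variance** uses per-case and per-control placement values
  computed with midranks; CIs are normal-approximation, clipped to [0, 1].
  The paired test for two models scored on the same samples uses the
  covariance of the shared placements; a zero-variance difference is p = 1
  when ΔAUC = 0 (model vs itself) and an error otherwise.
* **Youden threshold**: J = sensitivity + specificity − 1 maximised over
  midpoints between adjacent distinct scores plus ∓∞ sentinels. Ties are
  broken toward higher sensitivity (screening prioritises not missing
  cases), then the lower threshold. The positive-call convention is
  `score >= threshold` everywhere. When the optimum sits at an infinite
  sentinel (a no-discrimination degenerate case, e.g. constant scores),
  the pipeline clamps it to the observed validation score range so
  downstream reports stay well defined with identical calls.
* **Proportion CIs** are Wald intervals clipped to [0, 100]% — this
  reproduces the printed bounds of the modelled study exactly (25/26 →
  88.8%, 10/11 → 73.9% lower bounds); Wilson is available by flag.
* **Baseline comparability**: Pearson chi-square without continuity
  correction for anything larger than 2×2 (Yates available for 2×2 only),
  Kruskal–Wallis with tie correction for numeric covariates.

## Cohort splitting

Default fractions 0.49/0.21/0.30. All splits but the last receive
floor(n·f); the last absorbs the remainder — for 491 samples this yields
240/103/148, matching the design the package models (their test set was
assembled prospectively, so it takes the leftover). Stratification by
subgroup is on by default: the synthetic cohorts are small enough that a
simple random split can visibly imbalance rare subgroups; `stratify_by=None`
reproduces the plain random design. Strata smaller than 3 are pooled into a
global draw with a warning.

One root seed fans out to fixed per-stage seeds via SHA-256 of
`"{seed}:{stage}"`, so each stage is independently reproducible and no
stage's consumption of randomness perturbs another.

## Synthetic cohort generator

No public data accompany the modelled study, so the generator is the test
bed. It emulates:

* the enrolment structure — default 491 participants (Health 29, Benign
  172, LGIN 46, HGIN 45, stage I 124, II 23, III 35, IV 17), with the fixed
  mapping {Health, Benign} → control, {LGIN, HGIN} → ESPL, stages → ESCC;
* motif composition: a fixed baseline 256-vector drawn once from a
  symmetric Dirichlet(20) under a frozen internal seed (identical across
  installs and independent of the user seed); cases shift 75 planted motifs
  up and 128 down by exp(severity · delta) with delta = 0.3, severity
  rising 0.5 (LGIN) → 1.0 (stage IV) to emulate the monotone sensitivity
  gradient reported for progressing disease; per-sample compositions are
  Dirichlet with concentration 2,000 around the subgroup mean (≈35%
  coefficient of variation per motif — substantial biological spread);
  counts are multinomial given a negative-binomial fragment total (mean
  50,000, dispersion 10 — desk scale, deliberately far below real
  sequencing depth);
* proteins: log-normal concentrations at typical plasma medians (e.g. CEA
  ~2 ng/mL, PG I ~50 ng/mL, sigma ~0.5) with multiplicative case shifts for
  CEA and Cyfra21-1 (1.3 ESPL / 1.5 ESCC) and unequal shifts for PG I (1.6)
  and PG II (1.3) so the pepsinogen ratio PGR is itself differential, as
  reported; the other five markers are null;
* optional aligned fragments: one fragment per pair of motif observations
  on a compact synthetic reference (one segment per distinct end-motif
  pair), so the profiler must return the simulated counts exactly. An odd
  leftover observation becomes a fragment whose right terminal window is
  NNNN, which the profiler's N-rule skips.

What the generator does **not** emulate: real genome sequence, fragment
size spectra, GC and mappability bias, sequencing error, duplicates, batch
effects, or biologically calibrated per-motif effect sizes (no study
reports them; delta = 0.3 is chosen for testability). Passing tests
therefore demonstrate that the pipeline is leak-free, calibrated under the
null, and able to recover planted multivariate signal — not that any
particular clinical performance would be attained on real plasma.

Note the planted conditions are strong in aggregate: an effect detectable
per-motif by a t-test at n ≈ 200/arm, summed over 203 motifs, makes the
multivariate motif model nearly separable (test AUC ≈ 1 at default
conditions). That is a consequence of requiring ≥90% per-motif recovery,
not a tuned outcome; the protein layer, with only four shifted markers,
stays in a realistic AUC range (~0.7–0.85).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on one CPU in minutes, so
simulations use desk-scale sizes chosen as package defaults: cohorts of
~400–491 samples, 10,000–20,000 fragments per sample, forests of 60–100
trees inside pipeline-level checks (the library default stays 500), 1,000
replicates for the DeLong coverage/type-I calibrations, and a 30-sample ×
~3,000-fragment fixture for the exact alignment round trip. The null
leakage guard reads its [0.4, 0.6] band against the median over seeded
replicates: a single ~60-sample test split has null AUC sd ≈ 0.08, so
per-replicate containment would fail by chance alone.

## Known limitations

* DeLong CIs are asymptotic; at very small n or near-degenerate AUCs the
  Wald-type interval can be anti-conservative.
* Wald proportion CIs (chosen to mirror the printed results) behave poorly
  at extreme proportions; Wilson is the better default when fidelity to the
  published format is not required.
* Forest bit-reproducibility is guaranteed per platform/sklearn version,
  not across versions.
* The RFE importance criterion is impurity-based; strongly correlated
  features share credit and can be eliminated earlier than a
  permutation-importance ranking would suggest.
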