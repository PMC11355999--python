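# Methods

## Scope and data model

The package analyzes a samples × metabolites peak-area matrix from an
untargeted LC–MS experiment on four study groups (Control, Control+Flx,
CSIS, CSIS+Flx), together with per-animal forced-swim-test (FST)
trajectories.  A `PeakTable` carries per-sample metadata (group, QC role,
dilution fraction and stage, injection order) and a `stage` tag that
enforces the processing order `raw → qc_normalized → tss → log`
(`raw → tss` is allowed when no pooled QCs exist).  All downstream
statistics run on the log10 TSS stage except fold changes, which use the
un-logged TSS group means, matching the convention of the common
web-based metabolomics platforms.

The three contrasts are fixed and ordered — Control+Flx vs Control,
CSIS vs Control, CSIS+Flx vs CSIS — with the first-listed group the
positive class everywhere.

## Phenotype rules

All thresholds are strict percentages of baseline, so labels are
invariant under rescaling an animal's times by any positive constant.
*CSIS*: immobility above 1.2 × baseline at week 3 **and** week 6.
*Responder* (CSIS+Flx, after meeting the week-3 stress criterion):
week-6 immobility strictly below 0.8 × its own week-3 value **or**
0.8 × the untreated-CSIS group's mean week-6 immobility.  The source
wording ("compared to CSIS at the end of the 3rd or 6th week") admits
both an animal-level and a group-level reference; the disjunction covers
both readings and the branch that fired is recorded in each label's
rationale string.  Excluded (resilient) animals never enter any
downstream statistic.

## QC handling

Pooled-QC injections are replicate measurements of one material, so any
trend over injection order is instrumental drift.  Per metabolite, a
drift curve is fit to QC area vs injection order — an ordinary
least-squares line when ≤ 4 QCs are available, otherwise a lowess
smoother (frac = 2/3, one robustness iteration) interpolated linearly to
every injection position (clamped at the ends) — and each sample's area
is divided by the curve value at its own position, then rescaled so the
metabolite's median is unchanged.  A metabolite whose fitted curve would
be non-positive anywhere is flagged and left uncorrected.

Quality gates: residual pooled-QC CV ≤ 30 % and pre-extraction
dilution-series linearity R² ≥ 0.9 (straight-line fit of area vs
relative concentration 1/0.8/0.5/0.2/0.1).  The thresholds are stated
criteria without published values, so both are configuration keys
(`qc_cv_max`, `qc_linearity_r2_min`).  A metabolite with no dilution
series is judged on CV alone.  The CV is computed *after* drift
correction: it then measures the residual technical noise the filter is
meant to bound, and reduces to the raw CV when there is no drift.

Zeros are replaced by half the smallest positive TSS value of the same
metabolite before log10 — a common metabolomics convention; the choice is
recorded here because the upstream platform's behavior is unspecified.

## Statistical stages

**DEMs.** Student's equal-variance two-sample t-test by default (the
common platform default; Welch via `equal_var_ttest: false`), two-sided,
per metabolite on log10 TSS values.  Benjamini–Hochberg step-up
adjustment is applied per contrast across all retained metabolites.  A
record is a DEM iff `p_adjusted < 0.05` and FC > 1.25 or FC < 0.75
(strict), FC being the ratio of TSS group means, first-listed over
second.  Zero-variance-in-both-groups columns get p = 1, t = 0 when the
means agree.  Degenerate FC (zero denominator mean) is flagged, never
gated.

**PLS–DA.** Single centered ±1 response column, mean-centered features
(unit-variance autoscaling off by default, switchable), NIPALS
extraction with X-deflation via scikit-learn's `PLSRegression`.  R²X is
the fraction of centered-X sum of squares captured by the score/loading
reconstruction; R²Y is 1 − SSres/SStot of the response.  Q² =
1 − PRESS/TSS over held-out samples; leave-one-out by default because
group sizes are 6–8 (stratified k-fold switchable).  Components are
capped at the training rank inside CV folds.  The one-component weight
vector is proportional to the class-mean difference on centered data — a
closed form used as an independent check.

**ROC markers.** The empirical ROC over all thresholds; AUC via
trapezoidal integration equals the Mann–Whitney U statistic divided by
n₁n₂ with ties counting one half (verified exactly against pair counting
in the tests).  When the raw AUC is below 0.5 the variable is negated and
the recorded direction flips, so reported AUCs lie in [0.5, 1].  The
optimal cutoff minimizes the distance to the (0, 1) corner (Youden's J
switchable).  Confidence intervals are percentile intervals over
stratified bootstrap resamples (resampling within class keeps both
classes present).  The marker gate is strict: AUC > 0.9 exactly at 0.9
fails.  No smoothing is applied, so complete separation at n = 6–8
yields AUC exactly 1.

**SVM panel selection.** Linear-kernel SVC with C = 1 and within-fold
standardization (mean 0, sd 1 on the training split).  The greedy path
starts empty; each step scores every remaining metabolite by the mean
held-out accuracy of the panel-plus-candidate classifier over
10 repeats × stratified 3-fold CV (per-repeat reshuffles driven by seeds
derived from `rng_seed`), appends the arg-max (ties broken by lowest
feature index), and stops at ⌊m/2⌋ features.  The reported panel is the
shortest path prefix attaining the maximum mean CV accuracy, which
reconciles the stop-at-half rule with the small published panels.

Performance is reported from a **nested** scheme: within each repeat the
same 3-fold split acts as the outer loop, the greedy search is re-run on
each outer training set alone (inner 3-fold, one repeat), and the panel
found there predicts the outer held-out third.  Without nesting the
panel is chosen on the folds it is scored on and label-permuted data
yields ~80 % apparent accuracy; with nesting the permuted-label accuracy
is ~50 %, as a calibrated estimate must give.  The aggregated 2 × 2
confusion matrix sums outer predictions over repeats and folds (each
sample appears once per repeat).

Sensitivity, specificity and accuracy are percents rounded to two
decimals; balanced accuracy is the arithmetic mean of the *rounded*
sensitivity and specificity, which is the identity the published metric
tables satisfy (83.30/87.50 → 85.40).

**Random forest.** Grid {100, 500, 1000} trees × depth {2, 3, 5,
unlimited} scored by OOB accuracy on the full two-group data; ties break
toward fewer trees, then shallower depth.  Gini impurity, √m features
per split (the library convention; recorded here because it is not
prescribed).  Evaluation reuses the 10 × 3-fold scheme and the same
aggregation as the SVM.  Importances are mean impurity decreases of
full-data forests, averaged over `cv_repeats` forest seeds by default
(single-seed mode available), re-normalized to sum to one; ranking ties
break by name; zero-importance features are listed but flagged.  Because
of per-split feature subsampling, importances are equivariant to column
permutation only in distribution, not realization-by-realization; the
tests check the averaged values within a small tolerance.

**Correlation.** Pearson r between each metabolite (log10 TSS by
default; raw switchable) and week-6 immobility, pooled across all
retained animals of all four groups.  p comes from the exact t-transform
with n − 2 df.  Gate: |r| > 0.4 and p < 0.05, both strict, with no
multiplicity correction in the gate (a BH column is emitted alongside
for transparency).  Constant inputs give a flagged record, never a
gated one.

## Synthetic data generator

The generator is the package's study stand-in; its defaults are the
study conditions, not tuning knobs.

* **Abundances.** Metabolite j has a log10 mean drawn uniformly from
  [4, 7]; study samples are log-normal with biological CV 0.2
  (σln = √ln(1 + CV²)).  The planted log-offset makes the ratio of
  *population group means* equal the planted FC exactly.
* **Planting.** Default counts per contrast 13 / 3 / 9
  (Control+Flx:Control / CSIS:Control / CSIS+Flx:CSIS), FCs drawn
  log-uniformly from [0.30, 0.35] ∪ (1.25, 3.3].  Planting is restricted
  to the sub-dominant half of the abundance range: TSS is scale-invariant
  per sample, so mass planted on dominant peaks would drag every other
  metabolite's TSS value outside the fold-change dead-band
  (compositional closure); restricting planting keeps unplanted TSS fold
  changes near 1, which is also the realistic regime — dominant serum
  peaks are stable, disease markers are minor components.  The recorded
  ground truth holds the *effective* FC of every contrast, including the
  mirror effect of stress-planted metabolites in the treated-vs-stressed
  comparison (FC = 1/fc).
* **Run structure.** Blanks (areas ~10⁻⁴ of the pooled mean), a
  pre-extraction dilution series at relative concentrations
  1/0.8/0.5/0.2/0.1 plus post-extraction re-dilutions, then 6 pooled-QC
  injections spread evenly among the randomized study samples.  Every
  injection is multiplied by a half-cosine drift rising from 1 to
  1 + 0.2 over the run; QCs carry multiplicative technical noise with
  CV 0.05.
* **Behavior.** Baseline immobility ~ N(100, 15²) s clipped to
  [20, 250]; a log-normal animal trait (σ = 0.18) is shared across weeks
  so that week-to-week rank order is stable; CSIS arms rise ×1.6 (week 3)
  and ×1.7 (week 6); the treated arm's week 6 is 0.55 × its week-3
  value; additive test-retest noise 8 s.  Week-6 immobility receives
  ±25 s per standard deviation of log10 area for each coupled metabolite
  (by default one up-regulated stress metabolite couples positively and
  one up-regulated treatment metabolite negatively).  Times are clipped
  to the 300 s test stage, with swimming/climbing filled as fixed
  fractions of the remainder.  An optional `resilient_fraction` injects
  animals without the stress response to exercise the exclusion rule
  (default 0).

What the generator does **not** emulate: missing values and censoring,
batch structure beyond a single run, heavy-tailed or correlated
biological noise, chromatographic artifacts, annotation errors.  Tests
passing on this generator therefore show the statistics behave correctly
under the assumed model, not that the model captures every pathology of
real LC–MS data.

## Problem sizes in tests and the acceptance script

Null DEM calibration uses 200 simulated studies at the full default
design (101 metabolites, n = 6–8 per group); planted-recovery uses 50
studies of the same size with FCs drawn from [0.3, 0.5] ∪ [2.0, 3.3]
(|log2 FC| ≥ 1).  The classifier recovery and permutation runs use a
24-metabolite design with three planted metabolites per contrast: the
greedy forward search costs O(m²) SVM fits per repeat and the reduced
feature space keeps the demonstrations fast while leaving the procedure
untouched.  Label-permutation calibration is reported as the mean
accuracy over six independent permutations: one fixed permutation of a
dozen-odd labels sits a full sampling standard deviation (~14
percentage points) from 50 % far too often to be a useful single-run
check.  These sizes are the package's own choice of demonstration
scale.

## Determinism

All randomness flows from a single `rng_seed` through
`numpy.random.SeedSequence` spawning (table vs behavior streams,
per-repeat fold shuffles, per-grid-point and per-repeat forest seeds,
bootstrap streams).  Identical seed and configuration give byte-identical
machine-readable reports.

## Known limitations

* The drift model (line or lowess) is a smooth-trend assumption; abrupt
  instrument events are corrected only approximately.
* The BH family is the per-contrast retained-metabolite set; adjusted
  p-values are not comparable across differently sized families.
* With n = 6–8 per class, AUC and Q² have large sampling variance;
  bootstrap CIs on AUC are wide and Q² can go negative on null data by
  design.
* The mwTab reader handles the common samples × named-metabolites
  numeric block layout only.
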