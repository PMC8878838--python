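# Methods

This note documents the statistical model behind `metabscreen`, the
defaults that matter, what the synthetic cohorts do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Synthetic cohorts

The generator (`metabscreen.simulate`) emulates an untargeted serum GC-MS
screening study at the peak-table level (no chromatogram-level structure:
no retention times, mass spectra or co-elution).

**Model.** Peak areas are log-normal per feature. Each feature *j* draws a
log-mean μ<sub>j</sub> ~ N(13.0, 1.2²) from a common hyperprior (areas
span roughly 10⁴–10⁷, as typical for integrated GC-MS signals), and each
injection draws `area_ij = exp(μ_j + δ_ij + ε_ij)` with multiplicative
noise ε of coefficient of variation `cv_noise` (default 0.3; within-group
biological plus technical variability of serum metabolites commonly falls
in the 20–50% range, and 0.3 is the package's fixed middle choice).
δ<sub>ij</sub> is the planted effect: for `n_differential` features
(default 24, mirroring the number of volcano-significant metabolites a
study of this design reports) the CRC group is shifted by
`log(2)·log2fc`, with |log2fc| drawn uniformly from `log2fc_range`
(default 1.0–2.5) and a random sign recorded in the `truth` table.
Effects are multiplicative on the raw-area scale so the log transform
makes them additive. BCRT is generated identically to HS, since the
analysis pools both into CTRL.

**Internal standard.** Every injection carries an IS area drawn log-normally
around 5×10⁵ with 5% CV — the injection-to-injection stability expected of
a spiked standard such as 2-isopropylmalic acid.

**Batches and QC injections.** Study samples are assigned to batches of 25
in randomised enrollment order. Each batch appends four control
injections: a solvent blank (exponential noise six orders of magnitude
below typical areas), a standard mixture (15 compounds at fixed nominal
IS-normalised levels, ±2% noise), a pooled sample (geometric-mean profile,
±3%), and a duplicate of one random batch sample (±2%, linked through the
`duplicate_of` metadata column). `simulate_qc_batch` can corrupt exactly
one rule at a time, which the QC tests rely on.

**Missingness** is completely at random at `missing_rate` (default 0.04,
safely below the 20% a 0.80-prevalence filter tolerates); an optional
intensity-dependent mode censors low areas preferentially. The IS channel
is never missing.

**What passing tests do not show.** The generator has no batch drift, no
retention-time misalignment, no heteroscedastic noise floor, no
correlated metabolite blocks and no class-dependent missingness. Results
on it demonstrate that the pipeline's statistics are calibrated and its
machinery recovers planted effects of the stated size — not that real
cohorts of this size would yield the same accuracy.

## Preprocessing

Values are IS-normalised (`area / IS_area` per injection), imputed,
log-transformed and autoscaled. Imputation replaces a missing cell with
half the per-feature minimum **observed IS-normalised area** of the
training rows — the common GC-MS "half-minimum" rule, applied on the
ratio scale because the transform operates on ratios and the IS varies
per injection. Autoscaling uses the sample (n−1) standard deviation;
constant columns (sd ≤ 1e−12) are dropped and listed in
`LogAutoscaler.dropped_`. All parameters (half-minima, means, scales) are
estimated on the training split and frozen, so test-set values never
depend on test-set composition.

The prevalence filter defaults to 0.80 (feature observed in ≥ 80% of
study samples, QC injections excluded from the count); 0.75 is available
via configuration. The train fraction defaults to 133/200 = 0.665 so a
200-subject cohort splits 133/67 stratified by class; a plain 66:34 ratio
would give 132/68.

## Batch quality control

Four rules per batch, evaluated independently:

1. **Blank** — maximum blank peak area below 0.1% of the median study
   total-ion area (instrument noise always produces nonzero signal, so an
   absolute "no peaks" is replaced by this relative threshold).
2. **Standards** — every standard's IS-normalised area within ±10% of its
   expected value (supplied, or the median over all standard injections).
3. **Duplicate** — for the 100 largest IS-normalised peaks of the original
   injection, the duplicate within ±15%.
4. **Pooled** — the batch's pooled injection inside the Hotelling T² 95%
   ellipse centred on the other pooled samples (median centre, robust to
   one wild injection). The ellipse *scale* defaults to the score
   covariance of a 2-component PCA fit on all study samples
   (`pooled_reference="study"`). Using the covariance of the ≈ 7 other
   pooled injections instead (`pooled_reference="pooled"`) is supported
   but has an irreducible ~5% per-batch false-alarm rate — T² is
   scale-invariant, so no amount of pooled-sample stability avoids it —
   which would fail about one clean cohort in three.

Missing control injections mark the report *invalid* rather than failed.
Tightening any tolerance can only shrink the pass set (monotonicity).

## Univariate statistics

Volcano fold change is mean(CTRL)/mean(CRC) on the raw IS-normalised
scale (the log scale would yield geometric means; the arithmetic-mean
convention is fixed and documented here). The t-test runs on
log-transformed values and is Welch's by default — group variances are
not assumed equal — with the pooled-variance Student's test available via
`equal_var=True`. Significance requires p < α (0.05) **and** FC strictly
outside (0.5, 2); boundary values are not significant. No
multiple-testing correction is applied in the volcano; FDR control lives
in the enrichment stage only. The Shapiro–Wilk gate (p ≥ 0.05 ⇒ t-test,
otherwise rank-based) and the clinical-table t/χ² comparisons follow the
usual conventions (χ² without continuity correction, so small worked
examples match the closed form).

## PLS-DA

Two classes are coded as a single centred 0/1 indicator column (for two
classes, two-column coding changes nothing). The latent components come
from NIPALS partial least squares (scikit-learn's `PLSRegression`,
`scale=False` on the already-autoscaled matrix); score vectors are
mutually orthogonal by construction. R² is the fit fraction of indicator
variance explained; Q² is its 7-fold cross-validated analogue
(1 − PRESS/TSS with held-out predictions). VIP for feature *j*:

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),
    SSY_a = q_a² ‖t_a‖²

so that mean squared VIP is exactly 1. Component count is chosen by
seeded stratified-CV accuracy, ties resolved toward fewer components.
The permutation test refits the classifier on label-permuted data and
reports `p = (1 + #{null ≥ observed}) / (n_perm + 1)` with
cross-validated accuracy as the statistic (R²/Q² variants would be
straightforward but accuracy is what the component-selection curve also
uses); the default is 2000 permutations. Class probabilities come from a
Platt-style logistic mapping of the continuous PLS prediction fitted on
the training decision values.

## Model zoo

The ten kinds map to standard families: GaussianNB (NB), L2-regularised
logistic regression (GLM), unpenalised logistic regression (LR), a linear
hinge-loss large-margin classifier (FLM), a small fully-connected network
with hidden layers 64/32 (DL), CART (DT), random forest (RF), gradient
boosted trees (GBT), RBF support vector machine (SVM) and the PLS-DA
classifier above. Margin models (FLM, SVM) get sigmoid (Platt)
calibration on inner folds so every kind reports a winning-class
probability; for two classes that confidence lies in [0.5, 1].

**Pre-screen.** Features are dropped when they mirror the diagnosis too
closely or not at all (|point-biserial r| > 0.95 or < 1e−12 — the exact
cut-offs are configuration, not a claim about any particular software),
when nearly constant (modal-value frequency > 0.95), or when missing
beyond the prevalence threshold.

**Genetic algorithm.** Bit-mask chromosomes over the feature set;
tournament selection (size 3), uniform crossover (rate 0.9), bit-flip
mutation (rate 1/p), elitism 1, fitness = seeded stratified k-fold CV
accuracy of the wrapped classifier, with per-subset caching. The best
subset ever evaluated is returned and the best-fitness trace is
non-decreasing. Library defaults are population 20 / 40 generations; the
pipeline configuration uses a lighter budget (12 × 8, 3-fold fitness) to
keep a ten-model run in minutes on one CPU.

**Nested CV.** The GA runs once on the training split; hyperparameters
are then tuned by grid search inside each outer fold (defaults: 5 outer,
5 inner; the pipeline uses 3 inner), and `cv_accuracy` is the mean
outer-fold accuracy. The final model refits on the full training split
with the inner-CV-chosen settings. Running the GA inside every outer fold
would multiply cost roughly by the fold count without changing any
contract tested here; the single-pass placement is this package's
choice. Hyperparameter grids are deliberately small (e.g. C ∈ {0.1, 1,
10}); the goal is an honest tuning loop, not an exhaustive search.

**Feature weights and the elbow.** Linear kinds contribute
|coefficients|, tree ensembles impurity importances, PLS-DA its VIPs, and
kinds without an intrinsic weight permutation importance. Weights are
sorted descending and the elbow is the interior point of maximum
perpendicular distance to the chord joining the first and last points;
ties (within 1e−12) break toward fewer features, and degenerate curves
(all equal, or fewer than 3 weights) return everything. Features strictly
above the elbow are that model's "relevant" set; UpSet counts are exact
exclusive membership-pattern cardinalities over those sets.

## Ensemble score and cut-off

Votes are `± cv_accuracy × confidence` with the sign set by each model's
predicted class; the EML score is their sum. The shipped cut-off is 0 —
the point where votes for and against exactly balance. `optimize_cutoff`
maximises Youden's J over midpoints of adjacent scores (plus 0) on
*training* scores only; among ties the cut-off closest to zero wins,
which returns exactly 0 for perfectly separated training scores. A score
exactly at the cut-off is called CTRL: in a screening context a
borderline case should not trigger a cancer call. The vote confidence is
the calibrated winning-class probability from the model zoo (renormalised
alternatives would rescale every vote identically and change no
classification at cut-off 0).

## Diagnostics

Confusion-matrix metrics are computed in exact rational arithmetic
(`fractions.Fraction`) and only rounded for display (two decimals, half
away from zero). PLR = S/(1−Sp) is "ND" when specificity is 1; NLR =
(1−S)/Sp is "ND" when specificity is 0. Standard errors use
√(p(1−p)/n) with each metric's own denominator (e.g. sensitivity over
positives), which reproduces the ± values conventional in screening
tables; no SE is attached to the likelihood ratios. The positive class is
CRC everywhere. ROC curves enumerate all unique thresholds; the trapezoid
AUC equals the Mann–Whitney U statistic over (n₊·n₋) with ties counted
one half. The DeLong comparison uses placement values (structural
components): covariance S₁₀/m + S₀₁/n, two-sided normal p; identical or
both-perfect classifiers yield p = 1 with an explanatory note rather than
a division by zero.

## Enrichment

The universe is the set of measured metabolites that map to the pathway
database, not the whole database (MetaboAnalyst-compatible convention).
Over-representation is the exact hypergeometric tail P(X ≥ k);
Benjamini–Hochberg adjusts across pathways. Pathway impact is the sum of
relative betweenness centralities of the hit nodes — node betweenness by
shortest-path counting on the *directed* pathway graph, normalised by the
sum over all pathway nodes (0 when every centrality is zero, e.g. an
edgeless set). Per-pathway relative centrality (rather than out-degree or
a global-network variant) is the fixed choice. A bundled synthetic
12-pathway database (5–20 nodes each; no real pathway content) supports
tests and examples; real databases load from GMT plus per-pathway edge
TSVs, and compound-ID mapping is accepted as an input table rather than
resolved online.

## Pipeline, seeding, problem sizes

Every stochastic stage derives its seed as
`sha256(master_seed:stage_name) mod 2³¹`, so adding stages never perturbs
earlier draws and any stage can be re-run in isolation from the manifest
(stage, sub-seed, artifact SHA-256). Re-running a configuration
reproduces all artifacts bit-identically.

The shipped validation suites choose desk-scale problem sizes: null
calibration uses 200 signal-free cohorts of 60 subjects (12 000 feature
tests) for the volcano false-positive rate, 3 seeded 60-sample null
datasets across all ten classifier kinds, 40 permutation-test replicates
of 19 permutations, and 200 random hit lists against the toy pathway
database; signal recovery uses the study-sized cohort (200 subjects, 243
features, 24 planted effects with |log2FC| ≥ 1.5) for volcano recall and
the full ensemble, and 20 seeded replicates of the 2-informative-
plus-18-noise construction at n = 100 per class for GA panel recovery.
The GA recovery experiment deliberately plants *moderate* standardised
shifts (1.2): under the cohort generator's |log2FC| ≥ 1.5 effects,
cross-validated fitness saturates at 1 and ties between subsets hide
whether the second panel member is selected, so the moderate regime is
the one that actually probes subset search.

## Known limitations

- The pooled-sample QC rule is one operationalisation of an inherently
  vague criterion; the statistic and bound are reported so alternatives
  can be compared.
- Confidence calibration for margin models relies on Platt scaling with
  3 inner folds; with very small training splits those probabilities are
  coarse.
- The synthetic generator's independence across features understates the
  correlation structure of real metabolomes; VIP rankings and GA subsets
  on real data will be less stable than on these cohorts.
- The deep-learning kind is a small MLP; no architecture search is
  attempted.
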