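# Methods

## The modeling problem

Subthalamic deep brain stimulation (STN-DBS) improves motor function in most
but not all Parkinson's disease patients, and the surgery is costly and
invasive, so a pre-surgical predictor of benefit has clinical value. The
quantity to predict is the fractional motor improvement

    Δrate = (UPDRS-III_pre − UPDRS-III_post) / UPDRS-III_pre,

where UPDRS-III is the 27-item motor scale (each item 0–4, totals 0–108,
lower is better). The predictors are pre-surgical resting-state functional
connectivity (FC) values: Pearson correlations between band-limited
(0.01–0.1 Hz) BOLD time series of the 246 regions of a Brainnetome-style
parcellation. Because dopaminergic degeneration in Parkinson's disease is
lateralized — symptoms typically begin unilaterally — the connectome is
analyzed per hemispheric compartment. The `(n choose 2)` region pairs split
into four disjoint edge sets:

* **LH** — both endpoints in the left hemisphere (7 503 edges),
* **RH** — both endpoints in the right hemisphere (7 503),
* **Ho** — homotopic inter-hemispheric edges, each region to its
  geometrically corresponding partner (123),
* **He** — all other inter-hemispheric edges (15 006).

Each network is modeled separately so their predictive value can be
compared; hemispheric asymmetry of the prediction quality is itself the
scientific question.

## Pipeline

For one network with edge-feature matrix `X (N subjects × d edges)` and
outcomes `y`:

1. **Screening.** A bagged regression forest (20 CART trees, each fit on a
   bootstrap of the N subjects; candidate features per split ⌈d/3⌉, minimum
   leaf 2, unlimited depth) yields an out-of-bag permutation importance per
   edge:

       X_k = Σ_t (errOOB2_{t,k} − errOOB1_t) / n_trees,

   where `errOOB1_t` is tree t's mean squared error on its out-of-bag
   subjects and `errOOB2_{t,k}` the same after randomly permuting column k
   within the OOB rows (an additive-Gaussian perturbation is available via
   `ForestConfig.perturbation`). Edges with `X_k > 0.005` are retained; the
   threshold lives on the raw MSE-difference scale with `y` expressed as a
   fraction in [0, 1], and is a config value.
2. **Prediction.** Ridge regression minimizing
   `J(θ) = MSE(y, Xθ + b) + α·½·Σθ²` with unpenalized intercept `b`,
   solved in closed form on train-fold-centered (and by default
   train-fold-standardized) features. `α` (and a `max_iter` grid kept for
   protocol fidelity — the direct solver makes it inert) is chosen by an
   inner 5-fold grid search (13 log-spaced `α` from 1e−3 to 1e3; ties break
   toward stronger regularization, then smaller `max_iter`).
3. **Validation.** Outer leave-one-subject-out loop: screening and the
   inner grid search rerun on each fold's N−1 training subjects
   (`selection_scope="per_fold"`); the held-out subject's outcome and
   connectivity are never visible to any stage of its fold. A fold whose
   screening selects nothing falls back to an intercept-only model
   predicting the training mean (logged). Performance is the Pearson r
   between the N held-out predictions and the true rates, with a two-sided
   p from the t-transform `t = r·√((N−2)/(1−r²))`; R² is reported as r²
   of those out-of-sample predictions (the in-sample coefficient of
   determination is kept as a secondary diagnostic, since an in-sample R²
   of a regularized fit is not comparable across feature-set sizes).

Group analyses (age: two halves as even as possible after sorting by age,
ties by subject id, the younger half taking the extra subject at odd N;
sex: by label; exclusions always explicit config) screen features once on
the full cohort — inter-group screening, deliberately shared across groups
so the groups are compared on the same edge set — then run the nested LOOCV
within each group.

Reporting follows the field's convention for "top connections" tables: the
top-k edges by importance map to gyrus pairs (24 gyri per hemisphere,
grouped into 7 lobes) and receive a rank-based normalized connection value
`(k − rank + 1)/k`, i.e. 1.0, 0.9, …, 0.1 for a full top-10; raw
importances are emitted alongside. Gyrus-pair aggregation uses the maximum
edge score within the pair (mean available), preserving the identity of the
top edge.

## Synthetic cohorts

No patient data ship with the package; the generator produces cohorts whose
ground truth is analytic so that recovery is checkable:

* Every ROI signal is `√c·g + √(1−c)·ε` with a cohort-shared global
  component `g`, giving every pair background correlation
  `c = connectivity_base` (default 0.2). `c` is restricted to [0, 1): a
  shared component cannot realize a negative common correlation.
* Each planted edge's two private components share a pair-specific factor
  sized so the pair's population correlation equals
  `r_target = c + effect_spread·u_s` (`u_s ~ Uniform(0,1)` per subject,
  default spread 0.65, clipped to ±0.95). Planted edges must be
  node-disjoint, which keeps the construction exact.
* Signals are band-limited to 0.01–0.1 Hz at TR = 2 s by the same
  zero-phase Butterworth filter the analysis uses; the default 230 time
  points emulate an 8-minute scan minus 10 discarded equilibration volumes.
* The latent outcome is `y = Σβ_k·r_target + ε`, `ε ~ N(0, σ²)` (default
  σ = 0.05), clipped to [0.05, 0.98], then converted to integer UPDRS-III
  scores: `pre ~ TruncNormal(44, 12²)` on [15, 108] (surgical candidates
  carry substantial motor burden), `post = round(pre·(1−y))` clamped below
  `pre`, so every subject improves and recorded rates lie in (0, 1]. The
  defaults (five planted edges at β = 0.25, so Σβ = 1.25) put the
  improvement distribution near the 0.66 ± 0.20 that motivated them.
* Null cohorts use identical connectivity generation but draw outcomes
  `N(0.6562, 0.2048²)`, independent of every edge.
* Reproducibility: one seed per cohort; each subject's stream is
  `default_rng([seed, subject_index])`, forest bootstraps use
  `[seed, 0]`, per-tree/per-feature permutation streams `[seed, 1, t, k]`,
  and per-fold seeds derive via `SeedSequence`, so results are bitwise
  reproducible and independent of evaluation order.

What the generator does **not** emulate: hemodynamic response, head motion,
scanner drift and physiological noise, spatial autocorrelation between
neighboring ROIs, negative background correlations, and effects of age or
sex unless a `GroupEffect` is configured. Passing recovery tests therefore
show the statistical machinery is sound — not that real rs-fMRI supports
comparable prediction accuracy.

## Study conditions and observed behavior

The bundled studies (`hemiconn.studies`) run at desk scale: recovery uses
60 subjects on a 12-regions-per-hemisphere atlas (66 RH edges) with 5
planted RH edges; null calibration uses 200 replicate cohorts of 40
subjects on a 4-per-hemisphere atlas (6 RH edges). Larger atlases plug in
through the same arguments.

With seed 1 the recovery study selects ≥ 4 of the 5 planted edges in ~98%
of outer folds and reaches out-of-sample Pearson r ≈ 0.95 on RH, while the
three signal-free networks stay far below.

**Known limitation — null behavior of cross-validated correlation.** On
null cohorts the pipeline's Pearson p is *not* uniform: the false-positive
fraction at the nominal 0.05 level is ≈ 0.7, with null r centered near
−0.5. This is a structural property of correlating leave-one-out
predictions with outcomes, not an implementation defect: under the null the
inner grid search favors maximal shrinkage, so each held-out prediction
collapses toward its training mean `(Σy − y_i)/(N−1)` — an exactly
decreasing function of the held-out value (an all-fallback run gives
r = −1 identically). Significance claims for this class of pipeline should
therefore rest on permutation of the full procedure rather than the
analytic p of the cross-validated r; the analytic p is reported because it
is the protocol's evaluation statistic.

## Numerical choices

* Band-pass: 4th-order Butterworth, applied forward-backward
  (`sosfiltfilt`), so the effective attenuation is squared and no phase lag
  distorts correlations. DC and a 0.2 Hz respiratory-band sinusoid are
  suppressed below 10% amplitude; mid-band 0.05 Hz passes above 90%.
* Pearson FC via `numpy.corrcoef`, symmetrized and clipped to [−1, 1];
  zero-variance ROI columns are an error naming the ROI, never a silent
  NaN. No Fisher z-transform by default (raw coefficients feed the model);
  `fisher_z` is available. Negative correlations are retained; there is no
  sparsification.
* Ridge: closed-form solve of `(X'X + Nα/2·I)θ = X'y` on centered data
  (least-squares at α = 0); standardization statistics come from the
  training fold only.
* Forest bootstraps that produce an empty OOB set are redrawn (up to 100
  attempts); permuting a constant column leaves its importance exactly 0.
* Degenerate inputs error early: atlases failing involution/balance checks,
  duplicate subject ids, constant evaluation vectors, bands at or above
  Nyquist, fewer than 10 subjects for LOOCV.

## Scope

Voxel-level preprocessing (slice timing, motion correction, registration,
normalization) is out of scope — inputs are ROI-level series or precomputed
FC matrices, and the pipeline exposes no global-signal-regression or
scrubbing stage (documented assumption). The surgical procedure and
stimulation programming are irrelevant to the statistics and absent.
Alternative regressors and multiple-testing correction across the four
networks are deliberately not provided.
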