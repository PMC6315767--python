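# Methods

This note records the models and procedures `metabomark` implements, the
defaults and why, the numerical choices, and what the synthetic benchmark
does and does not demonstrate.

## Data model

The pipeline's currency is a samples × features intensity table with a group
label per sample and a flag for pooled-QC injections. Intensities are
nonnegative; `NaN` is a missing (undetected) peak. The reference design —
used throughout as the default problem size — is six groups of 10–11
children (healthy controls `HC`, Crohn's-disease timepoints `PA`–`PE`
spanning an exclusive-enteral-nutrition course), ~600 features, and five
pooled-QC injections.

## Preprocessing

* **QC-RSD filter** (default threshold 30%): per-feature
  RSD = 100·SD/mean over the QC injections only, sample SD with n−1
  denominator — appropriate for the small QC pool (n = 5). Features whose
  QC RSD is undefined (fewer than two QC values, nonpositive mean) are
  dropped with a recorded reason.
* **Missingness filter** (default 20%): computed over biological samples
  only. Both filters use strict inequalities ("more than"), so a feature at
  exactly the threshold is retained.
* **log2** improves normality of right-skewed intensity data. Zeros are
  rejected by default; the pipeline converts them to missing first, with a
  warning, since a zero peak area is an absence call, not a measurement.
* **Pareto scaling** mean-centres and divides by √SD. The division alone is
  sometimes quoted as "Pareto", but centring is the universal convention of
  chemometrics software and the projection model requires centred data; a
  scaled column retains variance equal to the original column's SD.
* **Half-minimum imputation** fills remaining missing values (at most 20%
  per feature after filtering) with half the feature's minimum observed
  intensity — the standard low-abundance fill when missingness is
  predominantly below-LOD — only where a complete matrix is required
  (PCA, OPLS-DA). Univariate statistics exclude missing values pairwise
  instead.

## OPLS-DA

Single-response orthogonal projections to latent structures, fitted
deterministically (started from y; no random initialisation). The class is
encoded as a centred ±1 dummy, making the model invariant to affine
relabelling. The predictive weight is w ∝ X'y (unit norm); each orthogonal
component is extracted from the current loading's part orthogonal to w and
deflated from X; the final predictive component is taken from the deflated
matrix. Score orthogonality t'to[k] = 0 and the explained-variation
bookkeeping X = tp' + Σ to po' + E with ‖E‖² = (1 − R2X(cum))·‖X‖² are
exact by construction and asserted to 1e−8 in tests.

* **Components**: default 1 predictive + 1 orthogonal, matching the
  pairwise models of the motivating study; `select_n_ortho` offers a
  stop-when-Q2-drops rule.
* **Cross-validation**: K = 7 folds (the convention of the commercial
  package this workflow descends from), deterministic round-robin by sample
  order, falling back to round-robin within class if a training split would
  be single-class. Everything — centres included — is refit per fold;
  PRESS accumulates held-out squared error, Q2 = 1 − PRESS/SS.
* **Coefficients**: b with ŷ − ȳ = (x − x̄)·b folds the orthogonal filter
  into the predictive direction; the per-fold b vectors feed the jack-knife
  marker filter.

### VIP

Per-feature variable importance normalised so the mean square over features
is 1, split into a predictive part (between-group contribution) and an
orthogonal part (within-group contribution). Published VIP formulations for
orthogonal projections differ; the one implemented is pinned by identity
tests, not external software:

* VIPpred from the squared predictive weights (exactly √(K·w²) for the
  single-predictive-component case);
* VIPortho from the squared orthogonal weights, weighted per component by
  the X-variation it captures;
* VIP total combines the two blocks weighted by their captured
  X-variation. Weighting both blocks by X-side sums of squares keeps them
  commensurable — mixing the y-block SS (order n) with X-block SS (order
  n·p) would let the orthogonal part swamp the predictive one on any
  realistically wide matrix.

The VIPpred/VIPortho ratio is ∞ when VIPortho is zero; VIPortho > VIPpred
flags a feature as "not biomarker-relevant" without removing it (strict
mode removes it), since reference marker tables retain such features.

## Validation

* **Permutation test** (default 999 shuffles, seeded): each permutation
  refits the model and its cross-validation. Passing requires either the
  least-squares line through (|corr(y_perm, y)|, Q2_perm) — anchored by the
  original model at correlation 1 — to have intercept ≤ 0 at correlation
  zero, or the original Q2 to exceed every permuted Q2 (a tie counts
  against the model, the conservative reading).
* **R2 − Q2 ≤ 0.3** guards against overfitting; the rule is applied as
  stated with no special case when Q2 > R2.
* **CV-ANOVA**: F = ((SS − PRESS)/d1)/(PRESS/d2) with d1 = number of
  fitted components (predictive + orthogonal) and d2 = n − d1 − 1; the
  named test's published formulation is followed since the workflow it
  comes from does not print one. A PRESS above SS clamps to F = 0, p = 1.
  Significance threshold p < 0.05.
* Whether the original software refits orthogonal components inside each
  CV fold is not documented anywhere; this implementation refits the whole
  model per fold.

## Marker cascade

Stages run in a fixed order, each seeing only the survivors of the previous
one: Student's t-test (pooled variance; Welch available) → jack-knife 95%
CI → BH FDR → AUC → VIP → per-group Q-Q normality; final ranking by VIP
total, descending. Design notes:

* **Jack-knife CI** reuses the 7 CV sub-models: SE = √((K−1)/K · Σ(bₖ−b̄)²),
  CI = b ± t₀.₉₇₅,K₋₁·SE. Reusing the folds makes the CI deterministic.
* **BH on survivors**: q-values are computed over the t-test survivors
  only, as the staged workflow prescribes. Consequence: under a global
  null the q-stage passes essentially whatever the t-stage passes (~5% of
  features), so the cascade's false-positive control comes from the stack
  of stages, not from the FDR step alone. A second consequence is that
  *relaxing* the t-test threshold can shrink the final list (more
  survivors → larger BH m → larger q-values), so cascade monotonicity
  holds for every threshold except `alpha_t`.
* **AUC** is the rank-sum probability with ties counted ½, folded to
  ≥ 0.5 (marker quality is direction-agnostic; both depleted and enriched
  markers are reported). Bands: ≥0.9 excellent, ≥0.8 good, ≥0.7 fair,
  ≥0.6 poor, else failed; below 0.7 is excluded.
* **Q-Q normality** is assessed per group (a genuine marker is bimodal
  when the groups are pooled) as the R² of ordered values against normal
  quantiles at plotting positions (i−0.5)/n. The null distribution of this
  R² depends strongly on n — its median for perfectly normal data at
  n = 11 is ≈ 0.94 — so the default pass threshold is the sample-size-
  calibrated 5% critical value of the normality correlation test
  (Ryan–Joiner approximation) rather than a fixed cutoff; a fixed
  `qq_r2_min` may be configured instead. At n = 11 the default admits
  ~95% of genuinely normal samples where a fixed 0.95 cutoff would reject
  ~60%.

## Quantification

Ordinary least-squares calibration lines (weighted 1/x calibration is
deliberately out of scope); inverse prediction flags, never clips,
out-of-range and negative concentrations. Conversion to µg/g of dry faeces
is parameterised by explicit extract volume, dilution factor and dry mass,
since extraction recipes rarely pin all three. Group summaries use the n−1
SD and SEM = SD/√n.

The group-comparison default is **Welch's t-test on the concentrations as
given**: calibrating the test variant against the bundled reference
fatty-acid table, Welch on the raw concentrations reproduces both published
p-values (0.019, 0.046) to two decimals, while pooled or Welch tests on
log2-transformed values do not (0.002 and 5·10⁻⁵) despite the table's
log-transform footnote; the log-scale option remains available.

## Synthetic data

The generator emulates: per-feature log-normal intensities (base log2 mean
uniform over 10–24, biological SD 1.0 log2 units ≈ two-fold spread —
typical for faecal extracts), multiplicative group effects on the first
`n_differential` features (defaults: the eight published marker fold
changes, 0.15–20.3, applied to `PA`), pooled-QC injections equal to the
biological mean times log-normal noise whose CV equals the requested
technical RSD exactly in expectation (default 14%, the reference run's
value), 2% MCAR dropout, and below-LOD censoring at the per-feature 5%
quantile. The missingness rates are free parameters (no published values
exist); they were fixed once at values typical for untargeted LC-MS.

What it does **not** emulate: heteroscedastic technical noise (every
feature shares one RSD, so the RSD filter removes almost nothing at the
default settings, unlike real data), correlated features/pathway structure,
retention-time drift, batch effects, or intensity-dependent variance. Hence
passing the recovery benchmark shows the machinery is correct and
well-calibrated under the assumed model, not that real studies will enjoy
the same power.

## Problem sizes and determinism

Monte-Carlo checks use: 100 random problems for the PLS1 oracle, 100 seeds
for null calibration, 20 replicates of the recovery benchmark (10 planted
markers, fold change 16, 10% technical RSD, 11 samples/group, 100 features)
with 199-permutation validation, and one 999-permutation run at a small
size; these sizes give stable averages at desk scale. Every stochastic
stage takes a seed; the pipeline derives per-stage seeds by hashing a
single master seed with the stage name, so results are reproducible and
adding a comparison never perturbs another.

## Known limitations

* Two-class models only; multi-group questions are handled as all pairwise
  comparisons, as in the motivating workflow.
* The bundled reference summaries carry printed-precision rounding; their
  reproduction tolerances are 0.5% (group statistics) and two decimals
  (p-values).
* The cascade's stage-wise FDR (see above) controls the false-discovery
  rate only jointly with the other stages.
* Hotelling-T² score-distance flagging is provided as an optional
  convention for outlier screening; it is not an automated exclusion rule.
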