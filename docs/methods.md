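# Methods

`lonebrain` implements a three-arm analysis of how a binary trait-loneliness
report relates to imaging-derived phenotypes (IDPs) in a large population
cohort, together with a generator of synthetic cohorts that makes every stage
testable without access to restricted data. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests do
and do not establish.

## Cohort and features

Each participant carries:

* 100 regional gray-matter volumes on a 100-parcel cortical atlas whose
  parcels partition into seven canonical networks (Visual, SomMot, DorsalAttn,
  Salience, Limbic, Control, Default);
* 4,950 functional-coupling edges (the lower triangle of the 100 x 100
  region-coupling matrix, row-major, i > j);
* 48 tract mean-FA values (JHU ICBM-DTI-81 catalog);
* covariates: sex, age, and nuisance variables (BMI, head size, task and
  rest head motion, head position x/y/z, scanner-table position, acquisition
  site);
* the binary outcome y (1 = often feels lonely).

The bundled parcel table is a synthetic stand-in for the public
Schaefer/Yeo 100-parcel release (same naming and ordering conventions,
hemisphere-symmetric counts, Default network largest at 20 regions); the
48-tract list is the standard JHU label set. Region indices are 0-based
internally; file headers are 1-based.

## Deconfounding

All three feature blocks are cleaned identically: each column's least-squares
projection onto a confound design (intercept, z-scored continuous confounds,
one-hot site with the alphabetically first level as reference) is removed.
Order of operations is residualize-then-z-score for volumes (the model
requires unit-variance inputs); coupling edges are z-scored across
participants *before* cleaning and not re-standardized after (a
`standardize_first` / `standardize_output` switch exposes the alternatives);
FA columns are residualized only, since correlation statistics are
scale-invariant. z-scores use the n-1 (sample) SD convention throughout,
which affects only scale constants. Higher-order age effects are available as
polynomial age columns (`age_degree`) for sensitivity analyses.

## Hierarchical volume models

The outcome is Bernoulli with

    logit(p) = x_1 beta_1 + ... + x_100 beta_100
             + alpha_men + alpha_women + alpha_men_age * age_z + alpha_women_age * age_z

where the sex-specific intercepts/slopes are two group intercepts (not
intercept + contrast) with standard-normal priors, and age enters z-scored.
Region coefficients are partially pooled through the atlas hierarchy:

* **network_level**: all regions of network k share one scale,
  beta_r ~ N(0, sigma_k^2); the posterior of sigma_k measures how much
  coefficient variance network k carries and induces the network importance
  ranking (ties broken by canonical network order).
* **region_level**: per-region scales tau_r, and within-network correlations
  of the coefficient block under an LKJ(eta) prior; `diagonal=True` drops the
  correlations.

Priors left open by the modeling tradition are half-normal(1) on every scale
and LKJ concentration eta = 2; both are exposed in `ModelSpec`. The
"5-95% HPD" reported everywhere is the 90%-mass highest-density interval
(narrowest sorted-sample window); for symmetric unimodal posteriors it
coincides with the 5th-95th percentile interval. Reported point estimates
are posterior means. Convergence is monitored with classic split-Rhat;
constant chains define Rhat = 1 with a warning.

### Sampler

Posteriors are approximated with the package's own No-U-Turn sampler:
recursive tree doubling with a slice variable, divergence threshold 1000 on
the energy error, dual-averaging step-size adaptation toward acceptance 0.8,
and a warmup schedule of fast windows (first 15%, last 10%) bracketing
doubling slow windows that estimate a diagonal metric from warmup draws.
Region coefficients are non-centered (beta = sigma * z), which keeps the
funnel geometry benign in the weak-signal regime this data occupies. The
within-network correlation Cholesky factor is parameterized by canonical
partial correlations (tanh of unconstrained values), under which the LKJ
prior factorizes into independent scaled-Beta terms with closed-form
gradients. Sampler correctness is tested against analytic Gaussian moments,
a logistic-regression MLE, and finite-difference gradient checks; the LKJ
construction is tested against the known scaled-Beta marginal of pairwise
correlations.

Default desk-scale sampler settings are 4 chains x (1,000 tune + 1,000
draws); `paper_settings=True` selects the long-warmup preset
(4,000 tune + 1,000 draws). Stratified fits duplicate coefficient blocks per
sex (women = group 0, men = group 1) with shared nuisance terms.

## PLS connectivity mode

The dominant population mode linking the 4,950 cleaned edges to the +-1
encoded outcome is the first PLS component. With a univariate target this
component is available in closed form: the x-weights are the normalized
X-by-y cross-covariance, scores are the projection of centered X onto them,
and the mode statistic is the Pearson correlation between scores and labels.
The sign convention orients the mode so this correlation is non-negative
(negating the label encoding therefore flips the weight vector but not the
axis or the statistic). Only k = 1 is computed and tested. Significance uses
a label-permutation null (default B = 1,000) refitting the full mode per
shuffle, with the one-sided add-one p-value (1 + #{null >= obs}) / (1 + B);
deconfounding is applied once before permutation. Edge weights are
back-projected to a symmetric 7 x 7 matrix of network-block means.

## Tract associations

Each FA column is tested against y with Pearson (equal to the point-biserial
correlation for a binary outcome) and Spearman statistics and two-sided
analytic p-values. Bonferroni correction uses m = 48 within each statistic
family (not m = 96 across families). Uncertainty is a 5-95% percentile
bootstrap of the Pearson coefficient over B = 100 participant resamples
(percentile, not BCa: B = 100 is too small for stable BCa corrections);
single-class resamples are redrawn with a logged retry cap. Tracts are
ranked by |Pearson rho| descending with catalog order breaking ties.

## Synthetic cohort generator

The generator mirrors the volume model generatively and plants known effects
in the other two arms. Defaults are the study conditions:

* n = 38,701; target prevalence 13.1% (the intercept is calibrated by
  bisection to 1e-6 on the mean inverse-logit); sex Bernoulli(0.475 male);
  age uniform on [40, 69] (z-scored at model entry).
* Volumes: unit-variance with exchangeable within-network correlation 0.3
  via a single network factor (feasible for correlations in [0, 1));
  between-network correlation defaults to 0 and is configurable.
* Network scales for the planted coefficients (canonical order): Visual
  0.04, SomMot 0.04, DorsalAttn 0.05, Salience 0.02, Limbic 0.06, Control
  0.03, Default 0.07 - the magnitudes reported for the real cohort, used as
  planted truth, not as values the fits are expected to reproduce at small n.
* Coupling edges: unit noise plus `fc_mode_strength` times a unit-norm
  planted mode (within-Default up-weighted, Default-to-Limbic/DorsalAttn/
  SomMot mildly up, within-Visual up, Visual-to-other down) times the +-1
  label. The default strength 0.1 is a realistic weak effect
  (score-label correlation ~0.1).
* Tract FA: column t is rho_t * z(y) + sqrt(1 - rho_t^2) * e with e
  residualized against z(y) and rescaled, so the sample point-biserial
  correlation is *exactly* rho_t. Defaults plant 0.06 on the fornix body
  and 0.05 on both fornix-cres tracts, 0 elsewhere; values are on an
  FA-like scale (0.45 +- 0.05).
* Optional confound contamination adds loading * z(confound) to every
  column of a named block.

Identical config + seed is bit-reproducible.

### Strong-signal test configurations

At the default (realistic) effect sizes, recovery at desk-scale n is weak by
design, so recovery tests amplify the planted signal and document it:

* volume arm: one network at sigma = 0.3 against 0.02 elsewhere;
* connectivity arm: `fc_mode_strength = 4.0`, chosen from the closed-form
  identifiability of the cross-covariance direction,
  cos ~ s sqrt(n v) / sqrt(s^2 n v + E) with v = 4p(1-p) ~ 0.455 and
  E = 4,950, which gives cosine ~0.86 at n = 2,000.

### Desk-scale problem sizes

The test suite runs the MCMC checks at n = 1,500-2,000 with 2-4 chains x
(400-500 tune + 400-500 draws), 3 seeds for ranking recovery, 400 replicates
for permutation calibration, and 500 replicates for bootstrap coverage;
these are the package's standard desk-scale configurations. The acceptance
script fits the network-level model at n = 2,000 with the full
4 x (1,000 + 1,000) sampler settings and generates one full-size
(n = 38,701) cohort for the prevalence check.

## What passing tests do and do not show

The generator produces Gaussian, exchangeably correlated features, exact
planted tract correlations, and a single linear connectivity mode. Passing
recovery tests therefore demonstrates that the estimators are correct under
the model's own assumptions - they do not establish robustness to
non-Gaussian IDP distributions, site batch structure beyond a categorical
shift, spatial autocorrelation within networks, nonlinear confound leakage,
or outcome misclassification, none of which the generator emulates. Results
on real cohort data additionally depend on preprocessing choices (image
registration, atlas projection, motion handling) that are entirely out of
scope here.

## Known limitations

* The sampler runs chains sequentially on one core; no within-chain
  parallelism.
* The region-level LKJ model carries ~900 unconstrained parameters on the
  bundled atlas and is markedly slower than the network-level model; it is
  exercised at reduced atlas sizes in tests.
* Network-importance ranking under the region-level model is defined as the
  per-network RMS of posterior-mean region scales (the network-level model's
  sigma is the primary ranking instrument).
* Percentile bootstrap intervals with B = 100 have coarse (5-95%) endpoints;
  coverage is validated to within +-5 percentage points, not finer.
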