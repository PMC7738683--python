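# lonebrain

Multimodal population-neuroimaging associations of trait loneliness.

Loneliness — the subjective experience of social isolation, captured in large
cohorts by a single binary item ("Do you often feel lonely?") — has been
linked to structural and functional brain differences concentrated in the
default network. Testing that at population scale requires three differently
shaped analyses over imaging-derived phenotypes (IDPs): regional gray-matter
volumes with a natural region-in-network hierarchy, ~5,000 strongly
collinear functional-coupling edges, and a few dozen white-matter tract
summaries. `lonebrain` implements all three arms as sklearn-style
estimators, plus a synthetic-cohort generator with known ground truth so the
whole pipeline is testable without restricted cohort data.

## The three arms

**Gray-matter volumes — Bayesian hierarchical logistic model.** The binary
outcome y is Bernoulli with

    logit(p) = Σ_r x_r β_r + α_men + α_women + α_men_age·age_z + α_women_age·age_z

over 100 z-scored regional volumes x_r. Region coefficients are partially
pooled through the 7-network atlas hierarchy: in the network-level model all
regions of network k share a variance component, β_r ~ N(0, σ_k²), so the
posterior of σ_k ranks networks by how much coefficient variance they carry;
the region-level model gives each region its own scale with within-network
LKJ-prior correlations. Posteriors are approximated by the package's own
No-U-Turn sampler (non-centered parameterization, dual-averaging step size,
diagonal metric adaptation) and reported as posterior means with 5–95%
highest-density intervals and split-R̂ diagnostics.

**Functional connectivity — dominant PLS mode.** The first partial-least-
squares component linking the 4,950 lower-triangle coupling edges to the
±1-encoded outcome (with a univariate target, its x-weights are exactly the
normalized X-by-y cross-covariance). Assessed with a label-permutation null
(B = 1,000 refits, add-one one-sided p-value) and back-projected to 7×7
network-block means.

**Tract microstructure — correlation screen.** Point-biserial (Pearson) and
Spearman associations of 48 tract mean-FA values with y, Bonferroni-corrected
at m = 48 per family, with 5–95% percentile bootstrap intervals (B = 100) and
an |ρ|-descending ranking.

All arms share one deconfounding step: least-squares removal of nuisance
variation (BMI, head size, task/rest motion, head position x/y/z, table
position, acquisition site) before modeling.

The synthetic generator mirrors the volume model generatively (network-level
coefficient scales, largest in the default network), calibrates the intercept
by bisection to a 13.1% prevalence at n = 38,701, plants a
default-network-dominant connectivity mode, and constructs FA columns whose
point-biserial correlations with the outcome are exact (fornix tracts
0.05–0.06 by default). See `docs/methods.md` for model details, priors,
numerical choices, and what the synthetic tests do and do not establish.

## Worked example

```python
from lonebrain import (GeneratorConfig, generate_cohort, clean_features,
                       HierarchicalVolumeModel, PLSPhenotypeMode, TractAssociation)

cohort = generate_cohort(GeneratorConfig(n=2000, fc_mode_strength=4.0, seed=1))
print(f"cohort: n={cohort.cohort.n}, prevalence={cohort.cohort.loneliness.mean():.3f}")

X = clean_features(cohort.volumes, cohort.cohort)
model = HierarchicalVolumeModel(kind="network_level", chains=2,
                                tune=500, draws=500, seed=0)
model.fit(X, cohort.cohort.loneliness, sex=cohort.cohort.sex, age=cohort.cohort.age)
print(f"max Rhat: {model.max_rhat_:.3f}")
print("network ranking:", " > ".join(model.network_ranking_[:3]), "...")

fc = clean_features(cohort.fc_edges, cohort.cohort, restandardize=False)
pls = PLSPhenotypeMode(n_permutations=1000, seed=0).fit(fc, cohort.cohort.loneliness)
perm = pls.permutation_test(fc, cohort.cohort.loneliness)
cos = abs(float(pls.x_weights_ @ cohort.truth.planted_mode))
print(f"PLS mode corr: {pls.mode_corr_:.3f}, permutation p = {perm.p_value:.4f}, "
      f"cosine to planted mode = {cos:.2f}")

fa = clean_features(cohort.fa, cohort.cohort, restandardize=False)
ta = TractAssociation(n_bootstrap=100, seed=0).fit(fa, cohort.cohort.loneliness)
for _, r in ta.table_.sort_values("rank").head(3).iterrows():
    print(f"  {r['tract']}: rho={r['pearson_rho']:.3f} "
          f"CI=({r['ci5']:.3f}, {r['ci95']:.3f}) p_bonf={r['p_bonferroni']:.3g}")
```

Output (about a minute on one core):

```
cohort: n=2000, prevalence=0.142
max Rhat: 1.009
network ranking: Default > Control > Limbic ...
PLS mode corr: 0.952, permutation p = 0.0010, cosine to planted mode = 0.87
  Fornix (column and body): rho=0.058 CI=(0.026, 0.091) p_bonf=0.435
  Fornix (cres) / Stria terminalis R: rho=0.051 CI=(0.019, 0.091) p_bonf=1
  Fornix (cres) / Stria terminalis L: rho=0.050 CI=(0.013, 0.090) p_bonf=1
```

Reading it: the sampler converged (all R̂ ≤ 1.02); this strong-signal
configuration plants a connectivity mode that the PLS arm recovers (cosine
0.87 to the true edge pattern) and flags against its permutation null
(p = 1/1001 is the add-one minimum at B = 1,000); the tract arm ranks the
three fornix-carrying tracts first, with sample correlations landing on the
planted 0.05–0.06 and bootstrap intervals quantifying their sampling
variability — at n = 2,000 such small effects are real but not
Bonferroni-significant, which is exactly why the original analyses needed
tens of thousands of participants. The volume-arm network ranking at this n
is driven by weak planted scales (0.02–0.07) and is not expected to be
stable; see the strong-signal recovery tests for the identifiable regime.

A command-line interface mirrors the library
(`lonebrain simulate | deconfound | fit-volumes | fit-fc | fit-tracts |
validate | run`), and `lonebrain run --config cfg.yaml` executes the whole
pipeline from one YAML config, writing a results bundle (summary tables,
permutation null, tract table, manifest with config hash and per-file
checksums, markdown report).

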