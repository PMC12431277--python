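# Methods

## Statistical model

All four model specifications are Gaussian variance-components models

y = Xβ + Σᵢ Zᵢuᵢ + ε,  uᵢ ~ N(0, σᵢ²I),  ε ~ N(0, R),

with X an intercept column only.  R is a single σ²ₑI for the per-year
models (1 and 5) and diag(σ²ₑ,ⱼ) per year for the across-year models (3 and
6), because the two trial years used different growing systems and assay
platforms and their error variances cannot be assumed equal.  All grouping
factors (replicate, year, genotype, female/male parent, cross, and their
year interactions) enter as independent i.i.d. random effects; there is no
pedigree or marker kinship, no spatial structure, and no fixed covariates —
the incomplete blocks of the field layout are not modelled (only complete
replicates), so replicate effects absorb whatever they can.

Under the NC II interpretation, σ²_GCA estimates the half-sib family
covariance per parent sex and σ²_SCA the extra full-sib covariance, giving
σ²_A = 2(σ²_GCA-F + σ²_GCA-M) and σ²_D = 4σ²_SCA in a non-inbred,
epistasis-free idealization.  Those coefficients — and everything derived
from them — are only as good as that idealization; with selfed parental
lines the "2" and "4" are approximations, which is the standard caveat for
this design.

## REML estimation

The restricted log-likelihood is maximized with average-information (AI)
updates preceded by three EM steps (the EM update is used again whenever an
AI step fails or the AI system is singular).  Because n is at most a few
hundred for this design, V = Σ σᵢ²ZᵢZᵢ' + R is formed densely and

l_R = −½[(n−p)log 2π + log|V| + log|X'V⁻¹X| + y'Py]

is evaluated by Cholesky factorization; scores and the AI matrix use the
projection matrix P directly.  This dense formulation is deliberately
simple and transparent; it would not scale to thousands of plots, which
this design never has.

Numerical policy:

- **Nonnegativity / boundary.** Components are clipped at 0 during step
  halving; a component below 1e-8·var(y) is fixed at 0 and removed from the
  update set, and re-enters if its score turns positive.  Residual
  variances are floored at 1e-10·var(y) so V stays positive definite.
- **Step control.** Each AI (or EM) step is halved up to 30 times until the
  restricted likelihood does not decrease; if that fails the exact EM step
  is taken, which cannot decrease it.
- **Convergence.** Relative log-likelihood change < 1e-8 *and* relative
  parameter change < 1e-6, within 200 iterations by default (all exposed as
  `fit()` arguments).  Non-convergence flags the result rather than raising.
- **Degenerate input.** A constant response returns μ̂ = y, all components
  0 at the boundary, converged, with an infinite restricted likelihood.
- **Starting values.** var(y) split equally over all parameters.

BLUPs are û = σᵢ²Zᵢ'Py with prediction-error variance
PEV = σᵢ² − σᵢ⁴·diag(Zᵢ'PZᵢ) (the Henderson mixed-model-equation solution
in V-form); components at the boundary have no BLUPs (the predictor is
identically zero).  Component standard errors are from the inverse AI
matrix at the optimum — one-sided in interpretation when the estimate sits
at a boundary.  BLUP significance uses t = û/√PEV against the standard
normal, appropriate because residual degrees of freedom are in the
hundreds here; the reference is a documented choice, not a small-sample
claim.  Variance-component significance uses the likelihood-ratio test with
the boundary null mixture ½χ²₀ + ½χ²₁.

The engine is validated two ways: on balanced two-way layouts REML must
equal the closed-form expected-mean-squares ANOVA estimators (checked to
1e-6 relative on 20+ randomized layouts, and exactly on a packaged 2×2
example whose solution is hand-computable), and by Monte-Carlo parameter
recovery at the trial scale (12×14, 118 crosses, 2 replicates), where mean
estimates over 100 replicates land within a few percent of the generating
truth and pooled ±2·SE coverage is ≈0.89.

## Derived statistics

σ²_P = σ²_A + σ²_D + σ²ₑ/r is a plot-mean-basis phenotypic variance.  Two
σ²_G readings coexist on purpose: narrow-sense heritability uses
σ²_A + σ²_D from the combining-ability fit, while broad-sense heritability
and genetic advance for hybrids use the total genotypic variance of the
per-year model-1 fit — the former targets additive transmission, the latter
total genotypic selection among the hybrids as they stand.  The average
degree of dominance is √(2σ²_D/σ²_A): with σ²_A = 4·Cov(HS-sum) and
σ²_D = 4·σ²_SCA this is the variance-ratio analogue of the classical d/a
scale, and >1 reads as overdominance-level nonadditivity.  Genetic advance
uses the standardized selection differential i = 2.06 (5% selected
fraction) and the *unrounded* heritability; GAM = 100·GA/μ.  No standard
errors are produced for derived ratios — propagating component SEs through
these nonlinear maps would need a delta-method machinery whose inputs
(component covariances at boundaries) are unreliable, so the package
reports the point values only.

## Heterosis and associations

Adjusted means are μ̂ + BLUP from per-year model-1 fits, parents and
hybrids fitted separately (they were also blocked separately in the
motivating trial).  MP is the parent average, BP the larger parent mean —
"larger is better" is applied uniformly to all nine minerals, with
direction left to interpretation in reports (negative heterosis can be
desirable, e.g. for sodium).  Since concentrations are positive, BP ≥ MP
implies BPH ≤ MPH entry-wise, which is asserted as an invariant.  Pooled
heterosis ranges scan every MPH and BPH entry across crosses, traits and
years.  Spearman correlations use midranks for ties and the t
approximation on n−2 df; panel cells are reported raw, without multiplicity
correction.  sGCA is the exact sum of the two parental GCA BLUPs.

## Outlier screening

Per population × trait × year, a fixed-effects screening regression on
genotype and replicate indicators supplies externally studentized
residuals; two-sided p-values are Holm-adjusted within the screening family
and flagged at family level α = 0.05.  Flagging and removal are separate
steps; the pipeline drops flagged rows but keeps them (with a warning) if
removal would orphan a hybrid's parent.  With two replicates a gross error
in one plot also inflates its sibling's residual (both deviate
symmetrically from the genotype mean), so flags should be read per
genotype-cell at r = 2.

## Synthetic data generator

The generator draws every term of the across-year combining-ability model
independently Gaussian and sums them.  Defaults describe a two-year,
2-replicate, 12×14/118-cross calcium-like trial: μ = 23.45 g kg⁻¹,
σ²_GCA-F = 5.19, σ²_GCA-M = 2.38, σ²_SCA = 0.36, σ²_Y = 68.7,
σ²_GCA-F×Y = 9.33, σ²_GCA-M×Y = 1.79, σ²_SCA×Y = 15.36, per-year residuals
{0.48, 0.84} (all in (g kg⁻¹)²), i.e. a year effect dominating everything
and interaction variance exceeding main-effect genetic variance.  The
replicate-within-year variance is set to 0.1 — a small value typical of
well-run greenhouse replicates — because no replicate variance is published
for this design.  `single_year_ca2019()` gives the corresponding one-year
configuration with σ²_GCA-F = 27.75, σ²_GCA-M = 6.69, σ²_SCA = 25.68,
σ²ₑ = 0.48.

Parent phenotypes are simulated as μ + year + replicate + 2·(own GCA) +
residual.  That is a *convention* to give synthetic heterosis a known
structure (an additive parent equals twice its transmitted effect above the
mean); real selfed parents carry inbreeding and non-additive deviations the
generator does not model.  Phenotypes are truncated at 0 (concentrations);
at the default signal-to-mean ratios this affects well under 1% of draws.
Consequently, passing tests demonstrate correct recovery of the *assumed*
Gaussian, independent-effects architecture — they say nothing about
robustness to non-normality, outliers, heteroscedasticity within year, or
incomplete-block field effects, none of which the generator emulates.

## Problem sizes in the test-suite

Unit tests run on toy layouts (2–8 levels per factor); the Monte-Carlo
checks use 100 replicates of the full 12×14/118 design for recovery and
15–20 replicates for ranking/consistency properties, sizes at which the
whole suite completes in well under a minute on one core.

## Known limitations

- No epistasis anywhere (not estimable in this design without further
  assumptions); σ²_D absorbs all nonadditive covariance.
- No incomplete-block (alpha-design) adjustment; replicate is the only
  blocking factor, as in the models above.
- Component SEs from the AI matrix are asymptotic and optimistic near
  boundaries; interval coverage for variances with ~a dozen levels runs a
  few points below nominal.
- The across-year broad-sense heritability for *hybrids* combines model-3
  components via the same formula as for parents; published values for that
  particular row are not reproducible from their printed components, so the
  package makes no claim of matching them.
- XLSX ingestion expects a long-format sheet mappable by a column-name
  schema; it does not parse arbitrary supplementary layouts.
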