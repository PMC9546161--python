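# Methods

## Model

Phenotype is a k-vector z, multivariate normal before selection:
z ~ N(μ, Σ). Expected absolute fitness is log-quadratic,

    W(z) = exp(f(z)),   f(z) = a + b′z + ½ z′gz,

with g symmetric (diagonal: quadratic terms, off-diagonal: correlational
terms). Directional and quadratic selection gradients are defined as the
expectations of the slope and curvature of relative fitness over the
phenotype distribution:

    β = E[∂W/∂z] / E[W],    γ = E[∂²W/∂z∂z′] / E[W].

Under Gaussian z these expectations have closed forms. Writing
Ω⁻¹ = Σ⁻¹ − g and ν = μ + Ω(b + gμ), the phenotype distribution after
selection is N(ν, Ω) whenever Ω is positive definite, and

    β = Q(b + gμ),     γ = ββ′ + Qg,     Q = (I − gΣ)⁻¹.

Two identities anchor everything: the selection differential ν − μ equals
Σβ, and when g is negative definite the model is an (unnormalized)
Gaussian fitness function with optimum θ = −g⁻¹b and width ω = (−g)⁻¹, so
the gradients coincide with the stabilizing-selection forms
β = −S(μ−θ), γ = ββ′ − S, S = (ω+Σ)⁻¹. Unlike the Gaussian special case,
the log-quadratic model also covers upwardly curved (disruptive or
accelerating) fitness surfaces, subject only to Ω being positive definite
(univariate: g < 1/σ²); beyond that boundary mean fitness diverges and
gradients are undefined, which the package reports as a failed
Ω-condition rather than a number.

Mean fitness E[W] is evaluated through the pointwise identity
W̄ = W(z)·p_{μ,Σ}(z)/p_{ν,Ω}(z), whose right side is constant in z (the
tests verify the constancy at several z); we evaluate at z = μ. This
avoids a separately transcribed closed form.

Scale is the caller's contract: μ and Σ must describe the phenotype on the
same scale as b and g. The univariate formulas then deliver unstandardized,
variance-standardized, or mean-standardized gradients as appropriate.
Estimators record the centring/scaling they applied.

## Uncertainty

(Co)variances of the elements of b and g — sampling covariance of a fit,
or biological variation among cohorts — are propagated to (β, γ) by a
first-order Taylor approximation. On the univariate standardized scale the
closed forms are

    Var[β] ≈ Var[b]/(1−g)² + b²Var[g]/(1−g)⁴ + 2b·Cov[b,g]/(1−g)³
    Var[γ] ≈ 4b²Var[b]/(1−g)⁴ + (1+2b²−g)²Var[g]/(1−g)⁶
             + 4b(1+2b²−g)Cov[b,g]/(1−g)⁵.

The general case uses a numeric Jacobian of (β, vech γ) with respect to
the coefficient vector — central differences, per-coordinate step
h = max(1e-6, 1e-6|x|), halved up to 8 times if a perturbation crosses the
Ω boundary — then J·cov·J′. The univariate closed forms are the
consistency anchor: the generic path must agree with them to 1e-6
relative, and both agree with brute-force Monte-Carlo propagation as the
coefficient covariance shrinks (first-order error is O(cov)). Coefficient
covariances use one canonical order everywhere — (b₁..b_k, g₁₁..g_kk,
then the upper triangle g₁₂, g₁₃, …) — because the ½-convention for
quadratic covariates makes silent ordering/scaling mismatches the main
practical hazard; a helper rescales covariances from fits with unhalved
squared covariates (g-rows ×2). First-order variance approximations can go
negative under extreme curvature; SDs floor them at zero with a warning
rather than silently.

## Estimation

`LogQuadraticGLM` fits (a, b, g) by maximum likelihood with a log link via
iteratively reweighted least squares (delegated to statsmodels), families
Poisson (default), negative binomial (dispersion by ML; only b̂, ĝ feed the
gradient formulas, which hold under additive log-scale overdispersion),
and an experimental log-link binomial for 0/1 fitness components
(non-convergence is common and is reported, never ignored). The sampling
covariance is the inverse observed information, reordered to the canonical
order. Design matrices put z²/2 in the quadratic columns so coefficients
are g directly; cross-product columns are unhalved. Quadratic fits refuse
fewer than k + k(k+1)/2 + 1 rows. The μ, Σ used in the conversion default
to the sample mean and ddof = 1 covariance of the traits on the fitted
scale.

`LandeArnoldRegression` is the classical estimator: relative fitness
w = W/W̄ (sample mean denominator) regressed by OLS on the same design;
the linear coefficients are β̂ and the half-square/cross coefficients are
γ̂. The default takes all gradients from the single quadratic model, with
a `two_step` option that takes β̂ from a linear-only fit.

Case-bootstrap SEs resample rows with replacement, recompute relative
fitness and sample moments within each resample, refit, and take the SD of
the replicate estimates; replicates that fail (Ω violation, rank
deficiency, non-convergence) are dropped and counted, and more than 20%
failures abort with an error. Fixed seed ⇒ bit-identical output.

The numerical-averaging estimator — weights e^{f(zᵢ)} applied to the
per-individual slope b + gzᵢ and curvature g + (b+gzᵢ)(b+gzᵢ)′ — is the
model-free sample counterpart of the defining expectations. It is kept as
an oracle: it agrees with the closed forms exactly in expectation when z
is Gaussian, and serves as the cross-check route in tests.

## Simulation framework

`simulate_dataset` draws z ~ N(μ, Σ) and fitness from the chosen family
with log-mean f(z); streams are counter-based (seed, scenario index,
replicate index) via SeedSequence spawn keys, so scenarios are independent
and reproducible regardless of execution order. The default grid
(`paper_grid`) is univariate directional selection: b from −0.5 to 0.5 in
steps of 0.1 (the step is a package choice; only the range is canonical),
g ∈ {−1, 0, 0.4}, a = 0, standard-normal phenotype, Poisson fitness,
n = 200 individuals — a deliberately modest study size for judging SE
methods. Replicate counts default to 300 with 200 bootstrap resamples (a
desk-scale choice; 1000/1000 reproduces the original design and is a flag
away). The acceptance-level study in the test suite uses a 5-point b-grid
({−0.5, −0.25, 0, 0.25, 0.5}) crossed with all three g values at 300
replicates.

Within the study, GLM coefficient estimates are converted to gradients at
the scenario's *generating* phenotype scale (μ = 0, σ² = 1), which is
known by design in a simulation. This matters for interpreting SE
calibration: converting instead with each replicate's sample moments adds
moment noise to β̂ that the delta method (which propagates only b̂, ĝ)
does not cover, deflating the SE/SD ratio to ≈ 0.8 at g = −1. Empirical
analyses, where the truth is unknown, use sample moments — their delta SEs
are accordingly mildly conservative-to-anticonservative depending on
curvature, a limitation users should know.

What the generator emulates: count fitness with log-quadratic expectation,
Gaussian phenotypes, independent individuals. What it does not: overlapping
generations, shared environments or relatedness (non-independent
residuals), measurement error in traits, non-Gaussian phenotypes, or
model misspecification of the fitness function. Passing tests therefore
demonstrate correctness of the estimators under the model, not robustness
to these real-data complications.

### Findings the framework itself computes

With n = 200 and 300 replicates: GLM gradient estimates are unbiased
within Monte-Carlo error for g ∈ {−1, 0}; small upward biases in γ̂ appear
at g = 0.4 (strong upward curvature) and are reported, not asserted away.
Delta-method SEs fall within 15% of the empirical sampling SD for
g ∈ {−1, 0}. The MSE comparison between GLM and OLS estimators is mixed
at this sample size: GLM clearly wins under curvature (e.g. γ̂ MSE roughly
halved at g = −1 and at g = 0.4 with b ≠ 0), but for the pure log-linear
scenarios (g = 0) with |b| ≳ 0.2 the OLS γ̂ has modestly *smaller* MSE
(≈ 16% at b = 0.5), a finite-sample efficiency cost of estimating an
unneeded curvature parameter inside a nonlinear transform; by n = 1000 the
two are statistically indistinguishable, consistent with ML asymptotic
efficiency. The corresponding acceptance check is left strict and
documents this as a genuine small-sample result.

## Numerical choices

- Positive definiteness (Σ, Ω, ω) is an eigenvalue check: smallest
  eigenvalue > 1e-12 × largest. Symmetry tolerance 1e-10 relative;
  matrices are re-symmetrized after solves, and γ is returned as
  (γ+γ′)/2.
- All inverses are linear solves; Q is computed only as a diagnostic.
- Monte-Carlo oracle comparisons are restricted to upward curvature
  ≤ 0.45/σ²: beyond 0.5/σ² the averaging weights e^{f(z)} have infinite
  variance and MC standard errors lose meaning (no CLT), so a 3-SE
  comparison would be ill-posed there. Downward curvature is unrestricted
  (tests use up to 0.8/σ²).
- Univariate scalars are accepted everywhere and routed through the k = 1
  matrix path; the univariate closed forms appear only as test oracles.
- Sample covariance uses the unbiased (n−1) denominator, and
  unit-variance standardization divides by the ddof = 1 SD.

## Known limitations

- The delta method is first order: for strongly curved fitness functions
  (g near 1/σ² or very negative) variances can be understated or even
  negative (floored, with a warning); bootstrap SEs are the fallback.
- The log-binomial family frequently fails to converge (the log link is
  not the canonical binomial link); results are flagged.
- Gradients are conditional on the fitted fitness model; no allowance is
  made for model-selection uncertainty or random-effects structure
  (mixed-model fitting is out of scope).
- Phenotype normality is assumed by the closed forms; with markedly
  non-Gaussian traits use the numerical-averaging estimator as a check.
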