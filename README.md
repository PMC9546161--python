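# selgrad

Selection gradients from log-linear and log-quadratic fitness models.

## The problem

Regression-based studies of natural selection summarize a fitness surface
with two evolutionary quantitative-genetic parameters: the directional
selection gradient **β** (the average slope of relative fitness with respect
to phenotype) and the quadratic selection gradient **γ** (the average
curvature). These are classically estimated by ordinary least squares of
relative fitness on trait values — even though fitness components such as
offspring counts or survival are far better described by generalized linear
models (GLMs) with a log link. `selgrad` implements the analytical bridge
between the two worlds: if expected fitness follows the log-quadratic model

    W(z) = exp(a + b′z + ½ z′gz),        z ~ N(μ, Σ),

then the selection gradients have closed forms

    β = (I − gΣ)⁻¹ (b + gμ)              γ = ββ′ + (I − gΣ)⁻¹ g

(univariate, mean-centred, variance-standardized traits: β = b/(1−g),
γ = (b² + g(1−g))/(1−g)²). The post-selection phenotype distribution is
again Gaussian with precision Ω⁻¹ = Σ⁻¹ − g and mean ν = μ + Ω(b+gμ), the
formulas coincide with the classical Gaussian (stabilizing-selection)
expressions β = −S(μ−θ), γ = ββ′ − S when g is negative definite, and they
remain valid for upwardly curved fitness functions as long as Ω is positive
definite (univariate: g < 1/σ²). First-order (delta-method) propagation of
the sampling or biological (co)variances of b and g yields standard errors
— or among-cohort standard deviations — of β and γ.

The package is for evolutionary ecologists and quantitative geneticists who
fit Poisson, negative-binomial, or other log-link fitness models and want
selection gradients, with honest uncertainty, out the other end.

## What is in the box

- `selgrad.core` — closed-form conversions between (a, b, g), (β, γ), the
  post-selection distribution (ν, Ω, mean fitness), and the Gaussian
  optimum/width parameterization (θ, ω); evolutionary response Δz̄ = Gβ.
- `selgrad.uncertainty` — univariate closed-form delta-method variances and
  a generic finite-difference Jacobian propagation for any trait count, in
  one canonical coefficient order (b₁..b_k, g₁₁..g_kk, upper-triangle gᵢⱼ).
- `selgrad.estimators` — scikit-learn style estimators `LogQuadraticGLM`
  (log-link ML fit + gradients + delta SEs) and `LandeArnoldRegression`
  (the classical OLS of relative fitness on the half-quadratic design),
  case-bootstrap SEs, and the model-free numerical-averaging estimator.
- `selgrad.simulate` — seeded synthetic trait–fitness data under the model
  and a replication framework for estimator bias / SE calibration / MSE.
- `selgrad.io` / `selgrad.cli` — CSV/TSV input, JSON reports, and the
  `selgrad` command with `estimate`, `gradients`, and `simulate`
  subcommands.

The quadratic design convention is the half-square one throughout: the
covariate for a quadratic term is z²/2, so its fitted coefficient *is* g
(cross products zᵢzⱼ are not halved). A helper converts covariance matrices
from fits that used unhalved squares.

## Worked example

Selection on lamb birth mass in Soay sheep has been summarized by a
log-quadratic fitness model for lifetime breeding success with log-scale
slope b = 1.07 and curvature g = −0.72 on the standardized trait scale,
with among-cohort (co)variances Var[b] = 0.25, Var[g] = 0.47,
Cov[b, g] = −0.26. Convert to gradients:

```sh
selgrad gradients -b 1.07 -g -0.72 --var-b 0.25 --var-g 0.47 --cov-bg -0.26
```

prints (abridged):

```json
{
  "beta": [0.622093023255814],
  "gamma": [[-0.031604921579232004]],
  "sd_beta": [0.1914208324650232],
  "sd_gamma": [0.3553298404058835],
  "rho_beta_gamma": 0.7638258266324462
}
```

Read: directional selection is strong (β ≈ 0.62 — larger-born lambs have
substantially higher relative fitness per standard deviation of birth
mass), while the *average* quadratic gradient is near zero (γ ≈ −0.03).
The delta-method standard deviations show both gradients vary a lot among
cohorts (σ_β ≈ 0.19, σ_γ ≈ 0.36): quadratic selection is sometimes
convex, sometimes concave, even though it averages out. The same numbers
are available programmatically:

```python
import selgrad as sg

coef = sg.LogQuadraticCoefficients(a=0.0, b=[1.07], g=[[-0.72]])
pheno = sg.PhenotypeDistribution.standardized(1)
sg.compute_beta(coef, pheno)      # array([0.62209302])
```

Fitting from individual records instead:

```python
est = sg.LogQuadraticGLM(family="poisson", standardize="unit_variance")
est.fit(traits, fitness)          # n x k array, length-n counts
est.beta_, est.gamma_             # gradients on the standardized scale
est.uncertainty_.sd_beta()        # delta-method SEs
```

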