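"""Estimation of selection gradients from individual trait-fitness records.

Two regression estimators are provided, both as scikit-learn style
estimator classes:

:class:`LogQuadraticGLM`
    Fits ``E[W | z] = exp(a + b'z + 1/2 z'gz)`` by maximum likelihood with a
    log link (Poisson, negative-binomial, or experimental log-binomial
    family) and converts the coefficients into selection gradients via the
    closed forms, with delta-method standard errors from the inverse
    observed information.

:class:`LandeArnoldRegression`
    The classical OLS regression of relative fitness ``w = W / W-bar`` on
    linear and half-quadratic trait terms; its coefficients are the
    selection gradients directly.

The design-matrix convention is half-quadratic: quadratic covariates enter
as ``z_i^2 / 2`` so that their fitted coefficients are the ``g_ii``
themselves, while cross products ``z_i z_j`` (i < j) are not halved.
Module-level functions (``fit_log_quadratic_glm``, ``ols_lande_arnold``,
``bootstrap_se``, ...) are thin wrappers over the estimator classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from numpy.typing import ArrayLike
from sklearn.base import BaseEstimator

from .core import (
    LogQuadraticCoefficients,
    PhenotypeDistribution,
    SelectionGradients,
    OmegaNotPositiveDefinite,
    compute_gradients,
)
from .uncertainty import (
    CoefficientCovariance,
    GradientUncertainty,
    coefficient_order,
    n_coefficients,
    propagate_multivariate,
)

__all__ = [
    "TraitFitnessTable",
    "GlmFitResult",
    "OlsFitResult",
    "LogQuadraticGLM",
    "LandeArnoldRegression",
    "standardize_traits",
    "build_design_matrix",
    "fit_log_quadratic_glm",
    "gradients_from_fit",
    "ols_lande_arnold",
    "bootstrap_se",
    "numerical_average_estimator",
    "DegenerateTrait",
    "NonConvergence",
    "SeparationOrRankDeficiency",
    "ZeroMeanFitness",
    "RankDeficiency",
    "TooManyFailures",
]

FAMILIES = ("poisson", "negative_binomial", "binomial_log")
STANDARDIZE_MODES = ("none", "center", "unit_variance", "mean_standardize")


class DegenerateTrait(ValueError):
    """A trait has zero variance (or zero mean where mean-standardizing)."""


class NonConvergence(RuntimeError):
    """The iterative fit did not converge."""


class SeparationOrRankDeficiency(ValueError):
    """The design matrix is rank deficient or the likelihood is unbounded."""


class ZeroMeanFitness(ValueError):
    """Sample mean fitness is zero; relative fitness undefined."""


class RankDeficiency(SeparationOrRankDeficiency):
    """OLS design matrix is rank deficient."""


class TooManyFailures(RuntimeError):
    """More than 20% of bootstrap replicates failed to fit."""


@dataclass(frozen=True)
class TraitFitnessTable:
    """Individual-level trait values and absolute fitness records.

    ``traits`` is n x k (trait units); ``fitness`` is a length-n vector of
    non-negative absolute fitness (counts for the Poisson and
    negative-binomial families).
    """

    traits: np.ndarray
    fitness: np.ndarray
    trait_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        traits = np.asarray(self.traits, dtype=float)
        if traits.ndim == 1:
            traits = traits[:, None]
        fitness = np.asarray(self.fitness, dtype=float).ravel()
        if traits.shape[0] != fitness.size:
            raise ValueError(
                f"traits has {traits.shape[0]} rows but fitness has "
                f"{fitness.size} entries")
        if not np.all(np.isfinite(traits)):
            raise ValueError("traits contain non-finite values")
        if not np.all(np.isfinite(fitness)):
            raise ValueError("fitness contains non-finite values")
        if np.any(fitness < 0):
            raise ValueError("fitness must be non-negative")
        names = tuple(self.trait_names) or tuple(
            f"z{i + 1}" for i in range(traits.shape[1]))
        if len(names) != traits.shape[1]:
            raise ValueError("trait_names length does not match trait count")
        object.__setattr__(self, "traits", traits)
        object.__setattr__(self, "fitness", fitness)
        object.__setattr__(self, "trait_names", names)

    @property
    def n(self) -> int:
        return self.traits.shape[0]

    @property
    def k(self) -> int:
        return self.traits.shape[1]

    def sample_phenotype(self) -> PhenotypeDistribution:
        """Sample mean and covariance (ddof = 1) of the traits."""
        mu = self.traits.mean(axis=0)
        if self.n < 2:
            raise ValueError("need at least 2 rows for a sample covariance")
        sigma = np.cov(self.traits, rowvar=False, ddof=1)
        return PhenotypeDistribution(mu=mu, sigma=np.atleast_2d(sigma))


@dataclass(frozen=True)
class GlmFitResult:
    """Log-link GLM fit: coefficients, their sampling covariance (canonical
    order), the family, and the standardization applied to the traits."""

    coef: LogQuadraticCoefficients
    sampling_cov: CoefficientCovariance
    family: str
    converged: bool
    center: np.ndarray
    scale: np.ndarray
    pheno: PhenotypeDistribution  # sample mean/cov of the fitted-scale traits

    @property
    def standardization(self) -> tuple[np.ndarray, np.ndarray]:
        return self.center, self.scale


@dataclass(frozen=True)
class OlsFitResult:
    """Lande-Arnold OLS fit of relative fitness on the quadratic design."""

    beta_hat: np.ndarray
    gamma_hat: np.ndarray
    se_beta: np.ndarray
    se_gamma: np.ndarray  # distinct elements: diagonal then upper triangle
    intercept: float
    relative_fitness_mean: float = 1.0


def standardize_traits(table: TraitFitnessTable, mode: str = "none",
                       ) -> tuple[TraitFitnessTable, np.ndarray, np.ndarray]:
    """Standardize trait columns; returns (table, center, scale).

    Modes: ``none``; ``center`` (subtract the mean); ``unit_variance``
    (center then divide by the ddof = 1 sample SD); ``mean_standardize``
    (divide by the mean, no centering).  Downstream gradients are on the
    transformed scale; the returned center/scale allow back-transformation
    ``z_raw = z * scale + center``.
    """
    if mode not in STANDARDIZE_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {STANDARDIZE_MODES}")
    k = table.k
    center = np.zeros(k)
    scale = np.ones(k)
    if mode in ("center", "unit_variance"):
        center = table.traits.mean(axis=0)
    if mode == "unit_variance":
        scale = table.traits.std(axis=0, ddof=1)
        if np.any(scale <= 0):
            raise DegenerateTrait("a trait has zero variance")
    elif mode == "mean_standardize":
        scale = table.traits.mean(axis=0)
        if np.any(scale == 0):
            raise DegenerateTrait("a trait has zero mean; cannot mean-standardize")
    new = TraitFitnessTable(
        traits=(table.traits - center) / scale,
        fitness=table.fitness,
        trait_names=table.trait_names,
    )
    return new, center, scale


def build_design_matrix(traits: ArrayLike, include_quadratic: bool = True,
                        trait_names: tuple[str, ...] | None = None,
                        ) -> tuple[np.ndarray, list[str]]:
    """Regression design matrix with the half-quadratic convention.

    Columns: intercept, the k linear traits, the k halved squares
    ``z_i^2/2``, then cross products ``z_i z_j`` (i < j, not halved).  The
    non-intercept columns follow the canonical coefficient order, so the
    fitted coefficients line up with :class:`CoefficientCovariance`.
    """
    z = np.asarray(traits, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if not np.all(np.isfinite(z)):
        raise ValueError("traits contain non-finite values")
    n, k = z.shape
    names = list(trait_names) if trait_names else [f"z{i + 1}" for i in range(k)]
    cols = [np.ones(n)]
    labels = ["intercept"]
    for i in range(k):
        cols.append(z[:, i])
        labels.append(names[i])
    if include_quadratic:
        for i in range(k):
            cols.append(0.5 * z[:, i] ** 2)
            labels.append(f"{names[i]}^2/2")
        for i in range(k):
            for j in range(i + 1, k):
                cols.append(z[:, i] * z[:, j])
                labels.append(f"{names[i]}*{names[j]}")
    return np.column_stack(cols), labels


def _coef_from_params(params: np.ndarray, k: int,
                      include_quadratic: bool) -> LogQuadraticCoefficients:
    a = params[0]
    b = params[1:1 + k]
    g = np.zeros((k, k))
    if include_quadratic:
        diag = params[1 + k:1 + 2 * k]
        np.fill_diagonal(g, diag)
        pos = 1 + 2 * k
        for i in range(k):
            for j in range(i + 1, k):
                g[i, j] = g[j, i] = params[pos]
                pos += 1
    return LogQuadraticCoefficients(a=a, b=b, g=g)


class LogQuadraticGLM(BaseEstimator):
    """Maximum-likelihood log-quadratic fitness model and selection gradients.

    Fits ``E[W | z] = exp(a + b'z + 1/2 z'gz)`` by IRLS (via statsmodels)
    under a log-link family, then converts ``(b, g)`` to the directional and
    quadratic selection gradients with delta-method standard errors.

    Parameters
    ----------
    family : {"poisson", "negative_binomial", "binomial_log"}
        Fitness distribution.  ``binomial_log`` (a log-link binomial for 0/1
        fitness components) is experimental: the log link is not the
        canonical binomial link and non-convergence is common; failures are
        reported, never silently ignored.
    include_quadratic : bool
        If False, fit the log-linear model (g = 0), under which beta = b.
    standardize : {"none", "center", "unit_variance", "mean_standardize"}
        Trait standardization applied before fitting; gradients are on the
        standardized scale.

    Attributes
    ----------
    coef_ : LogQuadraticCoefficients
        Fitted (a, b, g).
    sampling_cov_ : CoefficientCovariance
        Inverse observed information of (b, g), canonical order.
    beta_, gamma_ : ndarray
        Selection gradients (set only when the post-selection covariance
        condition holds; see ``omega_valid_``).
    uncertainty_ : GradientUncertainty
        Delta-method (co)variances of the gradients.
    pheno_ : PhenotypeDistribution
        Sample mean/covariance of the (standardized) traits used in the
        conversion.
    converged_ : bool
    omega_valid_ : bool
    center_, scale_ : ndarray
        Standardization record.
    """

    def __init__(self, family: str = "poisson", include_quadratic: bool = True,
                 standardize: str = "none"):
        self.family = family
        self.include_quadratic = include_quadratic
        self.standardize = standardize

    # -- internal ----------------------------------------------------------
    def _fit_family(self, X: np.ndarray, y: np.ndarray):
        """Returns (params, cov_params, converged)."""
        if self.family == "poisson":
            model = sm.GLM(y, X, family=sm.families.Poisson())
            res = model.fit(maxiter=100)
            return res.params, res.cov_params(), bool(res.converged)
        if self.family == "negative_binomial":
            # dispersion (alpha) estimated by ML; last parameter is alpha
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.NegativeBinomial(y, X)
                res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            return res.params[:-1], res.cov_params()[:-1, :-1], converged
        if self.family == "binomial_log":
            if not np.all(np.isin(y, (0.0, 1.0))):
                raise ValueError("binomial_log requires 0/1 fitness values")
            model = sm.GLM(y, X, family=sm.families.Binomial(
                link=sm.families.links.Log()))
            # log-binomial likelihoods are awkward; start near the mean
            start = np.zeros(X.shape[1])
            start[0] = np.log(max(y.mean(), 1e-8))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(start_params=start, maxiter=200)
            if not res.converged:
                warnings.warn("log-binomial fit did not converge; coefficients "
                              "are reported but flagged", RuntimeWarning)
            return res.params, res.cov_params(), bool(res.converged)
        raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: ArrayLike, y: ArrayLike) -> "LogQuadraticGLM":
        """Fit to trait matrix ``X`` (n x k) and absolute fitness ``y``."""
        table = TraitFitnessTable(traits=np.asarray(X, dtype=float),
                                  fitness=np.asarray(y, dtype=float))
        if self.family in ("poisson", "negative_binomial"):
            if not np.allclose(table.fitness, np.round(table.fitness)):
                raise ValueError(
                    f"{self.family} family requires integer-valued fitness counts")
        if self.include_quadratic:
            min_rows = n_coefficients(table.k) + 1
            if table.n < min_rows:
                raise ValueError(
                    f"quadratic fit needs at least {min_rows} rows for "
                    f"k={table.k}; got {table.n}")
        table, center, scale = standardize_traits(table, self.standardize)
        self.n_features_in_ = table.k
        self.center_ = center
        self.scale_ = scale

        design, labels = build_design_matrix(
            table.traits, self.include_quadratic, table.trait_names)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise SeparationOrRankDeficiency(
                "design matrix is rank deficient; check for constant or "
                "collinear traits")
        params, cov, converged = self._fit_family(design, table.fitness)
        if not converged:
            warnings.warn("GLM did not converge; result flagged", RuntimeWarning)
        self.converged_ = converged
        self.coef_ = _coef_from_params(np.asarray(params), table.k,
                                       self.include_quadratic)
        cov = np.asarray(cov)
        if self.include_quadratic:
            cov_bg = cov[1:, 1:]  # drop intercept; columns already canonical
        else:
            p = n_coefficients(table.k)
            full = np.zeros((p, p))
            full[:table.k, :table.k] = cov[1:, 1:]
            cov_bg = full
        self.sampling_cov_ = CoefficientCovariance(cov_bg)
        self.coef_labels_ = coefficient_order(table.k)
        self.design_labels_ = labels
        self.pheno_ = table.sample_phenotype()

        try:
            sg = compute_gradients(self.coef_, self.pheno_)
            self.omega_valid_ = True
            self.beta_ = sg.beta
            self.gamma_ = sg.gamma
            self.gradients_ = sg
            self.uncertainty_ = propagate_multivariate(
                self.coef_, self.pheno_, self.sampling_cov_)
        except OmegaNotPositiveDefinite:
            self.omega_valid_ = False
        return self

    def predict(self, X: ArrayLike) -> np.ndarray:
        """Expected absolute fitness at new phenotypes (original scale)."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted")
        z = np.asarray(X, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        z = (z - self.center_) / self.scale_
        return self.coef_.fitness(z)

    def result(self) -> GlmFitResult:
        """Immutable record of the fit (coefficients + sampling covariance)."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted")
        return GlmFitResult(
            coef=self.coef_, sampling_cov=self.sampling_cov_,
            family=self.family, converged=self.converged_,
            center=self.center_, scale=self.scale_, pheno=self.pheno_)


class LandeArnoldRegression(BaseEstimator):
    """Lande-Arnold OLS selection-gradient regression.

    Regresses relative fitness ``w_i = W_i / W-bar`` on the half-quadratic
    design; the linear coefficients are ``beta`` and the half-square /
    cross-product coefficients are ``gamma`` directly.

    Parameters
    ----------
    include_quadratic : bool
        Fit the quadratic surface (default) or the linear-only model.
    two_step : bool
        If True, take beta from a separate linear-only regression (the
        original two-model protocol); gamma still comes from the quadratic
        model.  Default False: all gradients from the single quadratic model.

    Attributes
    ----------
    beta_, gamma_ : selection-gradient estimates
    se_beta_, se_gamma_ : analytic OLS standard errors (se_gamma_ covers the
        distinct gamma elements, diagonal first then upper triangle)
    intercept_ : fitted intercept of the relative-fitness regression
    """

    def __init__(self, include_quadratic: bool = True, two_step: bool = False):
        self.include_quadratic = include_quadratic
        self.two_step = two_step

    @staticmethod
    def _ols(design: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, p = design.shape
        if np.linalg.matrix_rank(design) < p:
            raise RankDeficiency("OLS design matrix is rank deficient")
        coefs, _, _, _ = np.linalg.lstsq(design, w, rcond=None)
        resid = w - design @ coefs
        dof = n - p
        if dof > 0:
            s2 = resid @ resid / dof
            cov = s2 * np.linalg.inv(design.T @ design)
            se = np.sqrt(np.diag(cov))
        else:
            se = np.full(p, np.nan)
        return coefs, se

    def fit(self, X: ArrayLike, y: ArrayLike) -> "LandeArnoldRegression":
        table = TraitFitnessTable(traits=np.asarray(X, dtype=float),
                                  fitness=np.asarray(y, dtype=float))
        wbar = table.fitness.mean()
        if wbar <= 0:
            raise ZeroMeanFitness("sample mean fitness must be positive")
        w = table.fitness / wbar
        self.n_features_in_ = table.k
        k = table.k
        design, labels = build_design_matrix(
            table.traits, self.include_quadratic, table.trait_names)
        coefs, se = self._ols(design, w)
        self.intercept_ = float(coefs[0])
        self.design_labels_ = labels
        beta = coefs[1:1 + k]
        se_beta = se[1:1 + k]
        if self.include_quadratic:
            m = k * (k + 1) // 2
            gvals = coefs[1 + k:1 + k + m]
            self.se_gamma_ = se[1 + k:1 + k + m]
            gamma = np.zeros((k, k))
            np.fill_diagonal(gamma, gvals[:k])
            pos = k
            for i in range(k):
                for j in range(i + 1, k):
                    gamma[i, j] = gamma[j, i] = gvals[pos]
                    pos += 1
        else:
            gamma = np.zeros((k, k))
            self.se_gamma_ = np.zeros(k * (k + 1) // 2)
        if self.two_step and self.include_quadratic:
            lin_design, _ = build_design_matrix(table.traits, False,
                                                table.trait_names)
            lin_coefs, lin_se = self._ols(lin_design, w)
            beta = lin_coefs[1:1 + k]
            se_beta = lin_se[1:1 + k]
        self.beta_ = beta
        self.se_beta_ = se_beta
        self.gamma_ = gamma
        return self

    def predict(self, X: ArrayLike) -> np.ndarray:
        """Fitted relative fitness at new phenotypes."""
        if not hasattr(self, "beta_"):
            raise RuntimeError("estimator is not fitted")
        z = np.asarray(X, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        return (self.intercept_ + z @ self.beta_
                + 0.5 * np.einsum("ni,ij,nj->n", z, self.gamma_, z))

    def result(self) -> OlsFitResult:
        if not hasattr(self, "beta_"):
            raise RuntimeError("estimator is not fitted")
        return OlsFitResult(beta_hat=self.beta_, gamma_hat=self.gamma_,
                            se_beta=self.se_beta_, se_gamma=self.se_gamma_,
                            intercept=self.intercept_)


# -- module-level wrappers -------------------------------------------------

def fit_log_quadratic_glm(table: TraitFitnessTable, family: str = "poisson",
                          include_quadratic: bool = True,
                          standardize: str = "none") -> GlmFitResult:
    """Fit the log-quadratic GLM to a trait-fitness table (see
    :class:`LogQuadraticGLM`)."""
    est = LogQuadraticGLM(family=family, include_quadratic=include_quadratic,
                          standardize=standardize)
    est.fit(table.traits, table.fitness)
    return est.result()


def gradients_from_fit(fit: GlmFitResult,
                       pheno: PhenotypeDistribution | None = None,
                       ) -> tuple[SelectionGradients, GradientUncertainty]:
    """Selection gradients and delta-method uncertainty from a GLM fit.

    ``pheno`` defaults to the sample mean/covariance of the traits on the
    fitted (standardized) scale, recorded in the fit.
    """
    pheno = pheno if pheno is not None else fit.pheno
    try:
        sg = compute_gradients(fit.coef, pheno)
    except OmegaNotPositiveDefinite as err:
        raise OmegaNotPositiveDefinite(
            f"{err}  The fitted coefficients (b, g) are still interpretable "
            "as a fitness-function estimate; report them together with the "
            "failed condition rather than gradients.") from err
    gu = propagate_multivariate(fit.coef, pheno, fit.sampling_cov)
    return sg, gu


def ols_lande_arnold(table: TraitFitnessTable,
                     include_quadratic: bool = True,
                     two_step: bool = False) -> OlsFitResult:
    """Lande-Arnold OLS regression of relative fitness on the quadratic
    design (see :class:`LandeArnoldRegression`)."""
    est = LandeArnoldRegression(include_quadratic=include_quadratic,
                                two_step=two_step)
    est.fit(table.traits, table.fitness)
    return est.result()


def _gradient_vector_glm(table: TraitFitnessTable, family: str,
                         standardize: str) -> np.ndarray:
    fit = fit_log_quadratic_glm(table, family=family, standardize=standardize)
    sg, _ = gradients_from_fit(fit)
    k = table.k
    gam = [sg.gamma[i, i] for i in range(k)]
    gam += [sg.gamma[i, j] for i in range(k) for j in range(i + 1, k)]
    return np.concatenate([sg.beta, gam])


def _gradient_vector_ols(table: TraitFitnessTable) -> np.ndarray:
    res = ols_lande_arnold(table)
    k = table.k
    gam = [res.gamma_hat[i, i] for i in range(k)]
    gam += [res.gamma_hat[i, j] for i in range(k) for j in range(i + 1, k)]
    return np.concatenate([res.beta_hat, gam])


@dataclass(frozen=True)
class BootstrapResult:
    """Case-bootstrap standard errors per gradient (beta components then
    distinct gamma elements, canonical order)."""

    se: np.ndarray
    labels: tuple[str, ...]
    n_requested: int
    n_failed: int


def bootstrap_se(table: TraitFitnessTable, estimator: str = "ols",
                 b_reps: int = 1000, seed: int = 0, family: str = "poisson",
                 standardize: str = "none") -> BootstrapResult:
    """Case-bootstrap standard errors of the selection gradients.

    Resamples rows with replacement ``b_reps`` times, refits the chosen
    estimator (``ols`` or ``glm``), and returns the SD of the replicate
    gradient estimates.  Relative fitness and the sample phenotype moments
    are recomputed within each resample.  Replicates that fail (e.g. the
    GLM post-selection covariance condition is violated) are dropped and
    counted; more than 20% failures raises :class:`TooManyFailures`.
    """
    if b_reps < 2:
        raise ValueError("b_reps must be at least 2")
    if estimator not in ("ols", "glm"):
        raise ValueError("estimator must be 'ols' or 'glm'")
    rng = np.random.default_rng(seed)
    n = table.n
    estimates = []
    n_failed = 0
    for _ in range(b_reps):
        idx = rng.integers(0, n, size=n)
        sub = TraitFitnessTable(traits=table.traits[idx],
                                fitness=table.fitness[idx],
                                trait_names=table.trait_names)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if estimator == "ols":
                    estimates.append(_gradient_vector_ols(sub))
                else:
                    estimates.append(
                        _gradient_vector_glm(sub, family, standardize))
        except (OmegaNotPositiveDefinite, SeparationOrRankDeficiency,
                ZeroMeanFitness, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > 0.2 * b_reps:
        raise TooManyFailures(
            f"{n_failed}/{b_reps} bootstrap replicates failed")
    est = np.asarray(estimates)
    se = est.std(axis=0, ddof=1)
    k = table.k
    labels = tuple(f"beta_{nm}" for nm in table.trait_names)
    labels += tuple(f"gamma_{table.trait_names[i]}{table.trait_names[i]}"
                    for i in range(k))
    labels += tuple(f"gamma_{table.trait_names[i]}{table.trait_names[j]}"
                    for i in range(k) for j in range(i + 1, k))
    return BootstrapResult(se=se, labels=labels, n_requested=b_reps,
                           n_failed=n_failed)


def numerical_average_estimator(table: TraitFitnessTable,
                                coef: LogQuadraticCoefficients,
                                ) -> SelectionGradients:
    """Model-free numerical-averaging estimator of the gradients.

    Averages the slope and curvature of ``W(z) = exp(f(z))`` over the
    observed phenotypes, normalized by the average fitness::

        beta  = mean_i[(b + g z_i) W(z_i)] / mean_i[W(z_i)]
        gamma = mean_i[(g + (b+g z_i)(b+g z_i)') W(z_i)] / mean_i[W(z_i)]

    Exact sample counterpart of the defining expectations; used as an
    oracle for the closed forms (the two agree as the sample grows when
    ``z`` is Gaussian).
    """
    if coef.k != table.k:
        raise ValueError(f"coefficient k={coef.k} but table has k={table.k}")
    z = table.traits
    logw = coef.log_fitness(z)
    logw = logw - logw.max()  # stabilize; constant cancels in the ratio
    w = np.exp(logw)
    u = coef.b + z @ coef.g  # rows: b + g z_i
    wbar = w.mean()
    beta = (u * w[:, None]).mean(axis=0) / wbar
    outer = np.einsum("ni,nj,n->ij", u, u, w) / z.shape[0]
    gamma = (coef.g * wbar + outer) / wbar
    gamma = 0.5 * (gamma + gamma.T)
    q = np.eye(table.k)
    return SelectionGradients(beta=beta, gamma=gamma, q=q, valid=True)
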