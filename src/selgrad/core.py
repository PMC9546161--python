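"""Closed-form selection gradients for log-quadratic fitness functions.

The fitness model is ``W(z) = exp(f(z))`` with ``f(z) = a + b'z + 1/2 z'gz``,
where ``z`` is a k-trait phenotype assumed multivariate normal with mean
``mu`` and covariance ``sigma`` before selection.  Under that assumption the
directional and quadratic selection gradients have closed forms

    beta  = (I - g Sigma)^{-1} (b + g mu)
    gamma = beta beta' + (I - g Sigma)^{-1} g

and the post-selection phenotype distribution is again Gaussian with
precision ``Omega^{-1} = Sigma^{-1} - g`` and mean
``nu = mu + Omega (b + g mu)``.  When ``g`` is negative definite the model
is an unnormalized Gaussian fitness function with optimum ``theta = -g^{-1}b``
and width ``omega = (-g)^{-1}``, and the gradients coincide with the
classical stabilizing-selection expressions ``beta = -S(mu - theta)``,
``gamma = beta beta' - S`` with ``S = (omega + Sigma)^{-1}``.

All operations accept scalars for the univariate case and route them
through the same k = 1 matrix code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "PhenotypeDistribution",
    "LogQuadraticCoefficients",
    "SelectionGradients",
    "PostSelectionDistribution",
    "GaussianFitnessParams",
    "compute_beta",
    "compute_gamma",
    "compute_gradients",
    "post_selection_distribution",
    "gradients_from_gaussian",
    "gaussian_from_coefficients",
    "predict_response",
    "OmegaNotPositiveDefinite",
    "NotGaussianRepresentable",
    "NotPositiveDefinite",
    "DimensionMismatch",
]

# relative eigenvalue floor for "positive definite"
_PD_RTOL = 1e-12
_SYM_RTOL = 1e-10


class NotPositiveDefinite(ValueError):
    """A matrix required to be positive definite is not."""


class OmegaNotPositiveDefinite(NotPositiveDefinite):
    """The post-selection precision ``Sigma^{-1} - g`` is not positive
    definite: the fitness function curves upward too sharply relative to the
    phenotypic variance (univariate condition ``g < 1/sigma^2``)."""


class NotGaussianRepresentable(ValueError):
    """``g`` has a non-negative eigenvalue, so the fitness function has no
    interior maximum and no Gaussian (optimum/width) parameterization."""


class DimensionMismatch(ValueError):
    """Vector/matrix dimensions do not agree."""


def _as_vector(x: ArrayLike, name: str = "vector") -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.ndim != 1:
        raise DimensionMismatch(f"{name} must be one-dimensional, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite entries")
    return v


def _as_matrix(x: ArrayLike, k: int, name: str = "matrix") -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim == 0:
        m = m.reshape(1, 1)
    if m.shape != (k, k):
        raise DimensionMismatch(f"{name} must be {k}x{k}, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError(f"{name} contains non-finite entries")
    return m


def _check_symmetric(m: np.ndarray, name: str) -> np.ndarray:
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > _SYM_RTOL * scale:
        raise ValueError(f"{name} is not symmetric")
    return 0.5 * (m + m.T)


def _check_positive_definite(m: np.ndarray, name: str,
                             exc: type = NotPositiveDefinite) -> None:
    w = np.linalg.eigvalsh(m)
    if w[0] <= _PD_RTOL * max(w[-1], 0.0) or w[-1] <= 0:
        raise exc(f"{name} is not positive definite "
                  f"(eigenvalue range [{w[0]:.3e}, {w[-1]:.3e}])")


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Pre-selection phenotype distribution: ``z ~ N(mu, sigma)``.

    Parameters
    ----------
    mu : array-like, shape (k,) or scalar
        Trait means, in trait units (zero for centred traits).
    sigma : array-like, shape (k, k) or scalar
        Phenotypic covariance matrix; must be symmetric positive definite.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = _as_vector(self.mu, "mu")
        sigma = _as_matrix(self.sigma, mu.size, "sigma")
        sigma = _check_symmetric(sigma, "sigma")
        _check_positive_definite(sigma, "sigma")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def k(self) -> int:
        return self.mu.size

    @classmethod
    def standardized(cls, k: int = 1) -> "PhenotypeDistribution":
        """Standard phenotype scale: mu = 0, sigma = identity."""
        return cls(np.zeros(k), np.eye(k))


@dataclass(frozen=True)
class LogQuadraticCoefficients:
    """Coefficients of the log-scale fitness function
    ``f(z) = a + b'z + 1/2 z'gz``.

    ``g`` holds the quadratic coefficients on its diagonal and the
    correlational coefficients off-diagonal; it must be symmetric.  With the
    half-quadratic design-matrix convention (``z_i^2/2`` columns) the fitted
    GLM coefficients are exactly ``(a, b, g)``.
    """

    a: float
    b: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        a = float(self.a)
        if not np.isfinite(a):
            raise ValueError("a must be finite")
        b = _as_vector(self.b, "b")
        g = _as_matrix(self.g, b.size, "g")
        g = _check_symmetric(g, "g")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "g", g)

    @property
    def k(self) -> int:
        return self.b.size

    def log_fitness(self, z: ArrayLike) -> np.ndarray:
        """Evaluate ``f(z)`` at one or more phenotypes (rows of ``z``)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return self.a + z @ self.b + 0.5 * np.einsum("ni,ij,nj->n", z, self.g, z)

    def fitness(self, z: ArrayLike) -> np.ndarray:
        """Expected absolute fitness ``W(z) = exp(f(z))``."""
        return np.exp(self.log_fitness(z))


@dataclass(frozen=True)
class SelectionGradients:
    """Directional (``beta``) and quadratic (``gamma``) selection gradients.

    ``q`` is the diagnostic matrix ``Q = (I - g Sigma)^{-1}``; ``valid``
    records that the post-selection covariance condition held.
    """

    beta: np.ndarray
    gamma: np.ndarray
    q: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid: bool = True

    def __post_init__(self) -> None:
        beta = _as_vector(self.beta, "beta")
        gamma = _as_matrix(self.gamma, beta.size, "gamma")
        gamma = _check_symmetric(gamma, "gamma")
        q = self.q if self.q is not None else np.eye(beta.size)
        q = _as_matrix(q, beta.size, "q")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "q", q)

    @property
    def k(self) -> int:
        return self.beta.size


@dataclass(frozen=True)
class PostSelectionDistribution:
    """Post-selection phenotype distribution ``N(nu, omega)`` and mean
    fitness ``W-bar = E[W(z)]``."""

    nu: np.ndarray
    omega: np.ndarray
    mean_fitness: float

    def __post_init__(self) -> None:
        nu = _as_vector(self.nu, "nu")
        omega = _as_matrix(self.omega, nu.size, "omega")
        omega = _check_symmetric(omega, "omega")
        _check_positive_definite(omega, "omega", OmegaNotPositiveDefinite)
        if not (np.isfinite(self.mean_fitness) and self.mean_fitness > 0):
            raise ValueError("mean_fitness must be a positive real")
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "mean_fitness", float(self.mean_fitness))


@dataclass(frozen=True)
class GaussianFitnessParams:
    """Gaussian fitness function ``W(z) ∝ exp(-1/2 (z-theta)' omega_w^{-1}
    (z-theta))`` with optimum ``theta`` and width matrix ``omega_w``.

    ``s_matrix`` caches ``S = (omega_w + Sigma)^{-1}`` when constructed with
    a phenotype distribution; it is derived, not independent input.
    """

    theta: np.ndarray
    omega_w: np.ndarray
    s_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        theta = _as_vector(self.theta, "theta")
        omega_w = _as_matrix(self.omega_w, theta.size, "omega_w")
        omega_w = _check_symmetric(omega_w, "omega_w")
        _check_positive_definite(omega_w, "omega_w")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "omega_w", omega_w)
        if self.s_matrix is not None:
            object.__setattr__(
                self, "s_matrix", _as_matrix(self.s_matrix, theta.size, "s_matrix"))

    @property
    def k(self) -> int:
        return self.theta.size


def _omega_precision(coef: LogQuadraticCoefficients,
                     pheno: PhenotypeDistribution) -> np.ndarray:
    """Post-selection precision ``Omega^{-1} = Sigma^{-1} - g``, validated."""
    if coef.k != pheno.k:
        raise DimensionMismatch(
            f"coefficients have k={coef.k} but phenotype has k={pheno.k}")
    prec = np.linalg.inv(pheno.sigma) - coef.g
    prec = 0.5 * (prec + prec.T)
    _check_positive_definite(prec, "Omega^{-1} = Sigma^{-1} - g",
                             OmegaNotPositiveDefinite)
    return prec


def compute_gradients(coef: LogQuadraticCoefficients,
                      pheno: PhenotypeDistribution) -> SelectionGradients:
    """Selection gradients for a log-quadratic fitness function.

    Returns ``beta = Q(b + g mu)`` and ``gamma = beta beta' + Qg`` with
    ``Q = (I - g Sigma)^{-1}``, the multivariate generalization of the
    univariate standardized shortcuts ``beta = b/(1-g)`` and
    ``gamma = (b^2 + g(1-g))/(1-g)^2``.

    Raises
    ------
    OmegaNotPositiveDefinite
        If ``Sigma^{-1} - g`` is not positive definite (fitness curving
        upward too sharply; univariate ``g >= 1/sigma^2``).
    """
    _omega_precision(coef, pheno)
    k = coef.k
    iminus = np.eye(k) - coef.g @ pheno.sigma
    rhs = coef.b + coef.g @ pheno.mu
    beta = np.linalg.solve(iminus, rhs)
    q = np.linalg.solve(iminus, np.eye(k))
    gamma = np.outer(beta, beta) + np.linalg.solve(iminus, coef.g)
    gamma = 0.5 * (gamma + gamma.T)
    return SelectionGradients(beta=beta, gamma=gamma, q=q, valid=True)


def compute_beta(coef: LogQuadraticCoefficients,
                 pheno: PhenotypeDistribution) -> np.ndarray:
    """Directional selection gradient ``beta = (I - g Sigma)^{-1}(b + g mu)``."""
    return compute_gradients(coef, pheno).beta


def compute_gamma(coef: LogQuadraticCoefficients,
                  pheno: PhenotypeDistribution) -> np.ndarray:
    """Quadratic selection gradient ``gamma = beta beta' + (I-g Sigma)^{-1} g``,
    symmetrized."""
    return compute_gradients(coef, pheno).gamma


def _mvn_logpdf(z: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    k = mean.size
    diff = z - mean
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise NotPositiveDefinite("covariance has non-positive determinant")
    maha = diff @ np.linalg.solve(cov, diff)
    return -0.5 * (k * np.log(2.0 * np.pi) + logdet + maha)


def post_selection_distribution(
        coef: LogQuadraticCoefficients,
        pheno: PhenotypeDistribution) -> PostSelectionDistribution:
    """Post-selection phenotype distribution and mean fitness.

    The selected density ``K(z) = W(z) p(z) / W-bar`` is again Gaussian with
    precision ``Omega^{-1} = Sigma^{-1} - g`` and mean
    ``nu = mu + Omega(b + g mu)``.  Mean fitness follows from the pointwise
    identity ``W-bar = W(z) p_{mu,Sigma}(z) / p_{nu,Omega}(z)``, evaluated
    at ``z = mu`` (the ratio is constant in z).
    """
    prec = _omega_precision(coef, pheno)
    omega = np.linalg.solve(prec, np.eye(coef.k))
    omega = 0.5 * (omega + omega.T)
    nu = pheno.mu + omega @ (coef.b + coef.g @ pheno.mu)
    log_wbar = (coef.log_fitness(pheno.mu)[0]
                + _mvn_logpdf(pheno.mu, pheno.mu, pheno.sigma)
                - _mvn_logpdf(pheno.mu, nu, omega))
    return PostSelectionDistribution(nu=nu, omega=omega,
                                     mean_fitness=float(np.exp(log_wbar)))


def gaussian_from_coefficients(
        coef: LogQuadraticCoefficients) -> GaussianFitnessParams:
    """Optimum/width parameterization of a concave log-quadratic fitness
    function: ``omega = (-g)^{-1}``, ``theta = -g^{-1} b``.

    Raises
    ------
    NotGaussianRepresentable
        If ``g`` has any non-negative eigenvalue (no interior maximum).
    """
    w = np.linalg.eigvalsh(coef.g)
    if w[-1] >= 0:
        raise NotGaussianRepresentable(
            f"g has a non-negative eigenvalue ({w[-1]:.3e}); the fitness "
            "function has no interior maximum")
    omega_w = np.linalg.solve(-coef.g, np.eye(coef.k))
    omega_w = 0.5 * (omega_w + omega_w.T)
    theta = np.linalg.solve(-coef.g, coef.b)
    return GaussianFitnessParams(theta=theta, omega_w=omega_w)


def gradients_from_gaussian(gauss: GaussianFitnessParams,
                            pheno: PhenotypeDistribution) -> SelectionGradients:
    """Selection gradients under a Gaussian fitness function:
    ``beta = -S(mu - theta)``, ``gamma = beta beta' - S`` with
    ``S = (omega + Sigma)^{-1}``."""
    if gauss.k != pheno.k:
        raise DimensionMismatch(
            f"Gaussian params have k={gauss.k} but phenotype has k={pheno.k}")
    total = gauss.omega_w + pheno.sigma
    _check_positive_definite(total, "omega + Sigma")
    s = np.linalg.solve(total, np.eye(gauss.k))
    s = 0.5 * (s + s.T)
    beta = -s @ (pheno.mu - gauss.theta)
    gamma = np.outer(beta, beta) - s
    gamma = 0.5 * (gamma + gamma.T)
    # Q is a log-quadratic-side diagnostic; reconstruct it from g = -omega^{-1}
    g = -np.linalg.solve(gauss.omega_w, np.eye(gauss.k))
    q = np.linalg.solve(np.eye(gauss.k) - g @ pheno.sigma, np.eye(gauss.k))
    return SelectionGradients(beta=beta, gamma=gamma, q=q, valid=True)


def predict_response(beta: ArrayLike, g_matrix: ArrayLike) -> np.ndarray:
    """Predicted per-generation response of trait means to directional
    selection, ``delta z-bar = G beta``, with ``G`` the additive genetic
    covariance matrix."""
    beta = _as_vector(beta, "beta")
    g_matrix = _as_matrix(g_matrix, beta.size, "G")
    return g_matrix @ beta
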