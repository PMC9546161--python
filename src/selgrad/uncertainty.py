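"""Delta-method propagation of coefficient (co)variances into selection
gradients.

Biological (among-replicate) or sampling (co)variances of the log-scale
coefficients ``b`` and ``g`` are propagated into variances and covariances
of ``beta`` and ``gamma`` by a first-order Taylor approximation.  The
univariate standardized case (``mu = 0``, ``sigma^2 = 1``) has closed
forms::

    Var[beta]  ~  Var[b]/(1-g)^2 + b^2 Var[g]/(1-g)^4 + 2 b Cov[b,g]/(1-g)^3
    Var[gamma] ~  4 b^2 Var[b]/(1-g)^4 + (1 + 2b^2 - g)^2 Var[g]/(1-g)^6
                  + 4 b (1 + 2b^2 - g) Cov[b,g]/(1-g)^5

The general multivariate case uses a numeric central-difference Jacobian of
``(beta, vech gamma)`` with respect to the coefficient vector; the closed
forms above serve as the univariate consistency anchor.

Coefficient (co)variance matrices use one canonical parameter order
throughout the package: ``(b_1..b_k, g_11..g_kk, g_12, g_13, ...,
g_{k-1,k})`` — linear terms, then quadratic diagonals, then the upper
triangle row-major.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike

from .core import (
    LogQuadraticCoefficients,
    PhenotypeDistribution,
    OmegaNotPositiveDefinite,
    compute_gradients,
)

__all__ = [
    "CoefficientCovariance",
    "GradientUncertainty",
    "var_beta_univariate",
    "var_gamma_univariate",
    "propagate_multivariate",
    "corr_beta_gamma_univariate",
    "convert_unhalved_covariance",
    "coefficient_order",
    "InvalidCurvature",
    "DegenerateVariance",
    "JacobianFailure",
    "NegativeVarianceWarning",
]


class InvalidCurvature(ValueError):
    """Univariate curvature ``g >= 1`` on the standardized scale."""


class DegenerateVariance(ValueError):
    """A propagated variance needed for a correlation is zero."""


class JacobianFailure(RuntimeError):
    """Finite-difference perturbations kept violating the post-selection
    covariance condition even after repeated step halving."""


class NegativeVarianceWarning(UserWarning):
    """First-order approximation returned a negative variance."""


def coefficient_order(k: int) -> list[str]:
    """Canonical parameter labels for a k-trait coefficient covariance:
    ``b1..bk``, then ``g11..gkk``, then upper-triangle ``gij`` row-major."""
    labels = [f"b{i + 1}" for i in range(k)]
    labels += [f"g{i + 1}{i + 1}" for i in range(k)]
    labels += [f"g{i + 1}{j + 1}" for i in range(k) for j in range(i + 1, k)]
    return labels


def n_coefficients(k: int) -> int:
    """Number of (b, g) coefficients for k traits: k + k(k+1)/2."""
    return k + k * (k + 1) // 2


@dataclass(frozen=True)
class CoefficientCovariance:
    """Symmetric PSD (co)variance matrix of the ``(b, g)`` coefficients in
    canonical order (see :func:`coefficient_order`).

    May hold biological variation (among cohorts, populations, ...) or
    sampling variances from a fitted model; the propagation is identical.
    """

    cov: np.ndarray

    def __post_init__(self) -> None:
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise ValueError(f"cov must be square, got shape {cov.shape}")
        scale = max(np.abs(cov).max(), 1.0)
        if np.abs(cov - cov.T).max() > 1e-10 * scale:
            raise ValueError("cov is not symmetric")
        cov = 0.5 * (cov + cov.T)
        w = np.linalg.eigvalsh(cov)
        if w[0] < -1e-10 * max(w[-1], 1e-300):
            raise ValueError(
                f"cov is not positive semidefinite (min eigenvalue {w[0]:.3e})")
        object.__setattr__(self, "cov", cov)

    @property
    def p(self) -> int:
        return self.cov.shape[0]

    @property
    def k(self) -> int:
        """Trait count implied by p = k + k(k+1)/2."""
        p = self.p
        k = int(round((-3 + np.sqrt(9 + 8 * p)) / 2))
        if n_coefficients(k) != p:
            raise ValueError(f"cov dimension {p} does not match any trait count")
        return k

    @classmethod
    def univariate(cls, var_b: float, var_g: float,
                   cov_bg: float = 0.0) -> "CoefficientCovariance":
        """Convenience constructor for the k = 1 case (order: b, g)."""
        return cls(np.array([[var_b, cov_bg], [cov_bg, var_g]]))


@dataclass(frozen=True)
class GradientUncertainty:
    """Propagated (co)variances of the selection gradients.

    ``var_beta`` is the k x k covariance of ``beta``; ``var_gamma`` the
    m x m covariance of the distinct elements of ``gamma`` (m = k(k+1)/2,
    diagonal first then upper triangle row-major, mirroring the coefficient
    order); ``cov_beta_gamma`` the k x m cross-block.
    """

    var_beta: np.ndarray
    var_gamma: np.ndarray
    cov_beta_gamma: np.ndarray

    def __post_init__(self) -> None:
        vb = np.atleast_2d(np.asarray(self.var_beta, dtype=float))
        vg = np.atleast_2d(np.asarray(self.var_gamma, dtype=float))
        cbg = np.atleast_2d(np.asarray(self.cov_beta_gamma, dtype=float))
        object.__setattr__(self, "var_beta", vb)
        object.__setattr__(self, "var_gamma", vg)
        object.__setattr__(self, "cov_beta_gamma", cbg)

    @property
    def k(self) -> int:
        return self.var_beta.shape[0]

    def sd_beta(self) -> np.ndarray:
        """Standard deviations of beta; negative first-order variances are
        floored at zero with a warning."""
        return _sd_from_var(np.diag(self.var_beta))

    def sd_gamma(self) -> np.ndarray:
        """Standard deviations of the distinct gamma elements (diagonal
        first, then upper triangle)."""
        return _sd_from_var(np.diag(self.var_gamma))


def _sd_from_var(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        warnings.warn(
            "first-order variance approximation is negative; flooring at 0",
            NegativeVarianceWarning, stacklevel=3)
    return np.sqrt(np.clip(v, 0.0, None))


def _univariate_cc(cc: CoefficientCovariance) -> tuple[float, float, float]:
    if cc.p != 2:
        raise ValueError("univariate formulas require a 2x2 (b, g) covariance")
    return cc.cov[0, 0], cc.cov[1, 1], cc.cov[0, 1]


def var_beta_univariate(b: float, g: float, cc: CoefficientCovariance) -> float:
    """First-order variance of ``beta = b/(1-g)`` on the standardized scale
    (mu = 0, sigma^2 = 1).

    May return a small negative value for extreme curvature; callers that
    need an SD should floor at zero (see :meth:`GradientUncertainty.sd_beta`).
    """
    if g >= 1:
        raise InvalidCurvature(f"g = {g} >= 1: invalid on the standardized scale")
    var_b, var_g, cov_bg = _univariate_cc(cc)
    om = 1.0 - g
    return (var_b / om ** 2
            + b ** 2 * var_g / om ** 4
            + 2.0 * b * cov_bg / om ** 3)


def var_gamma_univariate(b: float, g: float, cc: CoefficientCovariance) -> float:
    """First-order variance of ``gamma = (b^2 + g(1-g))/(1-g)^2`` on the
    standardized scale (mu = 0, sigma^2 = 1)."""
    if g >= 1:
        raise InvalidCurvature(f"g = {g} >= 1: invalid on the standardized scale")
    var_b, var_g, cov_bg = _univariate_cc(cc)
    om = 1.0 - g
    c = 1.0 + 2.0 * b ** 2 - g
    return (4.0 * b ** 2 * var_b / om ** 4
            + c ** 2 * var_g / om ** 6
            + 4.0 * b * c * cov_bg / om ** 5)


def _pack_tri_indices(k: int) -> list[tuple[int, int]]:
    """(i, j) index pairs in canonical order: diagonal, then upper triangle
    row-major."""
    idx = [(i, i) for i in range(k)]
    idx += [(i, j) for i in range(k) for j in range(i + 1, k)]
    return idx


def _vector_to_coef(x: np.ndarray, k: int, a: float) -> LogQuadraticCoefficients:
    b = x[:k]
    g = np.zeros((k, k))
    for pos, (i, j) in enumerate(_pack_tri_indices(k)):
        g[i, j] = x[k + pos]
        g[j, i] = x[k + pos]
    return LogQuadraticCoefficients(a=a, b=b, g=g)


def coef_to_vector(coef: LogQuadraticCoefficients) -> np.ndarray:
    """Flatten (b, g) into the canonical parameter order."""
    k = coef.k
    parts = [coef.b]
    parts.append(np.array([coef.g[i, j] for (i, j) in _pack_tri_indices(k)]))
    return np.concatenate(parts)


def _gradients_vector(x: np.ndarray, k: int, a: float,
                      pheno: PhenotypeDistribution) -> np.ndarray:
    """Map coefficient vector -> (beta, distinct gamma elements)."""
    coef = _vector_to_coef(x, k, a)
    sg = compute_gradients(coef, pheno)
    gam = np.array([sg.gamma[i, j] for (i, j) in _pack_tri_indices(k)])
    return np.concatenate([sg.beta, gam])


def propagate_multivariate(coef: LogQuadraticCoefficients,
                           pheno: PhenotypeDistribution,
                           cc: CoefficientCovariance) -> GradientUncertainty:
    """General first-order propagation ``J cov J'`` with a numeric Jacobian.

    ``J`` is the Jacobian of ``(beta, vech gamma)`` with respect to the
    coefficient vector, by central finite differences with per-coordinate
    step ``h = max(1e-6, 1e-6 |x|)``.  If a perturbed point violates the
    post-selection covariance condition, the step is halved (up to 8 times)
    before failing.

    Raises
    ------
    OmegaNotPositiveDefinite
        If the condition fails at the point estimate itself.
    JacobianFailure
        If a perturbation cannot be made valid by step halving.
    """
    k = coef.k
    if cc.p != n_coefficients(k):
        raise ValueError(
            f"cov dimension {cc.p} does not match k={k} "
            f"(expected {n_coefficients(k)})")
    x0 = coef_to_vector(coef)
    # validates the Omega condition at the point estimate
    _gradients_vector(x0, k, coef.a, pheno)

    p = x0.size
    m = k * (k + 1) // 2
    jac = np.empty((k + m, p))
    for i in range(p):
        h = max(1e-6, 1e-6 * abs(x0[i]))
        for _ in range(9):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            try:
                fp = _gradients_vector(xp, k, coef.a, pheno)
                fm = _gradients_vector(xm, k, coef.a, pheno)
            except OmegaNotPositiveDefinite:
                h *= 0.5
                continue
            jac[:, i] = (fp - fm) / (2.0 * h)
            break
        else:
            raise JacobianFailure(
                f"could not find a valid finite-difference step for "
                f"coordinate {i} after 8 halvings")

    full = jac @ cc.cov @ jac.T
    full = 0.5 * (full + full.T)
    return GradientUncertainty(
        var_beta=full[:k, :k],
        var_gamma=full[k:, k:],
        cov_beta_gamma=full[:k, k:],
    )


def corr_beta_gamma_univariate(b: float, g: float,
                               cc: CoefficientCovariance) -> float:
    """Correlation between beta and gamma induced by (co)variation in
    (b, g), univariate standardized scale; from the cross-block of the
    general propagation."""
    coef = LogQuadraticCoefficients(a=0.0, b=np.array([b]),
                                    g=np.array([[g]]))
    gu = propagate_multivariate(coef, PhenotypeDistribution.standardized(1), cc)
    vb = gu.var_beta[0, 0]
    vg = gu.var_gamma[0, 0]
    if vb <= 0 or vg <= 0:
        raise DegenerateVariance(
            f"propagated variances must be positive (got {vb:.3e}, {vg:.3e})")
    rho = gu.cov_beta_gamma[0, 0] / np.sqrt(vb * vg)
    return float(np.clip(rho, -1.0, 1.0))


def convert_unhalved_covariance(cc: CoefficientCovariance,
                                k: int) -> CoefficientCovariance:
    """Rescale a coefficient covariance from a fit whose squared covariates
    were *not* halved.

    In that parameterization the quadratic-diagonal coefficients estimate
    ``g_ii / 2``, so mapping to the half-quadratic convention doubles those
    rows and columns (variances x4, covariances with other terms x2).
    Cross-product (correlational) columns are unaffected.
    """
    if cc.p != n_coefficients(k):
        raise ValueError(f"cov dimension {cc.p} does not match k={k}")
    scale = np.ones(cc.p)
    scale[k:2 * k] = 2.0  # the g_ii block
    return CoefficientCovariance(cc.cov * np.outer(scale, scale))
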