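"""Shared fixtures: random valid model instances.

Random (coefficients, phenotype) pairs are drawn so that the
post-selection covariance condition holds with margin: the spectral radius
of ``Sigma^{1/2} g Sigma^{1/2}`` is kept at or below 0.8, which also keeps
Monte-Carlo weights ``exp(f(z))`` well behaved.
"""

import numpy as np
import pytest

from selgrad import LogQuadraticCoefficients, PhenotypeDistribution


def random_phenotype(rng: np.random.Generator, k: int,
                     standardized: bool = False) -> PhenotypeDistribution:
    if standardized:
        return PhenotypeDistribution.standardized(k)
    mu = rng.normal(0.0, 1.0, k)
    a = rng.normal(size=(k, k))
    sigma = a @ a.T / k + 0.5 * np.eye(k)
    return PhenotypeDistribution(mu=mu, sigma=sigma)


def random_coefficients(rng: np.random.Generator,
                        pheno: PhenotypeDistribution,
                        max_curvature: float = 0.8,
                        max_upward: float | None = None,
                        negative_definite: bool = False,
                        ) -> LogQuadraticCoefficients:
    """Random (a, b, g) valid for `pheno` (Omega positive definite).

    ``max_upward`` optionally caps the largest *positive* whitened
    eigenvalue separately: Monte-Carlo weights exp(f(z)) only have finite
    variance (hence a CLT) when the upward curvature is below 0.5/sigma^2,
    so oracle comparisons need a stricter cap on that side.
    """
    k = pheno.k
    b = rng.normal(0.0, 0.5, k)
    g0 = rng.normal(size=(k, k))
    g0 = 0.5 * (g0 + g0.T)
    if negative_definite:
        g0 = -(g0 @ g0.T + 0.1 * np.eye(k))
    # scale so the whitened curvature Sigma^{1/2} g Sigma^{1/2} is tame
    w, v = np.linalg.eigh(pheno.sigma)
    root = v @ np.diag(np.sqrt(w)) @ v.T
    eigs = np.linalg.eigvalsh(root @ g0 @ root)
    scale = max_curvature / max(np.abs(eigs).max(), 1e-12)
    if max_upward is not None and eigs.max() > 0:
        scale = min(scale, max_upward / eigs.max())
    scale *= rng.uniform(0.3, 1.0)
    return LogQuadraticCoefficients(a=rng.normal(0, 0.5), b=b, g=g0 * scale)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
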