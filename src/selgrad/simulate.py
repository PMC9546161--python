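"""Seeded synthetic data under the log-quadratic fitness model and a
replication framework for the estimator-performance study.

Datasets are generated with multivariate-normal phenotypes and fitness
drawn from a log-link family (Poisson by default) with expectation
``exp(a + b'z + 1/2 z'gz)``.  :func:`run_study` fits the Lande-Arnold OLS
and the log-quadratic GLM estimators to many replicate datasets and
summarizes bias, empirical sampling SD, the mean of each standard-error
type (analytic OLS, case bootstrap, delta method), and mean squared error.

The default grid (:func:`paper_grid`) covers univariate directional
selection with log-scale slopes ``b`` from -0.5 to 0.5 (step 0.1) crossed
with curvatures ``g`` in {-1, 0, 0.4}, a = 0, standard-normal phenotype,
Poisson fitness and n = 200 individuals per dataset.

Randomness is counter-based: the stream for a replicate derives from
``(seed, scenario_index, replicate_index)`` via ``numpy`` ``SeedSequence``
spawn keys, so scenarios are independent and order-insensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    LogQuadraticCoefficients,
    PhenotypeDistribution,
    OmegaNotPositiveDefinite,
    compute_gradients,
    _omega_precision,
)
from .estimators import (
    TraitFitnessTable,
    LandeArnoldRegression,
    LogQuadraticGLM,
    SeparationOrRankDeficiency,
    ZeroMeanFitness,
    bootstrap_se,
    gradients_from_fit,
)

__all__ = ["SimulationScenario", "StudyResult", "simulate_dataset",
           "run_study", "paper_grid"]


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design.

    Rejected at construction if the post-selection covariance condition
    fails for (g, Sigma) — such a fitness function has no finite mean
    fitness under the phenotype distribution.
    """

    n: int
    a: float
    b: np.ndarray
    g: np.ndarray
    pheno: PhenotypeDistribution
    family: str = "poisson"
    reps: int = 300
    boot_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        coef = LogQuadraticCoefficients(a=self.a, b=self.b, g=self.g)
        _omega_precision(coef, self.pheno)  # raises if invalid
        object.__setattr__(self, "b", coef.b)
        object.__setattr__(self, "g", coef.g)
        if self.n < 1 or self.reps < 1:
            raise ValueError("n and reps must be positive")

    @property
    def coef(self) -> LogQuadraticCoefficients:
        return LogQuadraticCoefficients(a=self.a, b=self.b, g=self.g)

    @property
    def k(self) -> int:
        return self.b.size

    def true_gradients(self) -> np.ndarray:
        """(beta, distinct gamma) under the scenario's true parameters."""
        sg = compute_gradients(self.coef, self.pheno)
        k = self.k
        gam = [sg.gamma[i, i] for i in range(k)]
        gam += [sg.gamma[i, j] for i in range(k) for j in range(i + 1, k)]
        return np.concatenate([sg.beta, gam])

    def label(self) -> str:
        if self.k == 1:
            return f"b={self.b[0]:g},g={self.g[0, 0]:g},n={self.n}"
        return f"k={self.k},n={self.n}"


def _rng_for(seed: int, scenario_index: int, replicate_index: int,
             ) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(scenario_index, replicate_index))
    return np.random.default_rng(ss)


def simulate_dataset(scenario: SimulationScenario, replicate_index: int = 0,
                     scenario_index: int = 0) -> TraitFitnessTable:
    """Draw one dataset: ``z ~ N(mu, Sigma)`` and fitness from the scenario
    family with log-scale mean ``a + b'z + 1/2 z'gz``.  Fully determined by
    ``(seed, scenario_index, replicate_index)``."""
    rng = _rng_for(scenario.seed, scenario_index, replicate_index)
    z = rng.multivariate_normal(scenario.pheno.mu, scenario.pheno.sigma,
                                size=scenario.n)
    lam = scenario.coef.fitness(z)
    if scenario.family == "poisson":
        w = rng.poisson(lam).astype(float)
    elif scenario.family == "negative_binomial":
        # additive log-scale overdispersion, variance lam + lam^2/2
        shape = 2.0
        w = rng.poisson(rng.gamma(shape, lam / shape)).astype(float)
    elif scenario.family == "binomial_log":
        p = np.clip(lam, 0.0, 1.0)
        w = rng.binomial(1, p).astype(float)
    else:
        raise ValueError(f"unknown family {scenario.family!r}")
    return TraitFitnessTable(traits=z, fitness=w)


def _grad_labels(k: int) -> list[str]:
    labels = [f"beta_{i + 1}" for i in range(k)]
    labels += [f"gamma_{i + 1}{i + 1}" for i in range(k)]
    labels += [f"gamma_{i + 1}{j + 1}" for i in range(k)
               for j in range(i + 1, k)]
    return labels


@dataclass(frozen=True)
class StudyResult:
    """Tidy summary of an estimator-performance study.

    ``summary``: one row per scenario x estimator x gradient with columns
    for the mean estimate, bias, empirical SD, mean analytic / bootstrap /
    delta SE, MSE, their Monte-Carlo standard errors, and failure counts.
    ``raw`` keeps the per-replicate estimates (NaN where a replicate
    failed) keyed by ``(scenario_index, estimator)`` for paired
    comparisons.
    """

    summary: pd.DataFrame
    raw: dict = field(repr=False, default_factory=dict)

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False)


def _nan_summary(est: np.ndarray, ses: dict[str, np.ndarray],
                 truth: np.ndarray) -> list[dict]:
    """Summaries per gradient component from a (reps x q) estimate array."""
    rows = []
    q = truth.size
    for j in range(q):
        col = est[:, j]
        ok = np.isfinite(col)
        m = int(ok.sum())
        vals = col[ok]
        row: dict = {"n_ok": m, "n_failed": int((~ok).sum())}
        if m == 0:
            rows.append(row)
            continue
        err = vals - truth[j]
        row["mean_estimate"] = vals.mean()
        row["bias"] = err.mean()
        row["mse"] = float(np.mean(err ** 2))
        if m > 1:
            row["empirical_sd"] = vals.std(ddof=1)
            row["mc_se_mean"] = row["empirical_sd"] / np.sqrt(m)
            row["mc_se_mse"] = float(np.std(err ** 2, ddof=1) / np.sqrt(m))
        else:
            row["empirical_sd"] = np.nan
            row["mc_se_mean"] = np.nan
            row["mc_se_mse"] = np.nan
        for name, se_arr in ses.items():
            se_col = se_arr[:, j]
            se_ok = np.isfinite(se_col)
            row[f"mean_{name}_se"] = (se_col[se_ok].mean()
                                      if se_ok.any() else np.nan)
        rows.append(row)
    return rows


def run_study(scenarios: list[SimulationScenario],
              do_bootstrap: bool = False,
              progress: bool = False) -> StudyResult:
    """Fit OLS and GLM estimators to every replicate of every scenario and
    aggregate their performance.

    Per-replicate failures (non-convergence, post-selection covariance
    violations) are dropped from summaries and counted, never fatal.
    Bootstrap SEs (``do_bootstrap=True``) use each scenario's ``boot_reps``
    and add substantial cost; the analytic-OLS and delta-method SE columns
    are always produced.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    all_rows = []
    raw: dict = {}
    for s_idx, sc in enumerate(scenarios):
        truth = sc.true_gradients()
        q = truth.size
        labels = _grad_labels(sc.k)
        ols_est = np.full((sc.reps, q), np.nan)
        glm_est = np.full((sc.reps, q), np.nan)
        ols_se = np.full((sc.reps, q), np.nan)
        boot_se = np.full((sc.reps, q), np.nan)
        delta_se = np.full((sc.reps, q), np.nan)
        glm_fail = ols_fail = 0
        for r in range(sc.reps):
            table = simulate_dataset(sc, replicate_index=r,
                                     scenario_index=s_idx)
            # OLS (Lande-Arnold)
            try:
                ols = LandeArnoldRegression().fit(table.traits, table.fitness)
                ols_est[r] = np.concatenate([ols.beta_, _distinct(ols.gamma_)])
                ols_se[r] = np.concatenate([ols.se_beta_, ols.se_gamma_])
            except (ZeroMeanFitness, SeparationOrRankDeficiency,
                    np.linalg.LinAlgError):
                ols_fail += 1
            if do_bootstrap:
                try:
                    br = bootstrap_se(table, estimator="ols",
                                      b_reps=sc.boot_reps,
                                      seed=_boot_seed(sc.seed, s_idx, r))
                    boot_se[r] = br.se
                except Exception:
                    pass
            # GLM; the coefficient-to-gradient conversion uses the
            # scenario's generating phenotype scale (known by design in a
            # simulation), so the delta SEs answer for all the estimation
            # noise.  Empirical analyses use sample moments instead (the
            # default of gradients_from_fit).
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    glm = LogQuadraticGLM(family=sc.family).fit(
                        table.traits, table.fitness)
                    fit = glm.result()
                    sg, gu = gradients_from_fit(fit, sc.pheno)
                if not glm.converged_:
                    glm_fail += 1
                else:
                    glm_est[r] = np.concatenate([sg.beta, _distinct(sg.gamma)])
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        delta_se[r] = np.concatenate(
                            [gu.sd_beta(), gu.sd_gamma()])
            except (SeparationOrRankDeficiency, OmegaNotPositiveDefinite,
                    ValueError, np.linalg.LinAlgError):
                glm_fail += 1
        raw[(s_idx, "ols")] = ols_est
        raw[(s_idx, "glm")] = glm_est
        base = {"scenario": sc.label(), "scenario_index": s_idx,
                "n": sc.n, "reps": sc.reps}
        if sc.k == 1:
            base["b"] = sc.b[0]
            base["g"] = sc.g[0, 0]
        for est_name, est_arr, ses, failed in (
                ("ols", ols_est,
                 {"analytic": ols_se, "bootstrap": boot_se}, ols_fail),
                ("glm", glm_est, {"delta": delta_se}, glm_fail)):
            comp_rows = _nan_summary(est_arr, ses, truth)
            for j, row in enumerate(comp_rows):
                row.update(base)
                row["estimator"] = est_name
                row["gradient"] = labels[j]
                row["truth"] = truth[j]
                all_rows.append(row)
        if progress:
            print(f"scenario {s_idx + 1}/{len(scenarios)} "
                  f"({sc.label()}): glm failures {glm_fail}, "
                  f"ols failures {ols_fail}")
    front = ["scenario", "scenario_index", "estimator", "gradient", "truth"]
    summary = pd.DataFrame(all_rows)
    summary = summary[front + [c for c in summary.columns if c not in front]]
    return StudyResult(summary=summary, raw=raw)


def _distinct(gamma: np.ndarray) -> np.ndarray:
    k = gamma.shape[0]
    vals = [gamma[i, i] for i in range(k)]
    vals += [gamma[i, j] for i in range(k) for j in range(i + 1, k)]
    return np.asarray(vals)


def _boot_seed(seed: int, scenario_index: int, replicate_index: int) -> int:
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(scenario_index, replicate_index, 1))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def paper_grid(n: int = 200, reps: int = 300, boot_reps: int = 200,
               seed: int = 0,
               b_values: np.ndarray | None = None,
               g_values: np.ndarray | None = None,
               ) -> list[SimulationScenario]:
    """Default univariate study grid: log-scale slopes b from -0.5 to 0.5
    in steps of 0.1 crossed with curvatures g in {-1, 0, 0.4}; a = 0,
    standard-normal phenotype, Poisson fitness.

    Scenarios with ``g >= 1/sigma^2`` are invalid and raise at
    construction.
    """
    if b_values is None:
        b_values = np.round(np.arange(-0.5, 0.51, 0.1), 10)
    if g_values is None:
        g_values = np.array([-1.0, 0.0, 0.4])
    pheno = PhenotypeDistribution.standardized(1)
    scenarios = []
    for g in g_values:
        for b in b_values:
            scenarios.append(SimulationScenario(
                n=n, a=0.0, b=np.array([float(b)]),
                g=np.array([[float(g)]]), pheno=pheno,
                reps=reps, boot_reps=boot_reps, seed=seed))
    return scenarios
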