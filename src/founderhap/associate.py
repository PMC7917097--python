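"""MCMC-BayesB GWAS with a polygenic random effect and permutation thresholds.

Model: ``y = mu + X beta + u + e`` with per-column inclusion indicators
``delta_j ~ Bernoulli(pi)``, effect variances ``sigma_j^2 ~
scaled-inv-chi-square(v_beta, S_beta2)``, residual variance
``sigma_e^2 ~ scaled-inv-chi-square(v_e, S_e2)`` (the default v_e = -2,
S_e2 = 0 is the flat improper prior) and a polygenic effect ``u ~
N(0, G sigma_u^2)`` sampled via the eigendecomposition of the genomic
relationship matrix G (to absorb genetic stratification).  Defaults:
v_beta = 4, S_beta2 = 0.004, pi = 0.002 (about 20 expected nonzero
markers at p = 10,000), 50,000 cycles with 20,000 burn-in.

The per-marker association statistic ("gamma") is the posterior inclusion
frequency across post-burn-in samples.  Significance thresholds come from
permutation: y is permuted ``n_perm`` times (default 100), the sampler is
refit, and the threshold is the 99th percentile of the pooled gamma
values.  Per-locus contributions to phenotypic variance are the empirical
variance of the locus genotypic value divided by the variance of y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import bayesb_mcmc_kernel
from .features import GRM, DesignMatrix

logger = logging.getLogger(__name__)


@dataclass
class GWASConfig:
    v_beta: float = 4.0
    S_beta2: float = 0.004
    v_e: float = -2.0
    S_e2: float = 0.0
    pi: float = 0.002
    lambda_expected: float | None = 20.0
    n_cycles: int = 50_000
    burn_in: int = 20_000
    n_perm: int = 100
    perm_percentile: float = 99.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi <= 1.0:
            raise ValueError("pi must lie in (0, 1]")
        if self.burn_in >= self.n_cycles:
            raise ValueError("burn_in must be smaller than n_cycles")
        if not 0.0 < self.perm_percentile < 100.0:
            raise ValueError("perm_percentile must lie in (0, 100)")

    def scaled_down(self) -> "GWASConfig":
        """Desk-scale test profile: 5,000/2,000 cycles, 20 permutations."""
        return GWASConfig(
            v_beta=self.v_beta,
            S_beta2=self.S_beta2,
            v_e=self.v_e,
            S_e2=self.S_e2,
            pi=self.pi,
            lambda_expected=self.lambda_expected,
            n_cycles=5_000,
            burn_in=2_000,
            n_perm=20,
            perm_percentile=self.perm_percentile,
            seed=self.seed,
        )


@dataclass
class GWASFit:
    gamma: np.ndarray  # posterior inclusion frequency per column
    effects: np.ndarray  # posterior mean of delta_j * beta_j
    polygenic_mean: np.ndarray
    intercept: float
    residual_var: float
    polygenic_var: float
    column_keys: list | None = None


@dataclass
class GWASResult:
    fit: GWASFit
    threshold: float | None
    significant: np.ndarray | None
    permutation_gammas: np.ndarray | None = None


def _prep(X, y, G: GRM | None):
    if isinstance(X, DesignMatrix):
        values, keys = np.asfortranarray(X.values, dtype=np.float64), X.column_keys()
    else:
        values, keys = np.asfortranarray(np.asarray(X, dtype=np.float64)), None
    y = np.asarray(y, dtype=np.float64)
    if len(y) != values.shape[0]:
        raise ValueError("y must match the rows of X")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if G is None:
        Q = np.zeros((values.shape[0], 0))
        lam = np.zeros(0)
    else:
        Gm = np.asarray(G.matrix, dtype=np.float64)
        if Gm.shape != (values.shape[0], values.shape[0]):
            raise ValueError("G must be n x n, conformable with X")
        evals, evecs = np.linalg.eigh((Gm + Gm.T) / 2.0)
        if evals.min() < -1e-8:
            logger.warning(
                "G is not positive semidefinite (min eigenvalue %.3g); clipping at 0",
                evals.min(),
            )
        keep = evals > 1e-10
        lam = np.ascontiguousarray(evals[keep])
        Q = np.ascontiguousarray(evecs[:, keep])
    return values, y, Q, lam, keys


def fit_bayesb_mcmc(X, y, G: GRM | None, cfg: GWASConfig | None = None) -> GWASFit:
    """Run the Gibbs sampler; reproducible given ``cfg.seed``."""
    cfg = cfg or GWASConfig()
    values, y, Q, lam, keys = _prep(X, y, G)
    if cfg.lambda_expected is not None:
        expected = cfg.pi * values.shape[1]
        if not 0.2 <= (expected / cfg.lambda_expected if cfg.lambda_expected else 1.0) <= 5.0:
            logger.warning(
                "pi * p = %.2f is far from the expected nonzero-marker count %.1f",
                expected,
                cfg.lambda_expected,
            )
    gamma, effects, u_mean, mu, sige, sigu, ok = bayesb_mcmc_kernel(
        values,
        y,
        Q,
        lam,
        cfg.v_beta,
        cfg.S_beta2,
        cfg.v_e,
        cfg.S_e2,
        cfg.pi,
        cfg.n_cycles,
        cfg.burn_in,
        cfg.seed,
    )
    if not ok:
        raise RuntimeError("MCMC residual variance diverged")
    return GWASFit(gamma, effects, u_mean, float(mu), float(sige), float(sigu), keys)


def permutation_threshold(
    X, y, G: GRM | None, cfg: GWASConfig | None = None
) -> tuple[float, np.ndarray]:
    """Permutation significance threshold for the gamma statistic.

    For each of ``n_perm`` permutations of y (X and G fixed) the sampler
    is refit and every marker's gamma collected; the threshold is the
    ``perm_percentile``-th percentile of the pooled values.
    """
    cfg = cfg or GWASConfig()
    y = np.asarray(y, dtype=np.float64)
    if np.var(y) == 0:
        raise ValueError("constant y: permutation threshold is degenerate")
    if cfg.n_perm < 10:
        logger.warning("n_perm = %d gives an unstable percentile estimate", cfg.n_perm)
    rng = np.random.default_rng(cfg.seed)
    pooled = []
    for k in range(cfg.n_perm):
        y_perm = y[rng.permutation(len(y))]
        sub = GWASConfig(**{**cfg.__dict__, "seed": int(rng.integers(2**31 - 1))})
        sub.n_perm = cfg.n_perm  # irrelevant for the fit itself
        fit = fit_bayesb_mcmc(X, y_perm, G, sub)
        pooled.append(fit.gamma)
    pooled = np.concatenate(pooled)
    return float(np.percentile(pooled, cfg.perm_percentile)), pooled


def run_gwas(X, y, G: GRM | None, cfg: GWASConfig | None = None) -> GWASResult:
    """Fit + permutation threshold + significance flags."""
    cfg = cfg or GWASConfig()
    fit = fit_bayesb_mcmc(X, y, G, cfg)
    threshold, pooled = permutation_threshold(X, y, G, cfg)
    return GWASResult(fit, threshold, fit.gamma > threshold, pooled)


def locus_contribution(X_locus, effects, y) -> float:
    """Share of phenotypic variance explained by one locus:
    ``var(X_locus @ effects) / var(y)``, clipped to [0, 1]."""
    y = np.asarray(y, dtype=np.float64)
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("var(y) is zero")
    g = np.asarray(X_locus, dtype=np.float64) @ np.asarray(effects, dtype=np.float64)
    return float(np.clip(np.var(g) / var_y, 0.0, 1.0))


def gwas_table(result: GWASResult, meta) -> "object":
    """GWAS results table: one row per column with gamma, effect, flag."""
    import pandas as pd

    df = pd.DataFrame(meta).copy()
    df["gamma"] = result.fit.gamma
    df["effect"] = result.fit.effects
    df["significant"] = result.significant if result.significant is not None else False
    df["threshold"] = result.threshold
    return df
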