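"""Bayesian fine-mapping of TWAS signal at a locus.

Given m TWAS z-scores at a region, the m x p prediction weight matrix W and
the p x p reference LD matrix V, the z-scores are modelled as

    z | c ~ N(0, Sigma D_c Sigma + Sigma),   D_c = diag(sigma_alpha^2 * c),

where Sigma is the correlation of predicted expression (W V W' rescaled to
unit diagonal) and c is a binary causal-configuration vector.  Exhaustive
enumeration over configurations with an independent Bernoulli(theta) prior
yields the posterior per configuration, marginal posterior inclusion
probabilities (PIPs) per gene, and rho-level credible gene sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def predicted_expression_corr(W: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Correlation of predicted expression: S (W V W') S with unit diagonal."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    V = np.asarray(V, dtype=float)
    G = W @ V @ W.T
    d = np.diag(G)
    if np.any(d <= 0):
        raise ValueError("gene with non-positive predicted-expression "
                         "variance (w V w' <= 0)")
    s = 1.0 / np.sqrt(d)
    sigma = G * np.outer(s, s)
    np.fill_diagonal(sigma, 1.0)
    return (sigma + sigma.T) / 2


def config_loglik(z: np.ndarray, Sigma: np.ndarray, c: np.ndarray,
                  sigma2_alpha: float, ridge: float = 1e-8) -> float:
    """Log N(z; 0, Sigma D_c Sigma + Sigma) with a small diagonal ridge."""
    z = np.asarray(z, dtype=float)
    c = np.asarray(c, dtype=float)
    D = np.diag(sigma2_alpha * c)
    cov = Sigma @ D @ Sigma + Sigma
    cov = cov + ridge * np.eye(len(z))
    try:
        return float(stats.multivariate_normal.logpdf(
            z, mean=np.zeros(len(z)), cov=cov, allow_singular=True))
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance not PSD after ridge") from e


def empirical_sigma2_alpha(z: np.ndarray, floor: float = 1e-3) -> float:
    """Plug-in prior effect variance: locus mean chi-square minus 1.

    Under a single causal gene with unit-diagonal Sigma, E[z_i^2] is
    1 + sigma2_alpha, so the locus mean chi-square anchors the prior scale.
    """
    chi2 = np.mean(np.asarray(z, dtype=float) ** 2)
    return float(max(chi2 - 1.0, floor))


@dataclass
class LocusModel:
    """A fine-mapping locus: TWAS z-scores plus the predicted-expression
    correlation (given directly or derived from W and V)."""

    genes: list[str]
    z: np.ndarray
    Sigma: np.ndarray | None = None
    W: np.ndarray | None = None
    V: np.ndarray | None = None
    sigma2_alpha: float | None = None  # None -> empirical plug-in
    theta: float | None = None  # None -> 1/m
    include_null: bool = True

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        m = len(self.genes)
        if len(self.z) != m:
            raise ValueError("genes / z length mismatch")
        if self.Sigma is None:
            if self.W is None or self.V is None:
                raise ValueError("provide Sigma or both W and V")
            self.Sigma = predicted_expression_corr(self.W, self.V)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (m, m):
            raise ValueError("Sigma shape mismatch")
        if not np.allclose(np.diag(self.Sigma), 1.0, atol=1e-6):
            raise ValueError("Sigma must have unit diagonal")


@dataclass
class FineMapResult:
    """Configuration posterior table, per-gene PIPs and the credible set."""

    genes: list[str]
    pip: pd.Series
    config_table: pd.DataFrame  # config, n_causal, loglik, log_prior, posterior
    credible: list[str] = field(default_factory=list)
    rho: float = 0.9
    sigma2_alpha: float = np.nan
    theta: float = np.nan


def enumerate_posterior(locus: LocusModel, k_max: int | None = None
                        ) -> FineMapResult:
    """Exhaustive posterior over causal configurations.

    Prior: independent Bernoulli(theta) per gene.  Configurations with more
    than ``k_max`` causal genes can be excluded; the posterior is normalized
    over whatever set is enumerated.  PIP_i sums the posterior of every
    configuration with gene i causal.
    """
    m = len(locus.genes)
    if m > 16 and k_max is None:
        raise ValueError("m > 16 requires k_max to restrict enumeration")
    theta = locus.theta if locus.theta is not None else 1.0 / m
    s2a = locus.sigma2_alpha if locus.sigma2_alpha is not None else \
        empirical_sigma2_alpha(locus.z)

    configs = []
    for bits in itertools.product([0, 1], repeat=m):
        k = sum(bits)
        if k == 0 and not locus.include_null:
            continue
        if k_max is not None and k > k_max:
            continue
        configs.append(np.array(bits))
    logliks = np.array([config_loglik(locus.z, locus.Sigma, c, s2a)
                        for c in configs])
    with np.errstate(divide="ignore"):
        log_theta, log_1mt = np.log(theta), np.log1p(-theta)

    def _log_prior(k: int) -> float:
        # guard 0 * (-inf) at the theta = 0 / theta = 1 boundaries
        lp = k * log_theta if k else 0.0
        lp += (m - k) * log_1mt if m > k else 0.0
        return lp

    log_prior = np.array([_log_prior(int(c.sum())) for c in configs])
    log_post = logliks + log_prior
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    pip = np.zeros(m)
    for c, pr in zip(configs, post):
        pip += c * pr
    table = pd.DataFrame({
        "config": ["".join(map(str, c)) for c in configs],
        "n_causal": [int(c.sum()) for c in configs],
        "loglik": logliks,
        "log_prior": log_prior,
        "posterior": post,
    }).sort_values("posterior", ascending=False).reset_index(drop=True)
    result = FineMapResult(genes=list(locus.genes),
                           pip=pd.Series(pip, index=locus.genes),
                           config_table=table, sigma2_alpha=s2a, theta=theta)
    result.credible = credible_set(result, rho=0.9)
    result.rho = 0.9
    return result


def credible_set(result: FineMapResult, rho: float = 0.9) -> list[str]:
    """Smallest PIP-ranked gene set whose normalized cumulative inclusion
    mass reaches rho; ties broken by gene id."""
    pip = result.pip
    total = float(pip.sum())
    if total <= 0:
        return []
    order = sorted(pip.index, key=lambda g: (-pip[g], g))
    out, acc = [], 0.0
    for g in order:
        out.append(g)
        acc += pip[g] / total
        if acc >= rho:
            break
    return out


class FocusFineMapper:
    """Locus fine-mapper over TWAS z-scores (scikit-learn style).

    Parameters
    ----------
    sigma2_alpha : prior causal-effect variance; None uses the locus mean
        chi-square plug-in.
    theta : prior causal probability per gene; None uses 1/m.
    rho : credible level.
    k_max : optional cap on configuration size.

    Attributes (after fit)
    ----------
    pip_ : pd.Series per gene
    credible_set_ : gene ids at level rho
    result_ : FineMapResult with the configuration posterior table
    """

    def __init__(self, sigma2_alpha: float | None = None,
                 theta: float | None = None, rho: float = 0.9,
                 k_max: int | None = None, include_null: bool = True):
        self.sigma2_alpha = sigma2_alpha
        self.theta = theta
        self.rho = rho
        self.k_max = k_max
        self.include_null = include_null

    def get_params(self, deep=True):
        return {"sigma2_alpha": self.sigma2_alpha, "theta": self.theta,
                "rho": self.rho, "k_max": self.k_max,
                "include_null": self.include_null}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, z: np.ndarray, genes: list[str] | None = None,
            Sigma: np.ndarray | None = None, W: np.ndarray | None = None,
            V: np.ndarray | None = None) -> "FocusFineMapper":
        z = np.asarray(z, dtype=float)
        if genes is None:
            genes = [f"g{i + 1}" for i in range(len(z))]
        locus = LocusModel(genes=list(genes), z=z, Sigma=Sigma, W=W, V=V,
                           sigma2_alpha=self.sigma2_alpha, theta=self.theta,
                           include_null=self.include_null)
        self.result_ = enumerate_posterior(locus, k_max=self.k_max)
        self.pip_ = self.result_.pip
        self.credible_set_ = credible_set(self.result_, rho=self.rho)
        self.result_.credible = self.credible_set_
        self.result_.rho = self.rho
        return self
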