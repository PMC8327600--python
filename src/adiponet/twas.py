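"""Transcriptome-wide association: cis prediction weights and the weighted
summary-statistic test.

Workflow per gene: collect cis variants (+/- 500 kb of the gene body by
default), gate on cis heritability (Haseman-Elston regression with a block
jackknife p), train expression-prediction weights (best of top1 / ridge /
elastic net by cross-validated R^2), then test association with the GWAS
trait as z = w'z_gwas / sqrt(w'Vw) using a reference LD matrix V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge, ElasticNetCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


def cis_window_variants(gene: pd.Series | dict, variants: pd.DataFrame,
                        flank: int = 500_000) -> pd.DataFrame:
    """Variants within the closed interval [start - flank, end + flank] on
    the gene's chromosome."""
    chrom = str(gene["chrom"])
    lo = gene["start"] - flank
    hi = gene["end"] + flank
    mask = (variants["chrom"].astype(str) == chrom) & \
           (variants["pos"] >= lo) & (variants["pos"] <= hi)
    return variants[mask]


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    if np.ndim(sd) == 0:
        if sd == 0:
            raise ValueError("zero variance")
        return (x - x.mean()) / sd
    if np.any(sd == 0):
        raise ValueError("zero-variance column")
    return (x - x.mean(axis=0)) / sd


def cis_h2_gate(expr_gene: np.ndarray, cis_geno: np.ndarray,
                p_cut: float = 0.01, n_blocks: int = 30
                ) -> tuple[float, float, bool]:
    """Haseman-Elston cis-heritability estimate with a jackknife gate.

    Regresses off-diagonal phenotype cross-products y_i y_j on the cis GRM
    entries A_ij (A = ZZ'/p from standardized dosages); the slope estimates
    h2_cis for standardized expression.  The p-value is one-sided for
    h2 > 0 from a delete-a-block jackknife over individuals.

    Returns (hsq, p, pass_flag).
    """
    y = _standardize(expr_gene)
    Z = _standardize(cis_geno)
    n, p = Z.shape
    if p < 2 or n < 50:
        raise ValueError("need >= 2 cis variants and n >= 50")
    A = Z @ Z.T / p

    def he_slope(idx: np.ndarray) -> float:
        Ai = A[np.ix_(idx, idx)]
        yi = y[idx]
        num = yi @ Ai @ yi - np.sum(np.diag(Ai) * yi ** 2)
        den = (Ai ** 2).sum() - np.sum(np.diag(Ai) ** 2)
        return num / den

    full = he_slope(np.arange(n))
    blocks = np.array_split(np.arange(n), n_blocks)
    jk = np.array([he_slope(np.setdiff1d(np.arange(n), blk))
                   for blk in blocks])
    se = np.sqrt((n_blocks - 1) / n_blocks * ((jk - jk.mean()) ** 2).sum())
    pval = float(stats.norm.sf(full / se)) if se > 0 else (0.0 if full > 0
                                                           else 1.0)
    return float(full), pval, pval < p_cut


@dataclass
class GeneWeights:
    """Expression-prediction weights for one gene."""

    gene: str
    variant_ids: list[str]
    w: np.ndarray
    model: str
    cv_r2: float
    cv_p: float
    hsq: float = np.nan
    hsq_p: float = np.nan


def _cv_r2(Z: np.ndarray, y: np.ndarray, fit_fn, k_folds: int, seed: int
           ) -> float:
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for tr, te in kf.split(Z):
        w = fit_fn(Z[tr], y[tr])
        pred[te] = Z[te] @ w
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - ss_res / ss_tot


def _cv_pvalue(cv_r2: float, n: int) -> float:
    """F-based p-value for the cross-validated R^2 (1 df approximation)."""
    if cv_r2 <= 0:
        return 1.0
    f = cv_r2 * (n - 2) / (1 - cv_r2)
    return float(stats.f.sf(f, 1, n - 2))


def train_weights(expr_gene: np.ndarray, cis_geno: np.ndarray,
                  variant_ids: list[str] | None = None, gene: str = "gene",
                  models: tuple[str, ...] = ("top1", "ridge", "enet"),
                  k_folds: int = 5, seed: int = 0,
                  ridge_alpha: float | None = None) -> GeneWeights | None:
    """Fit candidate cis-prediction models and keep the best by CV R^2.

    Weights are refit on the full data for the selected model.  Returns None
    (with a log message) when every candidate has non-positive CV R^2 or the
    winning weight vector is all zero.
    """
    y = _standardize(expr_gene)
    Z = _standardize(cis_geno)
    n, p = Z.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(p)]
    alpha = ridge_alpha if ridge_alpha is not None else float(p)

    def fit_top1(Zt, yt):
        r = Zt.T @ yt / len(yt)
        j = int(np.argmax(np.abs(r)))
        w = np.zeros(Zt.shape[1])
        w[j] = r[j]
        return w

    def fit_ridge(Zt, yt):
        return Ridge(alpha=alpha, fit_intercept=False).fit(Zt, yt).coef_

    def fit_enet(Zt, yt):
        en = ElasticNetCV(l1_ratio=0.5, n_alphas=10, cv=3, max_iter=5000,
                          fit_intercept=False, random_state=seed)
        with np.errstate(all="ignore"):
            en.fit(Zt, yt)
        return en.coef_

    fitters = {"top1": fit_top1, "ridge": fit_ridge, "enet": fit_enet}
    results = {}
    for name in models:
        fn = fitters[name]
        try:
            results[name] = _cv_r2(Z, y, fn, k_folds, seed)
        except Exception:  # degenerate fold
            results[name] = -np.inf
    best = max(results, key=results.get)
    best_r2 = results[best]
    w = fitters[best](Z, y)
    if best_r2 <= 0 or not np.any(w):
        logger.info("gene %s skipped: best CV R^2 %.3f, model %s",
                    gene, best_r2, best)
        return None
    return GeneWeights(gene=gene, variant_ids=list(variant_ids), w=w,
                       model=best, cv_r2=float(best_r2),
                       cv_p=_cv_pvalue(best_r2, n))


def twas_association(weights: GeneWeights | np.ndarray, gwas_z: np.ndarray,
                     V: np.ndarray, tol: float = 1e-12
                     ) -> tuple[float, float]:
    """Weighted summary-statistic association test.

    z_twas = w'z / sqrt(w'Vw), two-sided normal p.  V is the cis LD matrix
    aligned to the weights; raises when the predicted-expression variance
    w'Vw is not positive.
    """
    w = weights.w if isinstance(weights, GeneWeights) else \
        np.asarray(weights, dtype=float)
    z = np.asarray(gwas_z, dtype=float)
    denom = float(w @ V @ w)
    if denom <= tol:
        raise ValueError("w'Vw <= tolerance: predicted expression has no "
                         "variance under this LD")
    zt = float(w @ z) / np.sqrt(denom)
    return zt, float(2 * stats.norm.sf(abs(zt)))


def bonferroni_gate(pvals: np.ndarray, n_tests: int,
                    alpha: float = 0.05) -> np.ndarray:
    """Strict Bonferroni significance flags: p < alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return np.asarray(pvals, dtype=float) < alpha / n_tests


class CisExpressionModel(BaseEstimator, RegressorMixin):
    """Cis expression prediction model (scikit-learn style).

    fit(X, y) takes an n x p cis genotype matrix and the gene's expression;
    the heritability gate runs first (unless gate=False), then the candidate
    models compete on cross-validated R^2.

    Attributes
    ----------
    coef_ : selected weight vector (p,)
    model_ : winning model tag
    cv_r2_, cv_p_, hsq_, hsq_p_ : fit diagnostics
    passed_ : False when the gene failed the gate or no model predicted
    """

    def __init__(self, models: tuple[str, ...] = ("top1", "ridge", "enet"),
                 k_folds: int = 5, hsq_p_cut: float = 0.01, gate: bool = True,
                 seed: int = 0, ridge_alpha: float | None = None):
        self.models = models
        self.k_folds = k_folds
        self.hsq_p_cut = hsq_p_cut
        self.gate = gate
        self.seed = seed
        self.ridge_alpha = ridge_alpha

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CisExpressionModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.hsq_, self.hsq_p_ = np.nan, np.nan
        if self.gate:
            self.hsq_, self.hsq_p_, ok = cis_h2_gate(y, X,
                                                     p_cut=self.hsq_p_cut)
            if not ok:
                self.passed_ = False
                self.coef_ = np.zeros(X.shape[1])
                self.model_, self.cv_r2_, self.cv_p_ = None, np.nan, np.nan
                return self
        gw = train_weights(y, X, models=self.models, k_folds=self.k_folds,
                           seed=self.seed, ridge_alpha=self.ridge_alpha)
        if gw is None:
            self.passed_ = False
            self.coef_ = np.zeros(X.shape[1])
            self.model_, self.cv_r2_, self.cv_p_ = None, np.nan, np.nan
            return self
        self.passed_ = True
        self.coef_ = gw.w
        self.model_ = gw.model
        self.cv_r2_ = gw.cv_r2
        self.cv_p_ = gw.cv_p
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _standardize(np.asarray(X, dtype=float)) @ self.coef_
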