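"""cis/trans eQTL scans and moderated differential expression.

The cis scan regresses residualized expression on residualized dosage for
every (gene, variant) pair within the cis window (1 Mb of either gene end by
default), with BH correction across all tested pairs.  The trans test is a
single linear model of a network eigengene on one variant's dosage.
Differential expression fits a per-gene linear model (group effect plus
optional pairing-block fixed effects) and shrinks the residual variances
toward a common prior by an empirical-Bayes method-of-moments fit of an
inverse-gamma (scaled inverse chi-square) prior, giving moderated t
statistics with d0 + d_g degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special
import statsmodels.api as sm

from .enrich import bh_fdr
from .simdata import GenotypePanel


def _residual_projector(cov: np.ndarray | None, n: int) -> np.ndarray:
    X = np.ones((n, 1)) if cov is None else \
        np.column_stack([np.ones(n), np.asarray(cov, dtype=float)])
    Q, _ = np.linalg.qr(X)
    return np.eye(n) - Q @ Q.T, X.shape[1]


def hwe_pvalue(dosages: np.ndarray) -> float:
    """Chi-square (1 df) Hardy-Weinberg test from rounded genotype counts."""
    g = np.round(dosages).astype(int)
    n = len(g)
    counts = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()])
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    if np.any(exp == 0):
        return 1.0
    chi2 = float(((counts - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, 1))


def cis_eqtl_scan(expr: pd.DataFrame, panel: GenotypePanel,
                  gene_annot: pd.DataFrame, window: float = 1e6,
                  covariates: np.ndarray | pd.DataFrame | None = None,
                  maf_min: float = 0.05, hwe_p_min: float = 1e-6
                  ) -> pd.DataFrame:
    """Per-(gene, cis variant) OLS of expression on dosage plus covariates.

    Variants failing the MAF or Hardy-Weinberg filters are excluded.  Betas
    are per effect-allele (alt) dosage; p-values are two-sided t with
    n - n_covariates - 2 df; q is BH across every tested pair.
    """
    n = len(expr)
    P, k_cov = _residual_projector(
        None if covariates is None else np.asarray(covariates, dtype=float), n)
    k_cov -= 1  # covariate count excluding the intercept
    df = n - k_cov - 2

    maf = panel.variants["maf"].to_numpy()
    keep = maf >= maf_min
    if hwe_p_min > 0:
        hwe = np.array([hwe_pvalue(panel.dosages[:, j])
                        for j in range(panel.n_variants)])
        keep &= hwe >= hwe_p_min
    variants = panel.variants[keep].reset_index(drop=True)
    dos = P @ panel.dosages[:, keep]

    rows = []
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].astype(str).to_numpy()
    any_cis = False
    for gene in expr.columns:
        if gene not in gene_annot.index:
            continue
        g = gene_annot.loc[gene]
        mask = (chrom == str(g["chrom"])) & \
               (pos >= g["start"] - window) & (pos <= g["end"] + window)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        any_cis = True
        y = P @ expr[gene].to_numpy(dtype=float)
        X = dos[:, idx]
        xtx = (X ** 2).sum(axis=0)
        beta = X.T @ y / xtx
        rss = (y ** 2).sum() - beta ** 2 * xtx
        se = np.sqrt(np.maximum(rss, 0) / df / xtx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2 * stats.t.sf(np.abs(t), df)
        for i, j in enumerate(idx):
            rows.append((gene, variants["snp"].iloc[j], beta[i], se[i],
                         p[i]))
    if not any_cis:
        raise ValueError("no cis variants for any gene")
    out = pd.DataFrame(rows, columns=["gene", "variant", "beta", "se", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def trans_eqtl_eigengene(eigengene: np.ndarray, dosage: np.ndarray,
                         covariates: np.ndarray | None = None
                         ) -> tuple[float, float, float]:
    """OLS of an eigengene on a single variant's dosage (+ covariates)."""
    x = np.asarray(dosage, dtype=float)
    if x.std() == 0:
        raise ValueError("constant dosage")
    cols = [np.ones(len(x)), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cols.append(cov if cov.ndim == 2 else cov[:, None])
    X = np.column_stack(cols)
    fit = sm.OLS(np.asarray(eigengene, dtype=float), X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def _trigamma_inverse(x: float, n_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, as in the standard
    empirical-Bayes variance-shrinkage fit)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(n_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float
                       ) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse chi-square prior (d0, s0^2)
    to observed residual variances with df residual degrees of freedom."""
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1)
    t2 = evar - special.polygamma(1, df / 2)
    if t2 <= 0:
        # no excess dispersion: infinite prior df, common variance = mean
        return np.inf, float(s2.mean())
    d0 = 2 * _trigamma_inverse(t2)
    s0_2 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s0_2)


def de_moderated(log_expr: pd.DataFrame, group: np.ndarray,
                 block: np.ndarray | None = None,
                 prior_df: float | None = None) -> pd.DataFrame:
    """Moderated-t differential expression with optional pairing blocks.

    Parameters
    ----------
    log_expr : samples x genes log-expression.
    group : two-level labels (the contrast is level 2 minus level 1 in
        sorted order).
    block : optional pairing factor; each block must contain exactly one
        sample per group (balanced pairs), modelled as fixed effects.
    prior_df : force the prior degrees of freedom d0 (np.inf recovers the
        common-variance limit, 0 the ordinary t); default fits d0 by the
        empirical-Bayes method of moments.

    Returns one row per gene: gene, log_fc, t (moderated), p, q, s2, df_total.
    """
    groups = np.asarray(group)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    g01 = (groups == levels[1]).astype(float)
    n = len(g01)
    cols = [np.ones(n), g01]
    if block is not None:
        blocks = np.asarray(block)
        for b in np.unique(blocks):
            sub = g01[blocks == b]
            if len(sub) != 2 or sub.sum() != 1:
                raise ValueError("block design must be balanced pairs "
                                 "(one sample per group per block)")
        lv = np.unique(blocks)
        for b in lv[1:]:
            cols.append((blocks == b).astype(float))
    X = np.column_stack(cols)
    n_par = np.linalg.matrix_rank(X)
    d_g = n - n_par
    if d_g <= 0:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    Y = log_expr.to_numpy(dtype=float)
    coefs = H @ Y
    resid = Y - X @ coefs
    s2 = (resid ** 2).sum(axis=0) / d_g
    log_fc = coefs[1]
    c_g = float(np.sqrt(XtX_inv[1, 1]))

    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, d_g)
    elif np.isinf(prior_df):
        d0, s0_2 = np.inf, float(s2.mean())
    else:
        d0 = float(prior_df)
        _, s0_2 = fit_variance_prior(s2, d_g) if d0 > 0 else (None, 1.0)
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_2)
        df_tot = 1e6
    elif d0 == 0:
        s2_mod = s2
        df_tot = d_g
    else:
        s2_mod = (d0 * s0_2 + d_g * s2) / (d0 + d_g)
        df_tot = d0 + d_g
    t = log_fc / (np.sqrt(s2_mod) * c_g)
    p = 2 * stats.t.sf(np.abs(t), df_tot)
    out = pd.DataFrame({"gene": log_expr.columns, "log_fc": log_fc,
                        "t": t, "p": p, "s2": s2, "df_total": df_tot})
    out["q"] = bh_fdr(out["p"].to_numpy())
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    return out


def intersect_network_de(network_genes: list[str], de_records: pd.DataFrame,
                         q_cut: float = 0.05, precision: int = 2
                         ) -> dict:
    """Counts and percentage of network genes that are significantly DE."""
    if len(network_genes) == 0:
        raise ValueError("empty network gene set")
    sig = set(de_records.loc[de_records["q"] < q_cut, "gene"])
    n_de = sum(1 for g in network_genes if g in sig)
    n_net = len(network_genes)
    return {"n_de": n_de, "n_network": n_net,
            "percent": round(100.0 * n_de / n_net, precision)}


class ModeratedDE:
    """Moderated-t differential expression (scikit-learn style).

    fit(X, y, block=None) with X samples x genes log-expression and y the
    two-level group labels; results land in ``results_`` with the fitted
    variance prior in ``d0_`` and ``s0_2_``.
    """

    def __init__(self, prior_df: float | None = None, q_cut: float = 0.05):
        self.prior_df = prior_df
        self.q_cut = q_cut

    def get_params(self, deep=True):
        return {"prior_df": self.prior_df, "q_cut": self.q_cut}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y: np.ndarray,
            block: np.ndarray | None = None) -> "ModeratedDE":
        self.results_ = de_moderated(X, y, block=block,
                                     prior_df=self.prior_df)
        self.d0_ = self.results_.attrs["d0"]
        self.s0_2_ = self.results_.attrs["s0_2"]
        self.significant_ = self.results_.loc[
            self.results_["q"] < self.q_cut, "gene"].tolist()
        return self
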