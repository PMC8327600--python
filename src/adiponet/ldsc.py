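"""Stratified LD-score regression (partitioned heritability).

Per-annotation LD scores are computed from a reference genotype panel with
the small-sample-adjusted squared correlation r2_adj = r^2 - (1 - r^2)/(n - 2)
within a physical window.  Chi-square GWAS statistics are then regressed on
N-scaled per-category LD scores with a free intercept; per-category
heritability shares use the standard overlapping-annotation accounting, and
enrichment = h2 share / SNP share with a delete-a-block jackknife for
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypePanel


@dataclass
class AnnotationSet:
    """Variants x categories annotation matrix; first category is the base
    (all ones)."""

    matrix: np.ndarray  # (m, C)
    names: list[str]

    def __post_init__(self):
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim != 2 or a.shape[1] != len(self.names):
            raise ValueError("annotation matrix / names mismatch")
        if not np.all(a[:, 0] == 1):
            raise ValueError("first category must be the all-ones base")
        if np.any(a.sum(axis=1) == 0):
            raise ValueError("every variant must be in at least one category")
        self.matrix = a

    @property
    def m_c(self) -> np.ndarray:
        """Per-category variant counts (column sums)."""
        return self.matrix.sum(axis=0)


def gene_set_annotation(variants: pd.DataFrame, gene_annot: pd.DataFrame,
                        gene_set: list[str] | None = None,
                        flank: int = 500_000,
                        name: str = "gene_set") -> AnnotationSet:
    """Binary annotation marking variants within +/- flank of any set gene.

    Interval is closed: [gene_start - flank, gene_end + flank].  Variants and
    genes must share a 1-based coordinate system; gene_annot needs columns
    chrom, start, end (indexed by gene id).
    """
    genes = gene_annot if gene_set is None else gene_annot.loc[gene_set]
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].astype(str).to_numpy()
    member = np.zeros(len(variants), dtype=bool)
    for _, g in genes.iterrows():
        member |= (chrom == str(g["chrom"])) & \
                  (pos >= g["start"] - flank) & (pos <= g["end"] + flank)
    base = np.ones(len(variants))
    if len(genes) == 0:
        return AnnotationSet(matrix=base[:, None], names=["base"])
    return AnnotationSet(matrix=np.column_stack([base, member.astype(float)]),
                         names=["base", name])


def ld_scores(panel: GenotypePanel, annotations: AnnotationSet,
              window_bp: float = 1e6) -> np.ndarray:
    """Per-variant, per-category LD scores from a reference panel.

    l(j, C) = sum over k in C with |pos_k - pos_j| <= window of
    r2_adj(j, k), where r2_adj = r^2 - (1 - r^2)/(n_ref - 2); the self term
    is included.
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    n = panel.n_individuals
    if n < 50:
        raise ValueError("reference panel too small (n < 50)")
    z = panel.standardized()
    pos = panel.variants["pos"].to_numpy()
    m = panel.n_variants
    A = annotations.matrix
    out = np.zeros((m, A.shape[1]))
    order = np.argsort(pos)
    zs, ps, As = z[:, order], pos[order], A[order]
    lo = 0
    for j in range(m):
        while ps[j] - ps[lo] > window_bp:
            lo += 1
        hi = j
        while hi + 1 < m and ps[hi + 1] - ps[j] <= window_bp:
            hi += 1
        r = zs[:, lo:hi + 1].T @ zs[:, j] / n
        r2 = r ** 2
        r2_adj = r2 - (1 - r2) / (n - 2)
        out[order[j]] = r2_adj @ As[lo:hi + 1]
    return out


@dataclass
class PartitionedH2:
    table: pd.DataFrame  # category, tau, h2, h2_share, prop_snps, enrichment,
    # enrichment_se, enrichment_p
    h2_total: float
    intercept: float
    n_blocks: int


def _fit_taus(chi2: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least squares of chi2 on [1, X]."""
    Xd = np.column_stack([np.ones(len(chi2)), X])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(Xd * sw[:, None], chi2 * sw, rcond=None)
    return coef


def _partition(coef: np.ndarray, A: np.ndarray) -> tuple[float, np.ndarray]:
    """Total h2 and per-category h2 under overlapping-annotation accounting.

    Per-SNP heritability of SNP k is sum over categories containing k of
    tau_C; h2 of category C sums that over its member SNPs.
    """
    taus = coef[1:]
    per_snp = A @ taus
    h2_total = float(per_snp.sum())
    h2_c = np.array([(per_snp * A[:, c]).sum() for c in range(A.shape[1])])
    return h2_total, h2_c


def partitioned_regression(sumstats: pd.DataFrame, ldscores: np.ndarray,
                           annotations: AnnotationSet,
                           n_blocks: int = 20) -> PartitionedH2:
    """Partitioned-heritability regression with block-jackknife enrichment SE.

    ``sumstats`` must carry Z and N aligned to the LD-score rows.
    """
    z = sumstats["Z"].to_numpy(dtype=float)
    N = sumstats["N"].to_numpy(dtype=float)
    m = len(z)
    if m < 2 * n_blocks:
        raise ValueError("fewer variants than 2 x n_blocks")
    chi2 = z ** 2
    A = annotations.matrix
    X = ldscores * N[:, None]
    w = 1.0 / np.maximum(ldscores[:, 0], 1.0)

    def estimate(idx: np.ndarray) -> tuple[float, np.ndarray, float, np.ndarray]:
        coef = _fit_taus(chi2[idx], X[idx], w[idx])
        h2_tot, h2_c = _partition(coef, A)  # annotation shares are global
        return coef[0], coef[1:], h2_tot, h2_c

    icpt, taus, h2_total, h2_c = estimate(np.arange(m))
    prop = annotations.m_c / m
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = (h2_c / h2_total) / prop

    blocks = np.array_split(np.arange(m), n_blocks)
    enr_jk = np.empty((n_blocks, A.shape[1]))
    for b, blk in enumerate(blocks):
        idx = np.setdiff1d(np.arange(m), blk, assume_unique=True)
        _, _, h2_t_b, h2_c_b = estimate(idx)
        with np.errstate(divide="ignore", invalid="ignore"):
            enr_jk[b] = (h2_c_b / h2_t_b) / prop
    enr_mean = enr_jk.mean(axis=0)
    enr_se = np.sqrt((n_blocks - 1) / n_blocks *
                     ((enr_jk - enr_mean) ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = (enr - 1.0) / enr_se
    p = 2 * stats.norm.sf(np.abs(zstat))
    table = pd.DataFrame({
        "category": annotations.names,
        "tau": taus,
        "h2": h2_c,
        "h2_share": h2_c / h2_total if h2_total != 0 else np.nan,
        "prop_snps": prop,
        "enrichment": enr,
        "enrichment_se": enr_se,
        "enrichment_p": p,
    })
    return PartitionedH2(table=table, h2_total=h2_total, intercept=float(icpt),
                         n_blocks=n_blocks)


class LdscRegression:
    """Stratified LD-score regression, scikit-learn style.

    Parameters
    ----------
    window_bp : LD-score window in base pairs.
    n_blocks : jackknife block count.

    Attributes (after fit)
    ----------
    ldscores_, result_ (PartitionedH2), enrichment_, h2_total_, intercept_.
    """

    def __init__(self, window_bp: float = 1e6, n_blocks: int = 20):
        self.window_bp = window_bp
        self.n_blocks = n_blocks

    def get_params(self, deep=True):
        return {"window_bp": self.window_bp, "n_blocks": self.n_blocks}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, sumstats: pd.DataFrame, panel: GenotypePanel,
            annotations: AnnotationSet) -> "LdscRegression":
        self.ldscores_ = ld_scores(panel, annotations, self.window_bp)
        self.result_ = partitioned_regression(sumstats, self.ldscores_,
                                              annotations, self.n_blocks)
        self.enrichment_ = self.result_.table["enrichment"].to_numpy()
        self.h2_total_ = self.result_.h2_total
        self.intercept_ = self.result_.intercept
        return self
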