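"""Weighted co-expression network discovery.

Implements the standard weighted-network workflow: expression filtering and
rank-based inverse-normal transformation after covariate correction,
soft-threshold selection by scale-free topology fit, signed/unsigned
adjacency, topological overlap (TOM), average-linkage module detection on
1 - TOM, module eigengenes (first principal component of the standardized
member submatrix) with kME membership correlations, and module-trait Pearson
association with a Bonferroni family of modules x traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

UNASSIGNED = "unassigned"


def _residualize(y: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, cov] via least squares."""
    X = np.column_stack([np.ones(len(y)), cov]) if cov is not None else \
        np.ones((len(y), 1))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with offset (rank - 0.5)/n.

    Ties receive average ranks.
    """
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def filter_and_transform(expr: pd.DataFrame,
                         min_expressed_frac: float = 0.9,
                         covariates: pd.DataFrame | np.ndarray | None = None
                         ) -> pd.DataFrame:
    """Filter to genes expressed (> 0) in at least ``min_expressed_frac`` of
    samples, residualize each on the covariates, then inverse-normal
    transform.

    Parameters
    ----------
    expr : samples x genes expression on a non-negative scale (e.g. FPKM).
    covariates : optional numeric table, one row per sample.
    """
    frac = (expr.to_numpy() > 0).mean(axis=0)
    keep = frac >= min_expressed_frac
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    out = expr.loc[:, keep].copy()
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        sds = cov.std(axis=0)
        if np.any(sds == 0):
            raise ValueError("covariate collinear with the intercept")
    vals = out.to_numpy(dtype=float)
    for j in range(vals.shape[1]):
        r = _residualize(vals[:, j], cov)
        vals[:, j] = inverse_normal_transform(r)
    return pd.DataFrame(vals, index=out.index, columns=out.columns)


def adjacency(expr: pd.DataFrame | np.ndarray, power: float,
              signed: bool = False) -> np.ndarray:
    """Soft-threshold co-expression adjacency.

    Unsigned: |cor|^power.  Signed: ((1 + cor)/2)^power.  Diagonal is 1.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    x = np.asarray(expr, dtype=float)
    if np.any(x.std(axis=0) == 0):
        raise ValueError("zero-variance gene")
    cor = np.corrcoef(x, rowvar=False)
    a = ((1 + cor) / 2) ** power if signed else np.abs(cor) ** power
    np.fill_diagonal(a, 1.0)
    return a


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame  # power, scale_free_r2, mean_k, median_k, slope
    chosen_power: int | None
    r2_cut: float

    @property
    def flagged(self) -> bool:
        return self.chosen_power is None


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) on log10 mean k over equal-width bins."""
    if np.allclose(k, k[0]):
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return np.nan, np.nan
    slope, _, r, *_ = stats.linregress(xs, ys)
    return float(r ** 2), float(slope)


def pick_soft_threshold(expr: pd.DataFrame | np.ndarray,
                        powers: list[int] | None = None,
                        r2_cut: float = 0.85, n_bins: int = 10,
                        signed: bool = False) -> SoftThresholdReport:
    """Scale-free topology report over candidate soft-threshold powers.

    Chooses the lowest power whose scale-free fit R^2 reaches ``r2_cut``;
    ``chosen_power`` is None (flagged) when no candidate qualifies or the
    connectivity distribution is degenerate.
    """
    if powers is None:
        powers = list(range(1, 21))
    x = np.asarray(expr, dtype=float)
    if x.shape[1] < 30:
        raise ValueError("need at least 30 genes for a scale-free fit")
    rows = []
    for beta in powers:
        a = adjacency(x, beta, signed=signed)
        k = a.sum(axis=0) - 1.0  # exclude self
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append((beta, r2, slope, float(k.mean()), float(np.median(k))))
    table = pd.DataFrame(rows, columns=["power", "scale_free_r2", "slope",
                                        "mean_k", "median_k"])
    ok = table[(table["scale_free_r2"] >= r2_cut)
               & np.isfinite(table["scale_free_r2"])]
    chosen = int(ok["power"].iloc[0]) if len(ok) else None
    return SoftThresholdReport(table=table, chosen_power=chosen, r2_cut=r2_cut)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    for i != j, with connectivity k excluding the diagonal; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=0) - np.diag(a)
    # shared-neighbour sums excluding both endpoints' self terms
    num = a @ a - a * np.diag(a)[None, :] - np.diag(a)[:, None] * a
    num = num + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(tom: np.ndarray, gene_ids: list[str] | pd.Index,
                   cut_height: float = 0.99, min_module_size: int = 20
                   ) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` are labelled ``unassigned``.
    Surviving modules are renamed M1, M2, ... by decreasing size.
    """
    if not (0 < cut_height < 1):
        raise ValueError("cut_height must be in (0, 1)")
    dis = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2, 0, None)
    Z = linkage(squareform(dis, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=list(gene_ids), dtype=object)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    mapping = {c: f"M{i + 1}" for i, c in enumerate(order)}
    return labels.map(lambda c: mapping.get(c, UNASSIGNED))


def eigengenes(expr: pd.DataFrame, labels: pd.Series
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module eigengenes and kME membership correlations.

    The eigengene is the first right-singular direction of the standardized
    member submatrix in sample space, unit norm, oriented so the mean member
    kME is non-negative.  kME is the Pearson correlation of every gene with
    every eigengene.
    """
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    if not modules:
        raise ValueError("no modules to summarise")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=0)
    eg = {}
    for mod in sorted(modules):
        members = np.flatnonzero((labels == mod).to_numpy())
        if len(members) < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        sub = x[:, members]
        ssd = sub.std(axis=0)
        if np.any(ssd == 0):
            raise ValueError(f"module {mod} contains zero-variance genes")
        subz = (sub - sub.mean(axis=0)) / ssd
        u, s, vt = np.linalg.svd(subz, full_matrices=False)
        e = u[:, 0]
        # orient: mean correlation of members with the eigengene >= 0
        ec = (e - e.mean()) / e.std()
        member_cor = subz.T @ ec / len(e)
        if member_cor.mean() < 0:
            e = -e
        eg[mod] = e / np.linalg.norm(e)
    eg_df = pd.DataFrame(eg, index=expr.index)
    xz = (x - x.mean(axis=0)) / np.where(sd == 0, 1, sd)
    ez = (eg_df.to_numpy() - eg_df.to_numpy().mean(axis=0))
    ez = ez / ez.std(axis=0)
    kme = pd.DataFrame(xz.T @ ez / len(expr), index=expr.columns,
                       columns=eg_df.columns)
    return eg_df, kme


def module_trait_association(eigengene_df: pd.DataFrame,
                             traits: pd.DataFrame,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait.

    Significance is flagged at the Bonferroni threshold
    alpha / (n_modules * n_traits).
    """
    n_mod, n_tr = eigengene_df.shape[1], traits.shape[1]
    threshold = alpha / (n_mod * n_tr)
    rows = []
    for mod in eigengene_df.columns:
        for tr in traits.columns:
            t = traits[tr].to_numpy(dtype=float)
            if t.std() == 0:
                raise ValueError(f"constant trait {tr}")
            r, p = stats.pearsonr(eigengene_df[mod].to_numpy(), t)
            rows.append((mod, tr, r, p, p < threshold))
    out = pd.DataFrame(rows, columns=["module", "trait", "r", "p",
                                      "significant"])
    out.attrs["bonferroni_threshold"] = threshold
    return out


class ModuleDetector(BaseEstimator, ClusterMixin):
    """Co-expression module detector (scikit-learn style clusterer).

    Pipeline: soft-threshold adjacency -> TOM -> average-linkage clustering
    of 1 - TOM with a static cut -> eigengenes and kME.

    Parameters
    ----------
    power : int or "auto"
        Soft-threshold exponent; "auto" picks the lowest power reaching the
        scale-free fit cut (falling back to 6 when flagged).
    signed : bool
        Signed vs unsigned adjacency.
    cut_height : float
        Static cut on the 1 - TOM dendrogram.
    min_module_size : int
        Smaller clusters are left unassigned.

    Attributes
    ----------
    labels_ : pd.Series gene -> module id ("M1", ..., "unassigned")
    eigengenes_ : samples x modules DataFrame (unit-norm columns)
    kme_ : genes x modules membership correlations
    power_ : the power actually used
    soft_threshold_report_ : SoftThresholdReport when power="auto"
    """

    def __init__(self, power: int | str = 6, signed: bool = False,
                 cut_height: float = 0.99, min_module_size: int = 20,
                 r2_cut: float = 0.85):
        self.power = power
        self.signed = signed
        self.cut_height = cut_height
        self.min_module_size = min_module_size
        self.r2_cut = r2_cut

    def fit(self, X: pd.DataFrame, y=None) -> "ModuleDetector":
        """Detect modules in a samples x genes expression DataFrame."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if self.power == "auto":
            rep = pick_soft_threshold(X, r2_cut=self.r2_cut,
                                      signed=self.signed)
            self.soft_threshold_report_ = rep
            self.power_ = rep.chosen_power if rep.chosen_power else 6
        else:
            self.power_ = int(self.power)
        a = adjacency(X, self.power_, signed=self.signed)
        tom = tom_similarity(a)
        self.labels_ = detect_modules(tom, X.columns,
                                      cut_height=self.cut_height,
                                      min_module_size=self.min_module_size)
        if (self.labels_ != UNASSIGNED).any():
            self.eigengenes_, self.kme_ = eigengenes(X, self.labels_)
        else:
            self.eigengenes_ = pd.DataFrame(index=X.index)
            self.kme_ = pd.DataFrame(index=X.columns)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_.to_numpy()
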