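"""Module preservation between a reference and a test expression dataset.

For each module defined in the reference data, two statistics are measured in
the test data and compared against a permutation null of random same-size
gene sets:

* density — mean absolute intra-module correlation in the test data;
* connectivity — Pearson correlation between the intramodular connectivity
  vectors (kIM, the row sums of absolute within-module correlation) computed
  in the reference and in the test data.

Z = (observed - null mean) / null sd per statistic, aggregated as
Z_summary = (Z_density + Z_connectivity) / 2.  By convention, Z_summary < 2
indicates no preservation, 2-10 weak-to-moderate, > 10 strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ModulePreservation:
    module: str
    size: int
    z_density: float
    z_connectivity: float
    z_summary: float
    obs_density: float
    obs_connectivity: float
    null_density_mean: float
    null_density_sd: float
    null_connectivity_mean: float
    null_connectivity_sd: float
    n_permutations: int


def _abs_cor(x: np.ndarray) -> np.ndarray:
    c = np.corrcoef(x, rowvar=False)
    return np.abs(c)


def _density(ac: np.ndarray) -> float:
    n = ac.shape[0]
    off = ac[np.triu_indices(n, k=1)]
    return float(off.mean())


def _kim(ac: np.ndarray) -> np.ndarray:
    return ac.sum(axis=0) - 1.0


def preservation_zsummary(ref_expr: pd.DataFrame, test_expr: pd.DataFrame,
                          labels: pd.Series, n_perm: int = 200,
                          seed: int = 0) -> pd.DataFrame:
    """Permutation Z_summary preservation of reference modules in test data.

    Null gene sets are drawn without replacement from the test-data genes
    outside the module under evaluation, so the null stays informative even
    when reference and test data coincide.

    Returns one row per module (excluding "unassigned").
    """
    rng = np.random.default_rng(seed)
    modules = [m for m in pd.unique(labels) if m != "unassigned"]
    test_genes = list(test_expr.columns)
    rows = []
    for mod in sorted(modules):
        genes = [g for g in labels.index[labels == mod]]
        missing = [g for g in genes if g not in test_expr.columns
                   or g not in ref_expr.columns]
        if missing:
            raise ValueError(f"module {mod} genes absent from data: "
                             f"{missing[:5]}")
        k = len(genes)
        ref_ac = _abs_cor(ref_expr[genes].to_numpy(dtype=float))
        kim_ref = _kim(ref_ac)

        test_ac = _abs_cor(test_expr[genes].to_numpy(dtype=float))
        obs_density = _density(test_ac)
        obs_conn = float(np.corrcoef(kim_ref, _kim(test_ac))[0, 1])

        pool = [g for g in test_genes if g not in set(genes)]
        if len(pool) < k:
            raise ValueError("test data has too few genes outside the module"
                             " to draw null sets")
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for b in range(n_perm):
            pick = rng.choice(len(pool), size=k, replace=False)
            sub = test_expr[[pool[i] for i in pick]].to_numpy(dtype=float)
            ac = _abs_cor(sub)
            null_d[b] = _density(ac)
            null_c[b] = np.corrcoef(kim_ref, _kim(ac))[0, 1]
        sd_d, sd_c = null_d.std(ddof=1), null_c.std(ddof=1)
        if sd_d == 0 or sd_c == 0:
            raise ValueError("degenerate permutation null (sd = 0)")
        z_d = (obs_density - null_d.mean()) / sd_d
        z_c = (obs_conn - null_c.mean()) / sd_c
        rows.append(ModulePreservation(
            module=mod, size=k, z_density=z_d, z_connectivity=z_c,
            z_summary=(z_d + z_c) / 2, obs_density=obs_density,
            obs_connectivity=obs_conn,
            null_density_mean=float(null_d.mean()), null_density_sd=float(sd_d),
            null_connectivity_mean=float(null_c.mean()),
            null_connectivity_sd=float(sd_c), n_permutations=n_perm))
    return pd.DataFrame([r.__dict__ for r in rows])
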