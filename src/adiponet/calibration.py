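"""Calibration and parameter-recovery studies on synthetic data.

Each function runs a self-contained simulation study sized for a single CPU
and returns summary numbers.  They back both the statistical test suite and
the reporting script, so the study definitions live in one place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .simdata import (SimConfig, simulate_genotypes, simulate_expression,
                      simulate_traits, simulate_sumstats,
                      simulate_sumstats_analytic, network_cis_window)
from .network import ModuleDetector
from .preservation import preservation_zsummary
from .ldsc import AnnotationSet, LdscRegression
from .prs import LdpredInf, score_individuals, PrsWeights
from .twas import train_weights, twas_association
from .focus import FocusFineMapper, predicted_expression_corr
from .eqtl_de import de_moderated


def ldsc_enrichment_study(n_seeds: int = 20, m: int = 2000,
                          n_gwas: int = 20_000, n_ref: int = 500,
                          h2: float = 0.4, enrichment: float = 2.0,
                          member_frac: float = 0.2, seed0: int = 1000
                          ) -> pd.DataFrame:
    """Enrichment recovery for a concentrated-heritability annotation.

    One binary category covering ``member_frac`` of the variants carries
    ``enrichment``-fold per-SNP heritability.  Returns one row per seed with
    the estimate, jackknife SE and a within-2-SE flag.
    """
    rows = []
    k = int(m * member_frac)
    member = np.arange(m) < k
    w = np.where(member, enrichment,
                 (1 - member_frac * enrichment) / (1 - member_frac))
    ann = AnnotationSet(
        matrix=np.column_stack([np.ones(m), member.astype(float)]),
        names=["base", "set"])
    for s in range(n_seeds):
        cfg = SimConfig(n_individuals=n_ref, n_variants=m, block_size=10,
                        ar_rho=0.7, seed=seed0 + s)
        panel = simulate_genotypes(cfg)
        rng = np.random.default_rng(seed0 + 500 + s)
        beta = rng.standard_normal(m) * np.sqrt(h2 * w / m)
        ss = simulate_sumstats_analytic(panel, beta, n_gwas,
                                        seed=seed0 + 900 + s)
        reg = LdscRegression(window_bp=1e6, n_blocks=20).fit(ss, panel, ann)
        row = reg.result_.table.iloc[1]
        ok = abs(row["enrichment"] - enrichment) <= 2 * row["enrichment_se"]
        rows.append((seed0 + s, row["enrichment"], row["enrichment_se"],
                     bool(ok)))
    return pd.DataFrame(rows, columns=["seed", "enrichment", "se",
                                       "within_2se"])


def twas_null_study(n_genes: int = 500, n: int = 400, p_cis: int = 20,
                    alpha: float = 0.05, seed: int = 2000) -> dict:
    """Type-I error of the TWAS z-test under a null GWAS trait.

    Every gene has genuinely heritable cis expression (so weights train),
    while the GWAS z-scores are drawn from their null distribution N(0, R).
    Returns the rejection rate at ``alpha``.
    """
    cfg = SimConfig(n_individuals=n, n_variants=p_cis, block_size=5,
                    ar_rho=0.5, seed=seed)
    panel = simulate_genotypes(cfg)
    Z = panel.standardized()
    R = Z.T @ Z / n
    L = np.linalg.cholesky(R + 1e-8 * np.eye(p_cis))
    rng = np.random.default_rng(seed + 1)
    n_tested = 0
    n_reject = 0
    for g in range(n_genes):
        beta = rng.standard_normal(p_cis) * np.sqrt(0.4 / p_cis)
        y = Z @ beta + np.sqrt(0.6) * rng.standard_normal(n)
        gw = train_weights(y, panel.dosages, models=("top1", "ridge"),
                           k_folds=3, seed=seed + 2 + g)
        if gw is None:
            continue
        z_null = L @ rng.standard_normal(p_cis)
        _, pval = twas_association(gw.w, z_null, R)
        n_tested += 1
        n_reject += pval < alpha
    return {"n_tested": n_tested, "type_i": n_reject / n_tested}


def focus_coverage_study(n_loci: int = 200, m: int = 4, rho: float = 0.9,
                         sigma2_alpha: float = 16.0, seed: int = 3000
                         ) -> dict:
    """Coverage of the rho-level credible set over simulated loci.

    Per locus, predicted-expression correlations come from a random Wishart
    draw, one gene is causal with effect variance ``sigma2_alpha``, and the
    z-scores follow the fine-mapping model exactly.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    pip_top_correct = 0
    for t in range(n_loci):
        A = rng.standard_normal((m, 2 * m))
        Sigma = predicted_expression_corr(np.eye(m), A @ A.T / (2 * m)
                                          + 0.5 * np.eye(m))
        causal = int(rng.integers(m))
        alpha = np.sqrt(sigma2_alpha) * rng.standard_normal()
        lam = np.zeros(m)
        lam[causal] = alpha
        L = np.linalg.cholesky(Sigma + 1e-9 * np.eye(m))
        z = Sigma @ lam + L @ rng.standard_normal(m)
        fm = FocusFineMapper(sigma2_alpha=sigma2_alpha, theta=1.0 / m,
                             rho=rho)
        fm.fit(z, genes=[f"g{i}" for i in range(m)], Sigma=Sigma)
        if f"g{causal}" in fm.credible_set_:
            covered += 1
        if int(np.argmax(fm.pip_.to_numpy())) == causal:
            pip_top_correct += 1
    return {"n_loci": n_loci, "coverage": covered / n_loci,
            "top_pip_accuracy": pip_top_correct / n_loci}


def module_recovery_study(n_seeds: int = 20, n: int = 300, seed0: int = 4000
                          ) -> pd.DataFrame:
    """Adjusted Rand index of detected vs planted module labels per seed."""
    rows = []
    for s in range(n_seeds):
        cfg = SimConfig(n_individuals=n, n_variants=100, seed=seed0 + s)
        panel = simulate_genotypes(cfg)
        expr, truth = simulate_expression(panel, cfg)
        det = ModuleDetector(power=6).fit(expr)
        in_mod = set(truth.module_genes)
        truth_lab = [1 if g in in_mod else 0 for g in expr.columns]
        pred_lab = [0 if l == "unassigned" else int(l[1:])
                    for l in det.labels_]
        rows.append((seed0 + s, adjusted_rand_score(truth_lab, pred_lab)))
    return pd.DataFrame(rows, columns=["seed", "ari"])


def de_null_fdr_study(n_trials: int = 10, n: int = 40, n_genes: int = 300,
                      q_cut: float = 0.05, seed0: int = 5000) -> dict:
    """Average fraction of BH-significant genes under the global null."""
    rates = []
    for t in range(n_trials):
        rng = np.random.default_rng(seed0 + t)
        gene_sd = np.sqrt(6.0 / rng.chisquare(6.0, n_genes))
        expr = pd.DataFrame(rng.standard_normal((n, n_genes)) * gene_sd,
                            columns=[f"g{i}" for i in range(n_genes)])
        group = np.repeat(["a", "b"], n // 2)
        res = de_moderated(expr, group)
        rates.append(float((res["q"] < q_cut).mean()))
    return {"n_trials": n_trials, "mean_false_rate": float(np.mean(rates))}


def network_prs_study(n: int = 4000, m: int = 1000, seed: int = 6000) -> dict:
    """Network-restricted vs genome-wide PRS on a held-out cohort half.

    GWAS summary statistics come from the first half of the cohort; both
    scores are evaluated on the second half.  The network score keeps only
    weights inside the module genes' cis-window union.
    """
    cfg = SimConfig(n_individuals=n, n_variants=m, network_enrichment=5.0,
                    seed=seed)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    quant, binary, sex, ttruth = simulate_traits(panel, truth, cfg)
    half = n // 2
    from .simdata import GenotypePanel
    train = GenotypePanel(dosages=panel.dosages[:half],
                          variants=panel.variants,
                          block_size=panel.block_size)
    test = GenotypePanel(dosages=panel.dosages[half:],
                         variants=panel.variants,
                         block_size=panel.block_size)
    ss = simulate_sumstats(train, quant[:half])
    model = LdpredInf(h2=cfg.h2_trait).fit(ss, train)
    full_scores = score_individuals(test, model.weights_)
    lo, hi = network_cis_window(truth)
    pos = panel.variants["pos"].to_numpy()
    in_net = (pos >= lo) & (pos <= hi)
    wnet = model.weights_.weights[in_net]
    net_scores = score_individuals(
        test, PrsWeights(weights=wnet, method="inf-network"))
    y = quant[half:]
    r_full = float(np.corrcoef(full_scores, y)[0, 1])
    r_net = float(np.corrcoef(net_scores, y)[0, 1])
    return {"r_full": r_full, "r_network": r_net,
            "ratio": r_net / r_full,
            "variant_fraction": float(in_net.mean())}


def preservation_study(n: int = 300, n_random: int = 10, n_perm: int = 100,
                       seed: int = 7000) -> dict:
    """Z_summary of a true module on resampled data vs random gene sets."""
    cfg = SimConfig(n_individuals=2 * n, n_variants=100, seed=seed)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    ref, test = expr.iloc[:n], expr.iloc[n:]
    labels = pd.Series("unassigned", index=expr.columns, dtype=object)
    labels[truth.module_genes] = "M1"
    res = preservation_zsummary(ref, test, labels, n_perm=n_perm, seed=seed)
    z_true = float(res["z_summary"].iloc[0])

    rng = np.random.default_rng(seed + 1)
    cols = [f"g{i}" for i in range(200)]
    ref_n = pd.DataFrame(rng.standard_normal((n, 200)), columns=cols)
    test_n = pd.DataFrame(rng.standard_normal((n, 200)), columns=cols)
    n_small = 0
    zs = []
    for t in range(n_random):
        pick = rng.choice(200, size=30, replace=False)
        lab = pd.Series("unassigned", index=cols, dtype=object)
        lab.iloc[pick] = "R1"
        r = preservation_zsummary(ref_n, test_n, lab, n_perm=60,
                                  seed=seed + 2 + t)
        z = float(r["z_summary"].iloc[0])
        zs.append(z)
        n_small += abs(z) < 2
    return {"z_true_module": z_true, "random_z": zs,
            "frac_random_below_2": n_small / n_random}
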