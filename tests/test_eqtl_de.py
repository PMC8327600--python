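"""cis/trans eQTL scans and moderated differential expression."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adiponet import (SimConfig, simulate_genotypes, simulate_expression,
                      cis_eqtl_scan, trans_eqtl_eigengene, de_moderated,
                      intersect_network_de, ModeratedDE)
from adiponet.eqtl_de import hwe_pvalue, fit_variance_prior


def test_hwe_pvalue_detects_deviation(rng):
    n = 2000
    p = 0.3
    g_ok = rng.binomial(1, p, (n, 2)).sum(axis=1)
    assert hwe_pvalue(g_ok) > 1e-4
    # all-heterozygote genotypes violate HWE strongly
    g_bad = np.ones(n)
    assert hwe_pvalue(g_bad) < 1e-10


def test_cis_eqtl_scan_detects_hub_cis_effect():
    cfg = SimConfig(n_individuals=500, n_variants=400, seed=81)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    scan = cis_eqtl_scan(expr[[truth.hub_gene]], panel, truth.gene_annot,
                         window=1e6)
    assert set(scan["gene"]) == {truth.hub_gene}
    top = scan.sort_values("p").iloc[0]
    # the top cis signal is the hub variant or a close LD partner
    pos = panel.variants.set_index("snp")["pos"]
    assert abs(pos[top["variant"]] - pos[truth.hub_variant]) < 50_000
    assert top["q"] < 0.05
    # every tested variant is inside the window and passes MAF
    g = truth.gene_annot.loc[truth.hub_gene]
    for v in scan["variant"]:
        assert g["start"] - 1e6 <= pos[v] <= g["end"] + 1e6


def test_cis_eqtl_beta_matches_statsmodels():
    import statsmodels.api as sm
    cfg = SimConfig(n_individuals=200, n_variants=300, seed=82)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    rng = np.random.default_rng(820)
    cov = rng.standard_normal(200)
    scan = cis_eqtl_scan(expr[[truth.hub_gene]], panel, truth.gene_annot,
                         window=1e6, covariates=cov)
    row = scan.iloc[3]
    j = int(np.flatnonzero(panel.variants["snp"] == row["variant"])[0])
    X = np.column_stack([np.ones(200), panel.dosages[:, j], cov])
    fit = sm.OLS(expr[truth.hub_gene].to_numpy(), X).fit()
    assert row["beta"] == pytest.approx(fit.params[1], rel=1e-8)
    assert row["se"] == pytest.approx(fit.bse[1], rel=1e-8)
    assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-6)


def test_cis_eqtl_filters_and_errors():
    cfg = SimConfig(n_individuals=300, n_variants=100, seed=83)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    scan = cis_eqtl_scan(expr[[truth.hub_gene]], panel, truth.gene_annot,
                         window=1e6, maf_min=0.05)
    maf = panel.variants.set_index("snp")["maf"]
    assert np.all(maf[scan["variant"]].to_numpy() >= 0.05)
    # impossible window -> no cis variants anywhere
    with pytest.raises(ValueError):
        cis_eqtl_scan(expr[[truth.hub_gene]], panel,
                      truth.gene_annot.assign(start=10**9, end=10**9 + 1),
                      window=1.0)


def test_trans_eqtl_eigengene_matches_ols(rng):
    import statsmodels.api as sm
    n = 300
    x = rng.integers(0, 3, n).astype(float)
    eg = 0.1 * x + rng.standard_normal(n)
    beta, se, p = trans_eqtl_eigengene(eg, x)
    fit = sm.OLS(eg, np.column_stack([np.ones(n), x])).fit()
    assert beta == pytest.approx(fit.params[1])
    assert se == pytest.approx(fit.bse[1])
    with pytest.raises(ValueError):
        trans_eqtl_eigengene(eg, np.ones(n))


def test_variance_prior_moment_fit(rng):
    """Variances drawn from a scaled inverse chi-square prior are recovered."""
    d0_true, s0_true, df, n_genes = 8.0, 1.5, 10, 4000
    s2 = d0_true * s0_true / rng.chisquare(d0_true, n_genes) * \
        rng.chisquare(df, n_genes) / df
    d0, s0_2 = fit_variance_prior(s2, df)
    assert d0 == pytest.approx(d0_true, rel=0.25)
    assert s0_2 == pytest.approx(s0_true, rel=0.1)


def test_de_moderated_prior_df_limits(rng):
    n, g = 30, 50
    expr = pd.DataFrame(rng.standard_normal((n, g)),
                        columns=[f"g{i}" for i in range(g)])
    group = np.repeat(["a", "b"], n // 2)
    ord_t = de_moderated(expr, group, prior_df=0)
    # d0 = 0 recovers the ordinary two-sample t-test
    ta = expr[group == "a"]
    tb = expr[group == "b"]
    t_ref, p_ref = stats.ttest_ind(tb.iloc[:, 0], ta.iloc[:, 0])
    assert ord_t["t"].iloc[0] == pytest.approx(t_ref, rel=1e-10)
    assert ord_t["p"].iloc[0] == pytest.approx(p_ref, rel=1e-10)
    # d0 = inf pools all genes to a common variance
    pool = de_moderated(expr, group, prior_df=np.inf)
    assert pool["t"].std() != 0
    mod = de_moderated(expr, group)
    d0 = mod.attrs["d0"]
    assert d0 > 0
    # moderated s2 lies between the gene estimate and the prior
    s2 = mod["s2"].to_numpy()
    s0 = mod.attrs["s0_2"]
    s2_mod_expect = (d0 * s0 + (n - 2) * s2) / (d0 + n - 2)
    t_expect = mod["log_fc"].to_numpy() / (np.sqrt(s2_mod_expect) *
                                           np.sqrt(4 / n))
    assert np.allclose(mod["t"].to_numpy(), t_expect, rtol=1e-8)


def test_de_moderated_blocked_pairs(rng):
    n_pairs = 12
    block = np.repeat(np.arange(n_pairs), 2)
    group = np.tile(["ctrl", "kd"], n_pairs)
    pair_effect = np.repeat(rng.standard_normal(n_pairs), 2)
    g_effect = np.where(group == "kd", 1.0, 0.0)
    expr = pd.DataFrame({
        "de": g_effect + pair_effect + 0.3 * rng.standard_normal(2 * n_pairs),
        "null": pair_effect + 0.3 * rng.standard_normal(2 * n_pairs),
    })
    res = de_moderated(expr, group, block=block)
    assert res.set_index("gene").loc["de", "p"] < 1e-4
    assert res.set_index("gene").loc["de", "log_fc"] == pytest.approx(
        1.0, abs=0.4)
    bad_block = block.copy()
    bad_block[0] = 5  # block 5 gets 3 samples
    with pytest.raises(ValueError):
        de_moderated(expr, group, block=bad_block)
    with pytest.raises(ValueError):
        de_moderated(expr, np.array(["a"] * 2 * n_pairs))


def test_de_null_fdr_control(rng):
    """Average BH-significant fraction under the global null stays <= 5%."""
    false_rates = []
    for t in range(5):
        r = np.random.default_rng(600 + t)
        expr = pd.DataFrame(r.standard_normal((40, 300)),
                            columns=[f"g{i}" for i in range(300)])
        group = np.repeat(["a", "b"], 20)
        res = de_moderated(expr, group)
        false_rates.append((res["q"] < 0.05).mean())
    assert np.mean(false_rates) <= 0.05


def test_intersect_network_de():
    de = pd.DataFrame({"gene": ["a", "b", "c", "d"],
                       "q": [0.01, 0.2, 0.04, 0.5]})
    out = intersect_network_de(["a", "b", "c"], de)
    assert out == {"n_de": 2, "n_network": 3, "percent": 66.67}
    with pytest.raises(ValueError):
        intersect_network_de([], de)


def test_moderated_de_estimator(rng):
    expr = pd.DataFrame(rng.standard_normal((24, 60)),
                        columns=[f"g{i}" for i in range(60)])
    expr.iloc[:12, 0] += 3.0
    group = np.repeat(["a", "b"], 12)
    est = ModeratedDE().fit(expr, group)
    assert "g0" in est.significant_
    assert est.d0_ == est.results_.attrs["d0"]


def test_moderated_t_matches_r_limma(tmp_path, rng):
    """Independent oracle: the R limma package must reproduce d0, s0^2 and
    every moderated t statistic."""
    if shutil.which("Rscript") is None:
        raise RuntimeError("Rscript is required for the limma oracle test")
    n, g = 16, 40
    # heterogeneous per-gene variances so the prior df d0 is finite
    gene_sd = np.sqrt(8.0 / rng.chisquare(8.0, g))
    expr = pd.DataFrame(rng.standard_normal((n, g)) * gene_sd,
                        columns=[f"g{i}" for i in range(g)])
    expr.iloc[:, :5] += np.where(np.repeat([0, 1], n // 2), 1.0, 0.0)[:, None]
    group = np.repeat(["a", "b"], n // 2)
    res = de_moderated(expr, group)

    expr.T.to_csv(tmp_path / "expr.tsv", sep="\t")
    (tmp_path / "groups.txt").write_text("\n".join(group) + "\n")
    rcode = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1))
    grp <- factor(readLines("{tmp_path}/groups.txt"))
    design <- model.matrix(~grp)
    fit <- eBayes(lmFit(x, design))
    out <- data.frame(gene=rownames(x), t=fit$t[,2], p=fit$p.value[,2])
    write.table(out, "{tmp_path}/limma.tsv", sep="\t", row.names=FALSE,
                quote=FALSE)
    cat(fit$df.prior, fit$s2.prior, sep="\\n")
    """
    proc = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                          text=True, check=True)
    d0_r, s0_r = [float(v) for v in proc.stdout.strip().split("\n")[-2:]]
    limma = pd.read_csv(tmp_path / "limma.tsv", sep="\t").set_index("gene")
    assert res.attrs["d0"] == pytest.approx(d0_r, rel=1e-6)
    assert res.attrs["s0_2"] == pytest.approx(s0_r, rel=1e-6)
    ours = res.set_index("gene")
    assert np.allclose(ours["t"].to_numpy(),
                       limma.loc[ours.index, "t"].to_numpy(), rtol=1e-8)
    assert np.allclose(ours["p"].to_numpy(),
                       limma.loc[ours.index, "p"].to_numpy(), rtol=1e-6)
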