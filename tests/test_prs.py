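"""Polygenic score construction and evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adiponet import (SimConfig, simulate_genotypes, simulate_expression,
                      simulate_traits, simulate_sumstats, LdpredInf,
                      LdpredGibbs, ClumpThreshold, ldpred_inf, ldpred_gibbs,
                      clump_threshold, score_individuals,
                      quantile_odds_ratios, cmh_compare, disease_prediction)
from adiponet.prs import block_ld, PrsWeights, _woolf_ci


def test_ldpred_inf_identity_ld_closed_form(rng):
    m, N, h2 = 30, 5000, 0.3
    beta = rng.standard_normal(m) * 0.01
    blocks = [np.eye(10)] * 3
    w = ldpred_inf(beta, blocks, N, h2)
    shrink = 1.0 / (1.0 + m / (N * h2))
    assert np.allclose(w, beta * shrink, atol=1e-12)
    # h2 = 0 collapses to zero weights
    assert np.allclose(ldpred_inf(beta, blocks, N, 0.0), 0.0)
    with pytest.raises(ValueError):
        ldpred_inf(beta, [np.eye(7)], N, h2)


def test_ldpred_inf_matches_direct_solve(rng):
    m, N, h2 = 12, 8000, 0.25
    A = rng.standard_normal((m, m))
    D = A @ A.T
    D = D / np.sqrt(np.outer(np.diag(D), np.diag(D)))
    beta = rng.standard_normal(m) * 0.02
    w = ldpred_inf(beta, [D], N, h2)
    lam = m / (N * h2)
    expect = np.linalg.solve(lam * np.eye(m) + D, beta)
    assert np.allclose(w, expect, atol=1e-10)


def test_gibbs_rho_one_approaches_infinitesimal():
    cfg = SimConfig(n_individuals=400, n_variants=100, seed=61)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    quant, *_ = simulate_traits(panel, truth, cfg)
    ss = simulate_sumstats(panel, quant)
    beta = ss["BETA"].to_numpy()
    blocks = block_ld(panel, ridge=1e-6)
    N, h2 = 400, 0.3
    w_inf = ldpred_inf(beta, blocks, N, h2)
    w_g = ldpred_gibbs(beta, blocks, N, h2, rho=1.0, n_iter=150, burn=30,
                       seed=2)
    rms = np.sqrt(np.mean((w_g - w_inf) ** 2)) / np.sqrt(np.mean(w_inf ** 2))
    assert rms <= 0.10


def test_gibbs_sparse_prior_shrinks_null_variants(rng):
    """With tiny rho, variants with weak marginals get near-zero weights."""
    m, N, h2 = 50, 20_000, 0.05
    beta = np.zeros(m)
    beta[10] = 0.08  # one strong signal
    blocks = [np.eye(m)]
    w = ldpred_gibbs(beta, blocks, N, h2, rho=0.02, n_iter=120, burn=20,
                     seed=3)
    assert abs(w[10]) > 10 * np.median(np.abs(np.delete(w, 10)))
    with pytest.raises(ValueError):
        ldpred_gibbs(beta, blocks, N, h2, rho=0.0)
    # deterministic given the seed
    w2 = ldpred_gibbs(beta, blocks, N, h2, rho=0.02, n_iter=120, burn=20,
                      seed=3)
    assert np.array_equal(w, w2)


def test_clump_threshold_properties():
    cfg = SimConfig(n_individuals=500, n_variants=300, seed=62)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    quant, *_ = simulate_traits(panel, truth, cfg)
    ss = simulate_sumstats(panel, quant)
    res = clump_threshold(ss, panel, r2_cut=0.2)
    # default five thresholds, nested by construction
    assert len(res) == 5
    sizes = [r.meta["n_variants"] for r in res]
    cuts = [r.meta["p_cut"] for r in res]
    for (s1, c1), (s2, c2) in zip(zip(sizes, cuts), zip(sizes[1:], cuts[1:])):
        if c2 < c1:
            assert s2 <= s1
    # kept index variants are pairwise below r2_cut within the window
    kept = res[0].weights["snp"].tolist()
    z = panel.standardized()
    idx = [int(np.flatnonzero(panel.variants["snp"] == s)[0]) for s in kept]
    pos = panel.variants["pos"].to_numpy()
    n = panel.n_individuals
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if abs(pos[idx[a]] - pos[idx[b]]) <= 1e6:
                r = z[:, idx[a]] @ z[:, idx[b]] / n
                assert r * r < 0.2
    # strict thresholds can be empty and are flagged, not fatal
    assert isinstance(res[-1].meta["empty"], bool)


def test_score_individuals_allele_alignment():
    cfg = SimConfig(n_individuals=50, n_variants=20, seed=63)
    panel = simulate_genotypes(cfg)
    w_alt = PrsWeights(weights=pd.DataFrame(
        {"snp": ["rs1", "rs2"], "a1": ["G", "G"], "weight": [1.0, 2.0]}),
        method="test")
    s_alt = score_individuals(panel, w_alt)
    expect = panel.dosages[:, 0] + 2 * panel.dosages[:, 1]
    assert np.allclose(s_alt, expect)
    # effect allele = ref flips the dosage
    w_ref = PrsWeights(weights=pd.DataFrame(
        {"snp": ["rs1"], "a1": ["A"], "weight": [1.0]}), method="test")
    assert np.allclose(score_individuals(panel, w_ref),
                       2.0 - panel.dosages[:, 0])
    # unknown alleles and unknown snps are dropped; all dropped -> error
    w_bad = PrsWeights(weights=pd.DataFrame(
        {"snp": ["rs1", "nope"], "a1": ["T", "G"], "weight": [1.0, 1.0]}),
        method="test")
    with pytest.raises(ValueError):
        score_individuals(panel, w_bad)


def test_estimators_fit_predict():
    cfg = SimConfig(n_individuals=400, n_variants=200, seed=64)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    quant, *_ = simulate_traits(panel, truth, cfg)
    ss = simulate_sumstats(panel, quant)
    for model in [LdpredInf(h2=0.3), ClumpThreshold(p_cut=0.5),
                  LdpredGibbs(h2=0.3, rho=0.1, n_iter=40, burn=10, seed=1)]:
        model.fit(ss, panel)
        scores = model.predict(panel)
        assert len(scores) == 400
        r = np.corrcoef(scores, quant)[0, 1]
        assert r > 0.2, f"{model} uninformative (r={r:.3f})"


def test_quantile_odds_ratios_structure(rng):
    n = 4000
    prs = rng.standard_normal(n)
    trait = prs + rng.standard_normal(n)
    sex = rng.integers(0, 2, n)
    tables = quantile_odds_ratios(prs, trait, n_quantiles=20, strata=sex)
    assert set(tables) == {0, 1}
    for t in tables.values():
        assert len(t) == 20
        assert t["odds_ratio"].iloc[0] == 1.0
        counts = t["count_top"] + t["count_rest"]
        assert counts.max() - counts.min() <= 1  # near-equal bins
        assert t.attrs["fold_change_top_vs_1"] == \
            pytest.approx(t["odds_ratio"].iloc[-1])
        # informative PRS: top quantile enriched for top-decile trait
        assert t["odds_ratio"].iloc[-1] > 3


def test_woolf_ci_and_cmh_single_stratum_identity():
    a, b, c, d = 30, 70, 10, 90
    orr, (lo, hi) = _woolf_ci(a, b, c, d)
    assert orr == pytest.approx(a * d / (b * c))
    assert lo < orr < hi
    # single-stratum CMH equals the (n-1)/n-scaled score statistic of the 2x2
    t = np.array([[a, b], [c, d]], dtype=float)
    stat, p = cmh_compare([t])
    n = t.sum()
    r1, r2 = t[0].sum(), t[1].sum()
    c1, c2 = t[:, 0].sum(), t[:, 1].sum()
    e = r1 * c1 / n
    v = r1 * r2 * c1 * c2 / (n ** 2 * (n - 1))
    expect = (a - e) ** 2 / v
    assert stat == pytest.approx(expect, rel=1e-10)
    assert p == pytest.approx(stats.chi2.sf(expect, 1), rel=1e-10)
    with pytest.raises(ValueError):
        cmh_compare([])
    with pytest.raises(ValueError):
        cmh_compare([np.array([[1, 2, 3], [4, 5, 6]])])


def test_cmh_detects_heterogeneous_strata(rng):
    # strong association in one stratum, none in the other -> large CMH chi2
    t1 = np.array([[80, 20], [20, 80]], dtype=float)
    t2 = np.array([[50, 50], [50, 50]], dtype=float)
    stat, p = cmh_compare([t1, t2])
    assert stat > 20 and p < 1e-5


def test_disease_prediction_and_separation_fallback(rng):
    n = 1500
    prs = rng.standard_normal(n)
    liab = prs + rng.standard_normal(n)
    status = (liab > np.quantile(liab, 0.9)).astype(float)
    cov = rng.standard_normal(n)
    out = disease_prediction(status, prs, cov)
    row = out[out["term"] == "prs"].iloc[0]
    assert row["beta"] > 0 and row["p"] < 1e-4
    assert out.attrs["separation"] is False
    # perfectly separated toy data falls back to the penalized fit
    prs2 = np.concatenate([np.zeros(50), np.ones(50)])
    status2 = prs2.copy()
    out2 = disease_prediction(status2, prs2 + 0.01 * rng.standard_normal(100),
                              np.zeros(100), decile_filter=False)
    assert out2.attrs["separation"] is True
    assert np.all(np.isfinite(out2["se"]))
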