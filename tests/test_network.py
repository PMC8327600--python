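"""Network discovery: transforms, adjacency, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from adiponet import (SimConfig, simulate_genotypes, simulate_expression,
                      simulate_traits, ModuleDetector, filter_and_transform,
                      pick_soft_threshold, adjacency, tom_similarity,
                      detect_modules, eigengenes, module_trait_association)
from adiponet.network import inverse_normal_transform


def test_inverse_normal_transform_is_monotone_and_standardish(rng):
    x = rng.standard_normal(501)
    z = inverse_normal_transform(x)
    assert np.all(np.diff(z[np.argsort(x)]) >= 0)
    assert abs(z.mean()) < 1e-10
    assert stats.kstest(z, "norm").pvalue > 0.2
    # ties get identical transformed values
    y = np.array([1.0, 2.0, 2.0, 3.0])
    zy = inverse_normal_transform(y)
    assert zy[1] == zy[2]


def test_filter_and_transform_filters_and_residualizes(rng):
    n = 200
    cov = rng.uniform(-1, 1, n)
    g_ok = 5.0 + 2 * cov + 0.5 * rng.standard_normal(n)  # positive FPKM-like
    g_low = np.where(rng.random(n) < 0.5, 0.0, 1.0)  # ~50% expressed
    expr = pd.DataFrame({"ok": g_ok, "low": g_low})
    out = filter_and_transform(expr, min_expressed_frac=0.9, covariates=cov)
    assert list(out.columns) == ["ok"]
    r = np.corrcoef(out["ok"], cov)[0, 1]
    assert abs(r) < 0.1
    with pytest.raises(ValueError):
        filter_and_transform(pd.DataFrame({"z": np.zeros(n)}))
    with pytest.raises(ValueError):
        filter_and_transform(expr[["ok"]], covariates=np.ones(n))


def test_adjacency_definitions(rng):
    x = rng.standard_normal((100, 5))
    cor = np.corrcoef(x, rowvar=False)
    a_u = adjacency(x, 3)
    a_s = adjacency(x, 3, signed=True)
    i, j = 1, 4
    assert a_u[i, j] == pytest.approx(abs(cor[i, j]) ** 3)
    assert a_s[i, j] == pytest.approx(((1 + cor[i, j]) / 2) ** 3)
    assert np.allclose(np.diag(a_u), 1.0)
    with pytest.raises(ValueError):
        adjacency(x, 0.5)


def test_tom_matches_triple_loop(rng):
    x = rng.standard_normal((60, 12))
    a = adjacency(x, 2)
    tom = tom_similarity(a)
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    for i in range(n):
        for j in range(n):
            if i == j:
                assert tom[i, j] == 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n)
                       if u != i and u != j)
            expect = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
            assert tom[i, j] == pytest.approx(expect, abs=1e-12)


def test_tom_in_unit_interval_and_symmetric(rng):
    x = rng.standard_normal((80, 30))
    tom = tom_similarity(adjacency(x, 6))
    assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)
    assert np.allclose(tom, tom.T)
    with pytest.raises(ValueError):
        tom_similarity(np.array([[1.0, 0.2], [0.3, 1.0]]))


def test_soft_threshold_scale_free_fit_behaviour():
    cfg = SimConfig(n_individuals=300, n_variants=60, n_module_genes=50,
                    n_background_genes=100, seed=21)
    panel = simulate_genotypes(cfg)
    expr, _ = simulate_expression(panel, cfg)
    rep = pick_soft_threshold(expr, powers=list(range(1, 7)))
    t = rep.table
    assert list(t["power"]) == [1, 2, 3, 4, 5, 6]
    # hub-and-module data: raising the power improves the scale-free fit
    # overall (endpoints ordered), and connectivity decays monotonically
    assert t["scale_free_r2"].iloc[-1] >= t["scale_free_r2"].iloc[0]
    assert np.all(np.diff(t["mean_k"]) < 0)
    # a single candidate power is returned verbatim when it qualifies
    rep10 = pick_soft_threshold(expr, powers=[10], r2_cut=0.5)
    assert rep10.chosen_power in (10, None)
    # impossible cut flags the report instead of guessing
    rep_hi = pick_soft_threshold(expr, powers=[1], r2_cut=0.999999)
    assert rep_hi.flagged


def test_detect_modules_recovers_planted_module():
    cfg = SimConfig(n_individuals=400, n_variants=100, seed=22)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    det = ModuleDetector(power=6).fit(expr)
    labels = det.labels_
    truth_lab = [1 if g in set(truth.module_genes) else 0
                 for g in expr.columns]
    pred_lab = [0 if l == "unassigned" else int(l[1:]) for l in labels]
    assert adjusted_rand_score(truth_lab, pred_lab) >= 0.8
    # the planted module maps onto a single detected module
    mod_of_hub = labels[truth.hub_gene]
    assert mod_of_hub != "unassigned"
    members = set(labels.index[labels == mod_of_hub])
    overlap = len(members & set(truth.module_genes))
    assert overlap / len(truth.module_genes) > 0.9


def test_min_module_size_labels_small_clusters_unassigned(rng):
    x = rng.standard_normal((50, 40))
    tom = tom_similarity(adjacency(x, 6))
    labels = detect_modules(tom, [f"g{i}" for i in range(40)],
                            cut_height=0.5, min_module_size=41)
    assert set(labels) == {"unassigned"}
    with pytest.raises(ValueError):
        detect_modules(tom, [f"g{i}" for i in range(40)], cut_height=1.5)


def test_eigengene_is_first_pc_and_oriented():
    cfg = SimConfig(n_individuals=300, n_variants=60, seed=23)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    labels = pd.Series("unassigned", index=expr.columns, dtype=object)
    labels[truth.module_genes] = "M1"
    eg, kme = eigengenes(expr, labels)
    assert np.linalg.norm(eg["M1"]) == pytest.approx(1.0)
    # first PC: matches direct SVD up to sign
    sub = expr[truth.module_genes].to_numpy()
    subz = (sub - sub.mean(0)) / sub.std(0)
    u = np.linalg.svd(subz, full_matrices=False)[0][:, 0]
    assert abs(abs(np.corrcoef(eg["M1"], u)[0, 1]) - 1) < 1e-10
    # orientation: mean member kME non-negative
    assert kme.loc[truth.module_genes, "M1"].mean() >= 0
    # hub gene has near-top membership
    assert kme.loc[truth.hub_gene, "M1"] > 0.8


def test_module_trait_association_bonferroni():
    rng = np.random.default_rng(31)
    n = 500
    eg = pd.DataFrame({"M1": rng.standard_normal(n),
                       "M2": rng.standard_normal(n)})
    traits = pd.DataFrame({
        "t1": 0.5 * eg["M1"].to_numpy() + rng.standard_normal(n),
        "t2": rng.standard_normal(n)})
    out = module_trait_association(eg, traits)
    thr = out.attrs["bonferroni_threshold"]
    assert thr == pytest.approx(0.05 / 4)
    row = out[(out["module"] == "M1") & (out["trait"] == "t1")].iloc[0]
    r, p = stats.pearsonr(eg["M1"], traits["t1"])
    assert row["r"] == pytest.approx(r) and row["p"] == pytest.approx(p)
    assert bool(row["significant"]) == (p < thr)
    with pytest.raises(ValueError):
        module_trait_association(eg, pd.DataFrame({"c": np.ones(n)}))


def test_module_detector_fit_predict_and_auto_power():
    cfg = SimConfig(n_individuals=250, n_variants=60, seed=24)
    panel = simulate_genotypes(cfg)
    expr, truth = simulate_expression(panel, cfg)
    det = ModuleDetector(power="auto", r2_cut=0.8)
    pred = det.fit_predict(expr)
    assert det.power_ >= 1
    assert len(pred) == expr.shape[1]
    # eigengene of the detected module correlates with the hub expression
    mod = det.labels_[truth.hub_gene]
    if mod != "unassigned":
        r = np.corrcoef(det.eigengenes_[mod], expr[truth.hub_gene])[0, 1]
        assert abs(r) > 0.8
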