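"""ssGSEA, preranked enrichment, co-expression, score tests, regulator ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from triadexpr import (SimulationConfig, compare_scores, coexpression, preranked_gsea,
                       rank_regulators, simulate_matched_pairs, ssgsea_score, uq_cpm)
from triadexpr import filter_low_abundance

from conftest import make_matrix


def test_ssgsea_top_gene_hand_value():
    """N=4, set = the single top gene, alpha=0: score = 1 + 2/3 + 1/3 + 0 = 2."""
    m = make_matrix(np.array([[10.0], [7.0], [5.0], [1.0]]), scale="abundance")
    s = ssgsea_score(m, ["g0"], alpha=0.0)
    assert s.iloc[0] == pytest.approx(2.0, abs=1e-10)


def test_ssgsea_full_set_rejected():
    m = make_matrix(np.ones((4, 1)), scale="abundance")
    with pytest.raises(ValueError, match="every gene"):
        ssgsea_score(m, [f"g{i}" for i in range(4)])


def test_ssgsea_no_overlap_rejected():
    m = make_matrix(np.ones((4, 1)), scale="abundance")
    with pytest.raises(ValueError, match="overlap"):
        ssgsea_score(m, ["absent"])


def test_ssgsea_upshift_never_decreases_score():
    rng = np.random.default_rng(0)
    vals = rng.normal(6, 2, size=(50, 3))
    m = make_matrix(vals, scale="log2cpm")
    gene_set = [f"g{i}" for i in range(0, 50, 7)]
    before = ssgsea_score(m, gene_set)
    shifted = vals.copy()
    rows = [int(g[1:]) for g in gene_set]
    shifted[rows, 1] += 2.0
    after = ssgsea_score(make_matrix(shifted, scale="log2cpm"), gene_set)
    assert after.iloc[1] >= before.iloc[1] - 1e-12
    assert after.iloc[0] == pytest.approx(before.iloc[0])


def test_ssgsea_monotone_transform_invariance():
    rng = np.random.default_rng(1)
    vals = rng.uniform(1, 100, size=(40, 4))
    gene_set = [f"g{i}" for i in range(5)]
    s1 = ssgsea_score(make_matrix(vals, scale="abundance"), gene_set)
    s2 = ssgsea_score(make_matrix(np.log1p(vals), scale="abundance"), gene_set)
    np.testing.assert_allclose(s1, s2, atol=1e-12)


def test_prerank_top_gene_es_one():
    rk = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
    res = preranked_gsea(rk, {"top": ["a"]}, n_perm=20, seed=0)
    assert res.loc["top", "es"] == pytest.approx(1.0, abs=1e-10)


def test_prerank_reversed_ranking_negates_es():
    rng = np.random.default_rng(2)
    rk = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
    sets = {"s1": [f"g{i}" for i in range(0, 12)], "s2": [f"g{i}" for i in range(30, 45)]}
    r1 = preranked_gsea(rk, sets, n_perm=10, seed=0)
    r2 = preranked_gsea(-rk, sets, n_perm=10, seed=0)
    np.testing.assert_allclose(r1["es"], -r2["es"], atol=1e-12)


def test_prerank_es_bounded_and_p_floor():
    rng = np.random.default_rng(3)
    rk = pd.Series(rng.normal(size=80), index=[f"g{i}" for i in range(80)])
    res = preranked_gsea(rk, {"s": [f"g{i}" for i in range(10)]}, n_perm=40, seed=1)
    assert -1.0 <= res.loc["s", "es"] <= 1.0
    assert res.loc["s", "p_nominal"] >= 1.0 / 41.0


def test_prerank_nominal_p_calibrated():
    """Random rankings and random sets: ~5% of sets reach nominal p < 0.05."""
    rng = np.random.default_rng(4)
    hits, total = 0, 0
    for rep in range(30):
        rk = pd.Series(rng.normal(size=150), index=[f"g{i}" for i in range(150)])
        sets = {f"s{j}": list(rng.choice(rk.index, size=12, replace=False))
                for j in range(4)}
        res = preranked_gsea(rk, sets, n_perm=99, seed=rep)
        hits += int((res["p_nominal"] < 0.05).sum())
        total += len(sets)
    assert 0.01 <= hits / total <= 0.10


def test_coexpression_duplicated_gene_perfect_rho():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    vals = np.vstack([x, x, rng.normal(size=30)])
    m = make_matrix(vals, scale="abundance")
    rho = coexpression(m, ["g0", "g1", "g2"])
    assert rho.loc["g0", "g1"] == pytest.approx(1.0)
    assert np.allclose(np.diag(rho), 1.0)


def test_coexpression_monotone_transform_invariance():
    rng = np.random.default_rng(6)
    vals = rng.uniform(1, 50, size=(3, 40))
    m1 = make_matrix(vals, scale="abundance")
    vals2 = vals.copy()
    vals2[0] = vals2[0] ** 3
    m2 = make_matrix(vals2, scale="abundance")
    r1 = coexpression(m1, ["g0", "g1", "g2"])
    r2 = coexpression(m2, ["g0", "g1", "g2"])
    np.testing.assert_allclose(r1, r2, atol=1e-12)


def test_coexpression_independent_genes_low_rho():
    rng = np.random.default_rng(7)
    vals = rng.normal(size=(20, 500))
    m = make_matrix(vals, scale="abundance")
    rho = coexpression(m, list(m.genes)).to_numpy()
    off = rho[~np.eye(20, dtype=bool)]
    assert np.abs(off).mean() < 0.1


def test_coexpression_constant_gene_nan(caplog):
    vals = np.vstack([np.full(10, 7.0), np.arange(10.0), np.arange(10.0)[::-1]])
    m = make_matrix(vals, scale="abundance")
    with caplog.at_level("WARNING"):
        rho = coexpression(m, ["g0", "g1", "g2"])
    assert rho.loc["g0"].isna().all()
    assert rho.loc["g1", "g2"] == pytest.approx(-1.0)


def test_compare_scores_identical_groups_p_near_one():
    s = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    out = compare_scores(s, ["a"] * 3 + ["b"] * 3, ("a", "b"))
    assert out["p_raw"] > 0.9


def test_compare_scores_complete_separation_exact_p():
    """n=10 vs 10 with no overlap: exact two-sided p = 2 / C(20,10)."""
    s = pd.Series(np.concatenate([np.arange(10), np.arange(100, 110)]), dtype=float)
    out = compare_scores(s, ["a"] * 10 + ["b"] * 10, ("a", "b"))
    assert out["p_raw"] == pytest.approx(2 / comb(20, 10), rel=1e-10)


def test_compare_scores_single_sample_group_ok():
    s = pd.Series([1.0, 2.0, 3.0, 2.5])
    out = compare_scores(s, ["a", "a", "a", "b"], ("a", "b"))
    assert 0.0 < out["p_raw"] <= 1.0
    assert out["n2"] == 1


def test_compare_scores_empty_group_error():
    s = pd.Series([1.0, 2.0])
    with pytest.raises(ValueError, match="empty group"):
        compare_scores(s, ["a", "a"], ("a", "b"))


def _matched_setup(seed, driver_effect, n_subjects=120):
    cfg = SimulationConfig(n_genes=600, n_tissues=1,
                           samples_per_condition={"H": 4, "A": n_subjects, "T": n_subjects},
                           model_proportions={"UD": 0.03}, min_shared_tissues=2,
                           effect_log2fc=2.0, driver_effect=driver_effect, seed=seed)
    em, truth = simulate_matched_pairs(cfg)
    lc = uq_cpm(filter_low_abundance(em), log2=True)
    nat = lc.subset_samples(lc.condition_mask("A"))
    tum = lc.subset_samples(lc.condition_mask("T"))
    tasa = list(truth.models.index[truth.models["tissue1"] == "UD"])
    scores = ssgsea_score(nat, tasa)
    return rank_regulators(scores, tum, nat.samples), truth


def test_rank_regulators_recovers_planted_driver():
    rank, truth = _matched_setup(seed=11, driver_effect=1.0)
    row = rank[rank["gene"] == truth.driver_gene]
    assert float(row["top_pct"].iloc[0]) <= 1.0


def test_rank_regulators_too_few_pairs_error():
    rank_table, truth = None, None
    cfg = SimulationConfig(n_genes=100, n_tissues=1,
                           samples_per_condition={"H": 3, "A": 3, "T": 3}, seed=1)
    em, truth = simulate_matched_pairs(cfg)
    lc = uq_cpm(em, log2=True)
    nat = lc.subset_samples(lc.condition_mask("A"))
    tum = lc.subset_samples(lc.condition_mask("T"))
    scores = pd.Series(np.arange(2.0), index=nat.sample_ids[:2])
    with pytest.raises(ValueError, match="matched pairs"):
        rank_regulators(scores, tum, nat.samples)


def test_rank_regulators_constant_gene_excluded(caplog):
    rng = np.random.default_rng(8)
    n = 10
    vals = rng.normal(6, 1, size=(5, n))
    vals[2] = 4.2  # constant across subjects
    meta_t = pd.DataFrame({"sample": [f"T{i}" for i in range(n)], "tissue": "t1",
                           "condition": "T", "source": "c",
                           "subject": [f"p{i}" for i in range(n)]})
    from triadexpr import ExpressionMatrix
    tum = ExpressionMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(5)],
                                        columns=meta_t["sample"]), meta_t, scale="log2cpm")
    nat_meta = pd.DataFrame({"sample": [f"A{i}" for i in range(n)],
                             "subject": [f"p{i}" for i in range(n)]})
    scores = pd.Series(rng.normal(size=n), index=nat_meta["sample"])
    with caplog.at_level("WARNING"):
        out = rank_regulators(scores, tum, nat_meta)
    assert "g2" not in set(out["gene"])
    assert len(out) == 4
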