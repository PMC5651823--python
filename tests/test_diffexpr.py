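"""NB GLM differential expression: dispersion, LRT calibration, gates."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from triadexpr import (SimulationConfig, classify_status, estimate_dispersion,
                       estimate_unwanted, simulate_triad, uq_cpm)
from triadexpr import test_de as run_de
from triadexpr.preprocess import uq_scale_factors

from conftest import make_matrix


def _two_group(seed=0, phi=0.2, n=50, n_genes=2000):
    cfg = SimulationConfig(n_genes=n_genes, n_tissues=1, n_housekeeping=5,
                           samples_per_condition={"H": n, "A": n},
                           model_proportions={}, n_unwanted_factors=0,
                           libsize_by_source={"c1": (0.0, 0.1)},
                           dispersion=phi, seed=seed)
    em, _ = simulate_triad(cfg)
    return em, em.samples["condition"].to_numpy()


def test_dispersion_poisson_data_near_zero():
    em, labels = _two_group(seed=1, phi=0.0)
    phi_hat = estimate_dispersion(em, labels)
    assert float(phi_hat.median()) <= 0.05


def test_dispersion_nb_data_recovered():
    em, labels = _two_group(seed=2, phi=0.4)
    phi_hat = estimate_dispersion(em, labels)
    assert 0.3 <= float(phi_hat.mean()) <= 0.5


def test_dispersion_constant_counts_zero_floor():
    vals = np.full((3, 8), 20)
    m = make_matrix(vals, conditions=["H"] * 4 + ["A"] * 4)
    phi_hat = estimate_dispersion(m, m.samples["condition"].to_numpy())
    np.testing.assert_allclose(phi_hat, 0.0)


def test_dispersion_small_group_error():
    m = make_matrix(np.ones((3, 3), dtype=int) * 5, conditions=["H", "H", "A"])
    with pytest.raises(ValueError, match="fewer than 2"):
        estimate_dispersion(m, m.samples["condition"].to_numpy())


@pytest.mark.parametrize("p_bonf,log2fc,avg,expected", [
    (0.01, 1.5, 4.0, "U"),    # all gates pass
    (0.01, 0.8, 4.0, "S"),    # fold-change gate fails
    (0.2, 3.0, 6.0, "S"),     # significance gate fails
    (0.01, -1.5, 4.0, "D"),
    (0.01, 1.5, 2.0, "S"),    # abundance gate fails
    (0.01, 1.0, 4.0, "S"),    # strict inequality at the fold-change boundary
])
def test_classify_status_gates(p_bonf, log2fc, avg, expected):
    assert classify_status([log2fc], [p_bonf], [avg])[0] == expected


def test_identical_groups_gene_is_stable():
    rng = np.random.default_rng(0)
    col = rng.poisson(60, size=30)
    vals = np.column_stack([col] * 8)
    m = make_matrix(vals, conditions=["H"] * 4 + ["A"] * 4)
    de = run_de(m, m.samples["condition"].to_numpy(), contrast=("H", "A"))
    np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-8)
    assert (de["status"] == "S").all()


def test_label_swap_negates_lfc_keeps_p():
    em, labels = _two_group(seed=3, n=10, n_genes=100)
    d1 = run_de(em, labels, contrast=("H", "A"))
    d2 = run_de(em, labels, contrast=("A", "H"))
    np.testing.assert_allclose(d1["log2fc"], -d2["log2fc"], atol=1e-10)
    np.testing.assert_allclose(d1["p_raw"], d2["p_raw"], atol=1e-10)


def test_poisson_limit_matches_glm_oracle():
    """phi=0, no covariates: p-values match a Poisson GLM LRT fit per gene."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(4)
    counts = rng.poisson(rng.uniform(20, 200, size=(15, 1)), size=(15, 16))
    labels = np.array(["H"] * 8 + ["A"] * 8)
    m = make_matrix(counts, conditions=labels)
    de = run_de(m, labels, contrast=("H", "A"),
                 phi=pd.Series(0.0, index=m.genes))
    eff = m.values.sum(axis=0).to_numpy() * uq_scale_factors(m).to_numpy()
    X = np.column_stack([np.ones(16), (labels == "A").astype(float)])
    for i in range(m.n_genes):
        full = sm.GLM(counts[i], X, family=sm.families.Poisson(),
                      offset=np.log(eff)).fit()
        red = sm.GLM(counts[i], X[:, :1], family=sm.families.Poisson(),
                     offset=np.log(eff)).fit()
        p = chi2.sf(2 * (full.llf - red.llf), 1)
        assert de["p_raw"].iloc[i] == pytest.approx(p, abs=1e-6)


def test_planted_effect_recovery():
    cfg = SimulationConfig(n_genes=1500, n_tissues=1,
                           samples_per_condition={"H": 30, "A": 30},
                           effect_log2fc=2.0, dispersion=0.2, seed=5)
    em, truth = simulate_triad(cfg)
    de = run_de(em, em.samples["condition"].to_numpy(), contrast=("H", "A"))
    planted = truth.planted_status("tissue1", "AH").reindex(de.index)
    deg = planted.isin(["U", "D"])
    assert (de.loc[deg, "status"] == planted[deg]).mean() >= 0.90


def test_bonferroni_scales_with_tested_universe():
    """p_bonf = min(1, p_raw * G) where G is the tested-gene count of the run."""
    em, labels = _two_group(seed=6, n=10, n_genes=120)
    phi = pd.Series(0.2, index=em.genes)
    full = run_de(em, labels, contrast=("H", "A"), phi=phi)
    small = run_de(em.subset_genes(em.genes[:40]), labels, contrast=("H", "A"),
                   phi=phi)
    for res, G in ((full, 120), (small, 40)):
        np.testing.assert_allclose(res["p_bonf"],
                                   np.minimum(1.0, res["p_raw"] * G), atol=1e-15)
    # enlarging the universe never shrinks the correction factor
    assert (full["p_bonf"].to_numpy()
            >= np.minimum(1.0, full["p_raw"].to_numpy() * 40) - 1e-15).all()


def test_singular_design_rejected():
    em, labels = _two_group(seed=7, n=5, n_genes=30)
    lc = uq_cpm(em, log2=True)
    w = estimate_unwanted(lc, list(em.genes[:10]), 1)
    # overwrite the factor with the group indicator (centered, normalized)
    g = (labels == "A").astype(float)
    g = (g - g.mean()) / np.linalg.norm(g - g.mean())
    w.factors.iloc[:, 0] = g
    with pytest.raises(ValueError, match="singular|collinear"):
        run_de(em, labels, contrast=("H", "A"), w=w)


def test_needs_exactly_two_groups():
    m = make_matrix(np.ones((3, 4), dtype=int), conditions=["H", "A", "T", "H"])
    with pytest.raises(ValueError, match="two groups"):
        run_de(m, m.samples["condition"].to_numpy())
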