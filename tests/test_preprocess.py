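"""Filtering, UQ-CPM, control-gene factor estimation/removal and RLE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triadexpr import (SimulationConfig, estimate_unwanted, filter_low_abundance,
                       remove_unwanted, rle, simulate_triad, uq_cpm)
from triadexpr.preprocess import uq_scale_factors

from conftest import make_matrix


@pytest.mark.parametrize("counts,kept", [
    ([9, 9, 9, 9], False),       # below threshold everywhere
    ([10, 10, 0, 0], True),      # two qualifying samples
    ([1000, 0, 0, 0], False),    # only one qualifying sample
    ([10, 9, 10, 0], True),
])
def test_filter_low_abundance_rules(counts, kept):
    m = make_matrix(np.vstack([counts, [50, 50, 50, 50]]), genes=["probe", "anchor"])
    out = filter_low_abundance(m)
    assert ("probe" in out.genes) == kept
    assert list(out.sample_ids) == list(m.sample_ids)


def test_filter_idempotent(small_triad):
    _, em, _ = small_triad
    once = filter_low_abundance(em)
    twice = filter_low_abundance(once)
    assert once.values.equals(twice.values)


def test_filter_rejects_non_counts():
    m = make_matrix(np.ones((3, 3)), scale="cpm")
    with pytest.raises(ValueError, match="counts"):
        filter_low_abundance(m)


def test_uq_cpm_identical_samples_symmetric():
    col = np.array([0, 100, 200, 700])
    m = make_matrix(np.column_stack([col, col]))
    out = uq_cpm(m)
    np.testing.assert_allclose(out.attrs["uq_scale"], [1.0, 1.0])
    np.testing.assert_allclose(out.values.to_numpy()[:, 0], col / col.sum() * 1e6)
    np.testing.assert_allclose(out.values.to_numpy()[:, 1], col / col.sum() * 1e6)


def test_uq_cpm_scale_invariance():
    rng = np.random.default_rng(0)
    a = rng.poisson(40, size=50)
    m = make_matrix(np.column_stack([a, 2 * a, rng.poisson(60, size=50)]))
    out = uq_cpm(m)
    np.testing.assert_allclose(out.values.to_numpy()[:, 0], out.values.to_numpy()[:, 1],
                               rtol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(1, 7), st.integers(0, 2 ** 31 - 1))
def test_uq_cpm_invariant_to_per_sample_rescaling(factor, seed):
    rng = np.random.default_rng(seed)
    base = rng.poisson(30, size=(20, 3)) + 1
    m1 = make_matrix(base)
    scaled = base.copy()
    scaled[:, 1] *= factor
    m2 = make_matrix(scaled)
    np.testing.assert_allclose(uq_cpm(m1).values.to_numpy(),
                               uq_cpm(m2).values.to_numpy(), rtol=1e-9)


def test_uq_cpm_all_zero_sample_error():
    m = make_matrix(np.column_stack([[1, 2, 3], [0, 0, 0]]))
    with pytest.raises(ValueError, match="s1"):
        uq_cpm(m)


def _log2cpm_of(cfg_seed=0, **kw):
    base = dict(n_genes=400, n_tissues=1, samples_per_condition={"H": 15, "A": 15},
                n_unwanted_factors=1, model_proportions={}, seed=cfg_seed)
    base.update(kw)
    cfg = SimulationConfig(**base)
    em, truth = simulate_triad(cfg)
    return uq_cpm(filter_low_abundance(em), log2=True), truth


def test_estimate_unwanted_k0_empty():
    lc, truth = _log2cpm_of(n_unwanted_factors=0)
    w = estimate_unwanted(lc, truth.housekeeping, 0)
    assert w.k == 0
    assert remove_unwanted(lc, w).values.equals(lc.values)


def test_estimate_unwanted_factor_columns_orthonormal():
    lc, truth = _log2cpm_of(3)
    w = estimate_unwanted(lc, truth.housekeeping, 3)
    F = w.factors.to_numpy()
    np.testing.assert_allclose(F.T @ F, np.eye(3), atol=1e-8)


def test_estimate_unwanted_recovers_planted_factor_noise_free():
    """A planted factor in noise-free log expression is recovered almost exactly."""
    rng = np.random.default_rng(1)
    n, g = 30, 60
    score = rng.normal(size=n)
    loading = rng.normal(size=g)
    vals = 8.0 + np.outer(loading, score)
    m = make_matrix(vals, scale="log2cpm")
    w = estimate_unwanted(m, list(m.genes), 1)
    r = np.corrcoef(w.factors.to_numpy()[:, 0], score)[0, 1]
    assert abs(r) > 0.99


def test_estimate_unwanted_constant_controls_no_signal():
    rng = np.random.default_rng(2)
    vals = np.vstack([np.full((5, 20), 3.0), rng.normal(5, 1, size=(40, 20))])
    m = make_matrix(vals, scale="log2cpm")
    controls = [f"g{i}" for i in range(5)]
    w = estimate_unwanted(m, controls, 1)
    ctrl = m.values.loc[controls].to_numpy().T
    ctrl = ctrl - ctrl.mean(0)
    explained = np.linalg.norm(ctrl.T @ w.factors.to_numpy()) ** 2
    assert explained <= 1e-20


def test_estimate_unwanted_k_bound_error():
    lc, truth = _log2cpm_of()
    with pytest.raises(ValueError, match="out of range"):
        estimate_unwanted(lc, truth.housekeeping[:4], 5)


def test_remove_unwanted_projects_out_factor_gene():
    lc, truth = _log2cpm_of(4)
    w = estimate_unwanted(lc, truth.housekeeping, 1)
    doped = lc.values.copy()
    doped.iloc[0] = 5.0 + 2.0 * w.factors.to_numpy()[:, 0]
    m2 = lc.with_values(doped)
    cleaned = remove_unwanted(m2, w)
    assert cleaned.values.shape == doped.shape
    assert cleaned.values.iloc[0].var() < 1e-20


def test_remove_unwanted_sample_mismatch_error():
    lc, truth = _log2cpm_of(5)
    w = estimate_unwanted(lc, truth.housekeeping, 1)
    sub = lc.subset_samples(np.arange(lc.n_samples) < lc.n_samples - 1)
    with pytest.raises(ValueError, match="mismatch"):
        remove_unwanted(sub, w)


def test_rle_identical_samples_zero():
    col = np.array([1.0, 2.0, 5.0])
    m = make_matrix(np.column_stack([col] * 4), scale="log2cpm")
    out = rle(m)
    np.testing.assert_allclose(out["rle_median"], 0.0)
    np.testing.assert_allclose(out["rle_iqr"], 0.0)


def test_rle_single_shifted_sample():
    """3-sample toy: +1 shift puts that sample's RLE median at +1, others at 0."""
    rng = np.random.default_rng(0)
    base = rng.normal(6, 1, size=100)
    vals = np.column_stack([base, base, base + 1.0])
    out = rle(make_matrix(vals, scale="log2cpm"))
    np.testing.assert_allclose(out["rle_median"].to_numpy(), [0.0, 0.0, 1.0], atol=1e-12)


def test_rle_single_sample_all_zero():
    out = rle(make_matrix(np.array([[1.0], [4.0]]), scale="log2cpm"))
    np.testing.assert_allclose(out["rle_median"], 0.0)


def test_uq_scale_factors_mean_one(small_triad):
    _, em, _ = small_triad
    s = uq_scale_factors(em)
    assert abs(s.mean() - 1.0) < 1e-12
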