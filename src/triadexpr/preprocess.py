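"""Filtering, upper-quartile CPM normalization, control-gene factor removal, RLE.

Cross-cohort count data carry technical variation (library size, preparation
batches) that would otherwise masquerade as condition effects.  This module
provides the standard count pipeline: low-abundance filtering, upper-quartile
CPM with per-sample scale factors, estimation of unwanted-variation factors
from negative-control (housekeeping) genes by SVD of their centered
log-expression, regression-based removal of those factors, and relative
log-expression (RLE) diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class UnwantedVariation:
    """Estimated unwanted-variation factor scores.

    ``factors`` is a sample x k frame of orthonormal score columns (the left
    singular vectors of the centered control-gene matrix); ``control_genes``
    records the negative-control set used.
    """

    factors: pd.DataFrame
    control_genes: list[str]

    @property
    def k(self) -> int:
        return self.factors.shape[1]


def filter_low_abundance(m: ExpressionMatrix, min_reads: int = 10,
                         min_samples: int = 2) -> ExpressionMatrix:
    """Keep genes with >= ``min_reads`` reads in >= ``min_samples`` samples."""
    if m.scale != "counts":
        raise ValueError(f"filter_low_abundance requires counts, got scale {m.scale!r}")
    ok = (m.values.to_numpy() >= min_reads).sum(axis=1) >= min_samples
    return m.subset_genes(m.genes[ok])


def uq_scale_factors(m: ExpressionMatrix) -> pd.Series:
    """Per-sample upper-quartile scale factors.

    The factor is the sample's 75th percentile (linear interpolation) of its
    non-zero count *fractions* (count / library size), divided by the
    across-sample mean of those percentiles.  Factors average to one and the
    effective library size is ``libsize * factor``; computing the quartile on
    fractions rather than raw counts makes the factors — and hence UQ-CPM —
    invariant to rescaling a sample's counts by a positive constant.
    """
    arr = m.values.to_numpy(float)
    libsize = arr.sum(axis=0)
    uq = np.empty(m.n_samples)
    for j in range(m.n_samples):
        col = arr[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {m.sample_ids[j]!r} has all-zero counts")
        uq[j] = np.percentile(nz, 75) / libsize[j]
    scale = uq / uq.mean()
    return pd.Series(scale, index=m.sample_ids, name="uq_scale")


def uq_cpm(m: ExpressionMatrix, log2: bool = False, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Upper-quartile-normalized counts per million.

    ``CPM_gj = count_gj / (libsize_j * scale_j) * 1e6`` with the scale factors
    of :func:`uq_scale_factors`.  With ``log2=True`` returns
    ``log2(CPM + pseudocount)``.
    """
    if m.scale != "counts":
        raise ValueError(f"uq_cpm requires counts, got scale {m.scale!r}")
    scale = uq_scale_factors(m)
    libsize = m.values.sum(axis=0).astype(float)
    eff = libsize * scale
    cpm = m.values / eff * 1e6
    out = m.with_values(cpm, scale="cpm")
    out.attrs["uq_scale"] = scale
    out.attrs["libsize"] = libsize
    if log2:
        out = out.with_values(np.log2(cpm + pseudocount), scale="log2cpm")
        out.attrs["uq_scale"] = scale
        out.attrs["libsize"] = libsize
    return out


def estimate_unwanted(m: ExpressionMatrix, controls, k: int) -> UnwantedVariation:
    """Estimate k unwanted-variation factors from negative-control genes.

    The factors are the first k left singular vectors of the sample x
    control-gene log2-CPM matrix after centering each control gene across
    samples.  Because controls carry no condition effect, variation captured
    here is attributed to technical sources.
    """
    if m.scale != "log2cpm":
        raise ValueError(f"estimate_unwanted requires log2cpm, got {m.scale!r}")
    controls = [g for g in controls if g in set(m.genes)]
    if not controls:
        raise ValueError("no control genes present in the matrix")
    kmax = min(len(controls), m.n_samples - 1)
    if not (0 <= k <= kmax):
        raise ValueError(f"k={k} out of range [0, {kmax}] "
                         f"(min(#controls, #samples - 1))")
    if k == 0:
        factors = pd.DataFrame(np.zeros((m.n_samples, 0)), index=m.sample_ids)
        return UnwantedVariation(factors=factors, control_genes=controls)
    ctrl = m.values.loc[controls].to_numpy(float).T  # samples x controls
    ctrl = ctrl - ctrl.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(ctrl, full_matrices=False)
    factors = pd.DataFrame(u[:, :k], index=m.sample_ids,
                           columns=[f"W{i + 1}" for i in range(k)])
    return UnwantedVariation(factors=factors, control_genes=controls)


def remove_unwanted(m: ExpressionMatrix, w: UnwantedVariation) -> ExpressionMatrix:
    """Regress each gene on the factor scores and subtract the fitted part.

    Shape and ordering are preserved; with zero factors this is the identity.
    Used for diagnostics and signature scoring — the DE stage instead takes
    the factors as model covariates.
    """
    if m.scale != "log2cpm":
        raise ValueError(f"remove_unwanted requires log2cpm, got {m.scale!r}")
    if list(w.factors.index) != list(m.sample_ids):
        raise ValueError("sample mismatch between matrix and unwanted-variation factors")
    if w.k == 0:
        return m.with_values(m.values.copy())
    X = np.column_stack([np.ones(m.n_samples), w.factors.to_numpy()])
    Y = m.values.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X[:, 1:] @ beta[1:]  # keep the intercept (gene means)
    return m.with_values(pd.DataFrame((Y - fitted).T, index=m.genes, columns=m.sample_ids))


def rle(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample relative log expression summary (median and IQR).

    ``RLE_gj = log2 expression - per-gene median across samples``; a
    well-normalized dataset has per-sample RLE medians near zero.
    """
    if m.scale != "log2cpm":
        raise ValueError(f"rle requires log2cpm, got {m.scale!r}")
    arr = m.values.to_numpy(float)
    dev = arr - np.median(arr, axis=1, keepdims=True)
    med = np.median(dev, axis=0)
    q75, q25 = np.percentile(dev, [75, 25], axis=0)
    return pd.DataFrame({"sample": m.sample_ids, "rle_median": med,
                         "rle_iqr": q75 - q25}).set_index("sample")
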