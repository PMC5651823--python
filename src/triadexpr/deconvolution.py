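"""Two-reference expression deconvolution.

Each sample profile x is decomposed as a convex combination of a healthy and
a tumor reference profile: minimize ||x - S f||^2 subject to f >= 0 and
sum(f) = 1.  With exactly two references the quadratic program collapses to a
single-variable constrained least squares whose solution is the projection of
the unconstrained optimum onto [0, 1] — exact and deterministic, no iterative
solver.  The reported ``fraction_tumor`` is the tumor weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def build_signature(m: ExpressionMatrix, tissue: str) -> pd.DataFrame:
    """Gene x 2 reference: arithmetic mean healthy and tumor profiles.

    Computed on the normalized-abundance scale of ``m`` restricted to one
    tissue; both conditions must be present.
    """
    mh = m.select(tissue=tissue, condition="H")
    mt = m.select(tissue=tissue, condition="T")
    if mh.n_samples == 0 or mt.n_samples == 0:
        missing = "H" if mh.n_samples == 0 else "T"
        raise ValueError(f"tissue {tissue!r} lacks condition {missing!r} samples")
    return pd.DataFrame({"healthy": mh.values.mean(axis=1),
                         "tumor": mt.values.mean(axis=1)})


def deconvolve(x, signature: pd.DataFrame) -> dict[str, float]:
    """Tumor-similarity fraction of one sample profile.

    ``x`` is a gene-indexed Series (or array aligned with the signature).
    Returns ``fraction_tumor`` in [0, 1] and the residual norm of the fit.
    """
    if isinstance(x, pd.Series):
        x = x.reindex(signature.index).to_numpy(float)
    else:
        x = np.asarray(x, dtype=float)
    h = signature["healthy"].to_numpy(float)
    t = signature["tumor"].to_numpy(float)
    d = t - h
    nd = float(d @ d)
    if nd == 0:
        raise ValueError("healthy and tumor reference columns are identical; "
                         "mixture fraction is unidentifiable")
    f = float(np.clip((x - h) @ d / nd, 0.0, 1.0))
    resid = x - (h + f * d)
    return {"fraction_tumor": f, "residual_norm": float(np.linalg.norm(resid))}


def deconvolve_matrix(m: ExpressionMatrix, signature: pd.DataFrame) -> pd.DataFrame:
    """Deconvolve every sample of ``m`` against one signature."""
    shared = signature.index.intersection(m.genes)
    sig = signature.loc[shared]
    rows = []
    for j, smp in enumerate(m.sample_ids):
        res = deconvolve(m.values[smp].loc[shared], sig)
        rows.append({"sample": smp,
                     "tissue": m.samples.at[j, "tissue"],
                     "condition": m.samples.at[j, "condition"],
                     **res})
    return pd.DataFrame(rows).set_index("sample")
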