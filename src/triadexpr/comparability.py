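"""Cross-cohort comparability checks.

Two sanity checks precede any joint analysis of samples from different
cohorts: (1) every tumor-adjacent (NAT) sample should correlate best with the
median healthy profile of its own tissue; (2) housekeeping genes should show
concordant median levels and variability between the healthy and NAT
compartments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """Per-tissue median healthy expression profiles (gene x tissue)."""

    medians: pd.DataFrame

    @property
    def tissues(self) -> list[str]:
        return list(self.medians.columns)


def build_reference(m: ExpressionMatrix) -> ReferencePanel:
    """Median profile of the healthy (H) samples of each tissue."""
    cols = {}
    for t in m.tissues():
        sub = m.select(tissue=t, condition="H")
        if sub.n_samples == 0:
            raise ValueError(f"tissue {t!r} has no healthy (H) samples")
        cols[t] = sub.values.median(axis=1)
    return ReferencePanel(medians=pd.DataFrame(cols))


def assign_tissue(panel: ReferencePanel, m: ExpressionMatrix) -> pd.DataFrame:
    """Assign each sample to the tissue whose median profile it best matches.

    Best tissue is the argmax of Pearson correlation between the sample
    profile and each tissue median on the shared gene universe; ties go to the
    first tissue in panel order (logged).  The result records the correlation
    and, where metadata carries a tissue label, whether the call is correct.
    """
    shared = panel.medians.index.intersection(m.genes)
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes; correlation undefined")
    R = panel.medians.loc[shared].to_numpy(float)     # genes x tissues
    X = m.values.loc[shared].to_numpy(float)          # genes x samples
    Rc = R - R.mean(axis=0, keepdims=True)
    Xc = X - X.mean(axis=0, keepdims=True)
    denom = np.outer(np.linalg.norm(Xc, axis=0), np.linalg.norm(Rc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ Rc) / denom                    # samples x tissues
    corr = np.nan_to_num(corr, nan=-np.inf)
    best = corr.argmax(axis=1)
    ties = (corr == corr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    for j in np.flatnonzero(ties):
        log.warning("tissue assignment tie for sample %s; keeping first tissue in panel order",
                    m.sample_ids[j])
    tissues = panel.tissues
    out = pd.DataFrame({
        "sample": m.sample_ids,
        "assigned": [tissues[i] for i in best],
        "correlation": corr[np.arange(len(best)), best],
    })
    out["true_tissue"] = m.samples["tissue"].to_numpy()
    out["correct"] = out["assigned"] == out["true_tissue"]
    return out


def housekeeping_concordance(m_h: ExpressionMatrix, m_a: ExpressionMatrix,
                             hk) -> dict[str, float]:
    """Concordance of housekeeping genes between healthy and NAT compartments.

    Pools per-(gene, tissue) median log2 levels of the housekeeping genes in
    the two matrices and reports their Pearson correlation, plus the Spearman
    correlation of the matching per-(gene, tissue) standard deviations.
    Zero-variance points contribute to medians but SD pairs with zero spread
    on both sides are kept (rank ties are handled by averaging).
    """
    hk = [g for g in hk if g in set(m_h.genes) and g in set(m_a.genes)]
    if not hk:
        raise ValueError("no housekeeping genes shared by both matrices")
    med_h, med_a, sd_h, sd_a = [], [], [], []
    tissues = sorted(set(m_h.tissues()) & set(m_a.tissues()))
    for t in tissues:
        vh = m_h.select(tissue=t).values.loc[hk]
        va = m_a.select(tissue=t).values.loc[hk]
        med_h.append(vh.median(axis=1))
        med_a.append(va.median(axis=1))
        sd_h.append(vh.std(axis=1, ddof=1))
        sd_a.append(va.std(axis=1, ddof=1))
    med_h = pd.concat(med_h).to_numpy(float)
    med_a = pd.concat(med_a).to_numpy(float)
    sd_h = pd.concat(sd_h).to_numpy(float)
    sd_a = pd.concat(sd_a).to_numpy(float)
    if med_h.size < 2:
        raise ValueError("need at least 2 (gene, tissue) points for a correlation")
    pear = float(pearsonr(med_h, med_a).statistic)
    ok = np.isfinite(sd_h) & np.isfinite(sd_a)
    spear = float(spearmanr(sd_h[ok], sd_a[ok]).statistic) if ok.sum() >= 2 else float("nan")
    return {"pearson_median": pear, "spearman_sd": spear,
            "n_points": int(med_h.size), "n_genes": len(hk), "n_tissues": len(tissues)}
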