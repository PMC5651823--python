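"""Effect of the control choice on tumor differential expression.

Tumor DE can use healthy tissue (T:H) or tumor-adjacent tissue (T:A) as the
control.  This module quantifies how much the two choices agree: the Pearson
correlation of the log2 fold-change vectors over the common tested universe,
the DEG counts of each contrast, their overlap, the mutual overlap fractions
and the counts of discordant genes (significant in both contrasts with
opposite direction).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


@dataclass
class ControlComparison:
    """Agreement summary between the T:H and T:A contrasts."""

    r_logfc: float
    n_th: int
    n_ta: int
    n_both: int
    n_up_th_down_ta: int
    n_down_th_up_ta: int
    frac_ta_in_th: float
    frac_th_in_ta: float
    n_genes: int

    def as_dict(self) -> dict:
        return asdict(self)


def compare_controls(de_th: pd.DataFrame, de_ta: pd.DataFrame) -> ControlComparison:
    """Compare tumor-vs-healthy and tumor-vs-NAT DE results.

    All quantities are computed on the intersection of the tested gene
    universes; the fold-change correlation uses all tested genes, not only
    the significant ones.
    """
    shared = de_th.index.intersection(de_ta.index)
    if len(shared) == 0:
        raise ValueError("the two DE results share no tested genes")
    th = de_th.loc[shared]
    ta = de_ta.loc[shared]
    r = float(pearsonr(th["log2fc"].to_numpy(float),
                       ta["log2fc"].to_numpy(float)).statistic) if len(shared) >= 2 else float("nan")
    sig_th = th["status"] != "S"
    sig_ta = ta["status"] != "S"
    both = sig_th & sig_ta
    n_th, n_ta, n_both = int(sig_th.sum()), int(sig_ta.sum()), int(both.sum())
    up_down = int((both & (th["status"] == "U") & (ta["status"] == "D")).sum())
    down_up = int((both & (th["status"] == "D") & (ta["status"] == "U")).sum())
    return ControlComparison(
        r_logfc=r, n_th=n_th, n_ta=n_ta, n_both=n_both,
        n_up_th_down_ta=up_down, n_down_th_up_ta=down_up,
        frac_ta_in_th=n_both / n_ta if n_ta else float("nan"),
        frac_th_in_ta=n_both / n_th if n_th else float("nan"),
        n_genes=int(len(shared)))
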