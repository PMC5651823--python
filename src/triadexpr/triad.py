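"""Nine expression models, within-tissue model enrichment and cross-tissue sharing.

Combining the NAT-vs-healthy (A:H) and tumor-vs-NAT (T:A) calls assigns each
gene, per tissue, one of nine models: the 3x3 combinations of {U, D, S}.
``UD`` is tumor-adjacent-specific activation (TASA: up in NAT relative to both
neighbours) and ``DU`` its repression counterpart; ``UU``/``DD`` are gradient
models, ``SS`` the null.

Sharing of a model across tissues is judged against an independence null: a
gene's chance of carrying the model in >= k of T tissues is the tail of a
Poisson-Binomial with per-tissue marginal rates, the expected shared count is
``lambda = G * tail``, and the observed count gets a Poisson upper-tail
p-value at that lambda (the Poisson approximation to the Binomial over genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .synthetic import MODELS

#: TriadAssignment: gene x tissue DataFrame of two-letter model labels.
TriadAssignment = pd.DataFrame


@dataclass
class SharingResult:
    """Observed vs expected count of genes carrying a model in >= k tissues."""

    k: int
    observed: int
    #: per-gene Poisson-Binomial tail probability P(>= k tissues)
    tail: float
    #: expected shared-gene count under tissue independence
    lam: float
    fold: float
    #: Poisson upper-tail probability P(X >= observed) at lambda
    p: float


def assign_models(de_ah: dict[str, pd.DataFrame],
                  de_ta: dict[str, pd.DataFrame]) -> TriadAssignment:
    """Concatenate per-tissue A:H and T:A statuses into model labels.

    Both inputs map tissue -> DE table (with a ``status`` column on a shared
    gene index).  Gene universes must agree within each tissue.
    """
    if set(de_ah) != set(de_ta):
        raise ValueError(f"tissue sets differ: {sorted(de_ah)} vs {sorted(de_ta)}")
    out = {}
    for t in de_ah:
        a, b = de_ah[t], de_ta[t]
        if set(a.index) != set(b.index):
            missing = sorted(set(a.index) ^ set(b.index))
            raise ValueError(f"gene universes differ in tissue {t!r}; e.g. {missing[:5]}")
        b = b.reindex(a.index)
        out[t] = a["status"].str.cat(b["status"])
    return pd.DataFrame(out)


def model_enrichment(assignment: TriadAssignment, tissue: str) -> pd.DataFrame:
    """Observed vs expected gene counts per model within one tissue.

    Under independence of the two contrasts, ``expected(XY) = G * p(X in A:H)
    * p(Y in T:A)`` from the marginal status rates; the p-value is the Poisson
    upper tail at the expected count.
    """
    labels = assignment[tissue].dropna()
    G = len(labels)
    ah = labels.str[0]
    ta = labels.str[1]
    p_ah = ah.value_counts(normalize=True)
    p_ta = ta.value_counts(normalize=True)
    rows = []
    for m in MODELS:
        obs = int((labels == m).sum())
        exp = G * float(p_ah.get(m[0], 0.0)) * float(p_ta.get(m[1], 0.0))
        if exp > 0:
            fold = obs / exp
            p = float(poisson.sf(obs - 1, exp))
            flagged = False
        else:
            fold = np.inf if obs > 0 else 0.0
            p = 0.0 if obs > 0 else 1.0
            flagged = True
        rows.append({"model": m, "observed": obs, "expected": exp,
                     "fold": fold, "p": p, "degenerate": flagged})
    return pd.DataFrame(rows).set_index("model")


def poisson_binomial_tail(q, k: int) -> float:
    """P(>= k successes) of independent Bernoulli(q_t) trials, by exact DP."""
    q = np.asarray(q, dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("success probabilities must lie in [0, 1]")
    T = q.size
    if not 1 <= k <= T:
        raise ValueError(f"k={k} out of range [1, {T}]")
    # pmf[j] = P(j successes among trials seen so far)
    pmf = np.zeros(T + 1)
    pmf[0] = 1.0
    for t in range(T):
        pmf[1:t + 2] = pmf[1:t + 2] * (1 - q[t]) + pmf[0:t + 1] * q[t]
        pmf[0] *= (1 - q[t])
    return float(pmf[k:].sum())


def sharing_null(q, G: int, k: int, observed: int) -> SharingResult:
    """Sharing statistics for ``observed`` genes with a model in >= k tissues.

    ``q`` holds the per-tissue marginal probability of the model.  The
    expected count is ``G`` times the Poisson-Binomial tail; significance is
    the Poisson upper tail at that expectation.
    """
    if observed > G:
        raise ValueError(f"observed={observed} exceeds the gene universe G={G}")
    tail = poisson_binomial_tail(q, k)
    lam = G * tail
    fold = observed / lam if lam > 0 else (np.inf if observed > 0 else 0.0)
    p = float(poisson.sf(observed - 1, lam)) if lam > 0 else (0.0 if observed > 0 else 1.0)
    return SharingResult(k=k, observed=int(observed), tail=tail, lam=lam,
                         fold=fold, p=p)


def model_sharing(assignment: TriadAssignment, model: str, k: int) -> SharingResult:
    """Sharing of a full two-letter model across tissues vs the independence null.

    Marginal rates are the per-tissue model frequencies on the common tested
    universe (genes assigned in every tissue).
    """
    common = assignment.dropna()
    G = len(common)
    q = [(common[t] == model).mean() for t in common.columns]
    observed = int(((common == model).sum(axis=1) >= k).sum())
    return sharing_null(q, G, k, observed)


def status_sharing(de_by_tissue: dict[str, pd.DataFrame], status: str, k: int) -> SharingResult:
    """Sharing of a one-contrast status (U or D) across tissues."""
    tissues = sorted(de_by_tissue)
    stat = pd.DataFrame({t: de_by_tissue[t]["status"] for t in tissues}).dropna()
    G = len(stat)
    q = [(stat[t] == status).mean() for t in tissues]
    observed = int(((stat == status).sum(axis=1) >= k).sum())
    return sharing_null(q, G, k, observed)


def shared_genes(assignment: TriadAssignment, model: str, min_tissues: int) -> list[str]:
    """Genes assigned ``model`` in at least ``min_tissues`` tissues."""
    if min_tissues < 1:
        raise ValueError("min_tissues must be >= 1")
    hits = (assignment == model).sum(axis=1)
    return list(assignment.index[hits >= min_tissues])


def directional_consistency(de_by_tissue: dict[str, pd.DataFrame], genes) -> float:
    """Fraction of genes whose log2fc sign agrees across all tissues.

    Significance is not required — only the direction of change.  Genes
    missing from any tissue are excluded.  Returns NaN for an empty set.
    """
    tissues = sorted(de_by_tissue)
    genes = list(genes)
    if not genes:
        import warnings
        warnings.warn("directional_consistency called with an empty gene set")
        return float("nan")
    lfc = pd.DataFrame({t: de_by_tissue[t]["log2fc"] for t in tissues}).reindex(genes)
    ok = lfc.notna().all(axis=1)
    dropped = [g for g, keep in zip(genes, ok) if not keep]
    if dropped:
        import logging
        logging.getLogger(__name__).warning(
            "directional_consistency: %d genes missing in some tissue, excluded", len(dropped))
    lfc = lfc[ok]
    if lfc.empty:
        return float("nan")
    sign = np.sign(lfc.to_numpy())
    agree = np.all(sign > 0, axis=1) | np.all(sign < 0, axis=1)
    return float(agree.mean())
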