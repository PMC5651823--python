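"""Gene-set scoring and enrichment statistics.

Implements single-sample gene-set enrichment (the TASA-score statistic),
preranked gene-set enrichment with permutation NES/FDR, signature
co-expression, rank-based group comparison of scores, and the empirical
regulator ranking that correlates tumor-side gene expression with the matched
NAT-side signature score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


def _descending_order(values: np.ndarray) -> np.ndarray:
    """Indices ordering ``values`` descending, ties broken by position (stable)."""
    return np.lexsort((np.arange(values.size), -values))


def ssgsea_score(m: ExpressionMatrix, gene_set, alpha: float = 0.25) -> pd.Series:
    """Single-sample enrichment score of ``gene_set`` for every sample.

    Per sample, genes are ranked by descending abundance (ties broken by
    gene order).  With N genes and position i = 1..N, in-set genes carry
    weight ``(N - i + 1) ** alpha``; the score is the integrated difference
    ``sum_i (P_in(i) - P_out(i))`` between the weight-normalized cumulative
    in-set distribution and the uniform cumulative over out-of-set genes.
    Rank-based, hence invariant to any strictly monotone per-sample transform.
    """
    genes = list(m.genes)
    in_set = np.array([g in set(gene_set) for g in genes])
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no overlap with the matrix genes")
    N = len(genes)
    if n_in == N:
        raise ValueError("gene set covers every gene; out-of-set distribution undefined")
    vals = m.values.to_numpy(float)
    rank_weight = (N - np.arange(N)).astype(float) ** alpha  # weight at position i
    scores = np.empty(m.n_samples)
    for j in range(m.n_samples):
        order = _descending_order(vals[:, j])
        hit = in_set[order]
        w = np.where(hit, rank_weight, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~hit) / (N - n_in)
        scores[j] = float((p_in - p_out).sum())
    return pd.Series(scores, index=m.sample_ids, name="score")


def _es_batch(score_sorted: np.ndarray, hit_matrix: np.ndarray, p: float = 1.0) -> np.ndarray:
    """Enrichment scores for B candidate sets given one sorted ranking.

    ``score_sorted``: ranking metric in descending order (length N);
    ``hit_matrix``: (B, N) boolean membership in ranked order.  ES is the
    running-sum value of maximum absolute deviation, with hit increments
    ``|s|^p / sum_set |s|^p`` and miss decrements ``1 / (N - n_set)``.
    """
    B, N = hit_matrix.shape
    n_set = hit_matrix.sum(axis=1)
    w = np.abs(score_sorted) ** p
    hit_w = hit_matrix * w[None, :]
    denom = hit_w.sum(axis=1)
    # degenerate: all |scores| in the set are 0 -> uniform hit increments
    zero = denom == 0
    if zero.any():
        hit_w[zero] = hit_matrix[zero].astype(float)
        denom[zero] = n_set[zero]
    delta = hit_w / denom[:, None] - (~hit_matrix) / (N - n_set)[:, None].astype(float)
    run = np.cumsum(delta, axis=1)
    idx = np.abs(run).argmax(axis=1)
    return run[np.arange(B), idx]


def preranked_gsea(ranking: pd.Series, sets: dict[str, list[str]],
                   n_perm: int = 1000, seed: int = 0,
                   weight_p: float = 1.0) -> pd.DataFrame:
    """Preranked enrichment with a random-gene-set (gene-tag) null.

    Genes are ordered by descending ranking metric (e.g. log2 fold change).
    Each set's null is ``n_perm`` random gene sets of equal size; nominal p is
    the same-sign permutation fraction with +1 correction, NES divides ES by
    the mean same-sign null |ES|, and FDR follows the standard positive /
    negative NES pooling procedure.
    """
    if ranking.isna().any():
        raise ValueError("ranking contains missing values")
    genes = list(ranking.index)
    N = len(genes)
    order = _descending_order(ranking.to_numpy(float))
    s_sorted = ranking.to_numpy(float)[order]
    pos_of = np.empty(N, dtype=int)
    pos_of[order] = np.arange(N)
    gene_pos = {g: pos_of[i] for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    rows = {}
    null_by_size: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        present = [g for g in members if g in gene_pos]
        if not present:
            raise ValueError(f"gene set {name!r} has no overlap with the ranking")
        if len(present) >= N:
            raise ValueError(f"gene set {name!r} covers the whole ranking")
        n = len(present)
        hit = np.zeros((1, N), dtype=bool)
        hit[0, [gene_pos[g] for g in present]] = True
        es = float(_es_batch(s_sorted, hit, weight_p)[0])
        if n not in null_by_size:
            hits = np.zeros((n_perm, N), dtype=bool)
            for b in range(n_perm):
                hits[b, rng.choice(N, size=n, replace=False)] = True
            null_by_size[n] = _es_batch(s_sorted, hits, weight_p)
        null = null_by_size[n]
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        extreme = int((np.abs(null[same]) >= abs(es)).sum())
        p_nom = (1 + extreme) / (1 + n_same)
        mean_same = float(np.abs(null[same]).mean()) if n_same else float("nan")
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else float("nan")
        # normalized null for the FDR pool
        pos_mean = float(np.abs(null[null >= 0]).mean()) if (null >= 0).any() else np.nan
        neg_mean = float(np.abs(null[null < 0]).mean()) if (null < 0).any() else np.nan
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        rows[name] = {"es": es, "nes": nes, "p_nominal": p_nom, "n_genes": n,
                      "_null_nes": null_nes}

    all_null = np.concatenate([r["_null_nes"] for r in rows.values()])
    all_null = all_null[np.isfinite(all_null)]
    obs = np.array([r["nes"] for r in rows.values()])
    fdrs = {}
    for name, r in rows.items():
        nes = r["nes"]
        if not np.isfinite(nes):
            fdrs[name] = float("nan")
            continue
        if nes >= 0:
            null_frac = (all_null >= nes).sum() / max((all_null >= 0).sum(), 1)
            obs_frac = (obs >= nes).sum() / max((obs >= 0).sum(), 1)
        else:
            null_frac = (all_null <= nes).sum() / max((all_null < 0).sum(), 1)
            obs_frac = (obs <= nes).sum() / max((obs < 0).sum(), 1)
        fdrs[name] = float(min(1.0, null_frac / obs_frac)) if obs_frac > 0 else float("nan")
    out = pd.DataFrame({
        "es": {k: r["es"] for k, r in rows.items()},
        "nes": {k: r["nes"] for k, r in rows.items()},
        "p_nominal": {k: r["p_nominal"] for k, r in rows.items()},
        "fdr": fdrs,
        "n_genes": {k: r["n_genes"] for k, r in rows.items()},
    })
    out.attrs["n_perm"] = n_perm
    out.attrs["seed"] = seed
    return out


def coexpression(m: ExpressionMatrix, genes, tissue: str | None = None,
                 condition: str | None = None) -> pd.DataFrame:
    """Pairwise Spearman correlation of ``genes`` across the selected samples.

    Constant genes get NaN rows/columns (logged); the diagonal is 1 for
    non-constant genes.
    """
    sub = m.select(tissue=tissue, condition=condition)
    if sub.n_samples < 3:
        raise ValueError("need at least 3 samples for co-expression")
    genes = [g for g in genes if g in set(sub.genes)]
    X = sub.values.loc[genes].to_numpy(float)
    const = X.std(axis=1) == 0
    rho = np.full((len(genes), len(genes)), np.nan)
    keep = ~const
    if keep.sum() >= 2:
        r = spearmanr(X[keep].T).statistic
        r = np.atleast_2d(r)
        rho[np.ix_(keep, keep)] = r
    elif keep.sum() == 1:
        rho[np.flatnonzero(keep)[0], np.flatnonzero(keep)[0]] = 1.0
    for g in np.array(genes)[const]:
        log.warning("coexpression: gene %s constant across samples; reported as NaN", g)
    return pd.DataFrame(rho, index=genes, columns=genes)


def compare_scores(scores: pd.Series, groups, pair: tuple,
                   correction_factor: int = 1,
                   significance: float = 0.001) -> dict[str, float]:
    """Two-sided Mann-Whitney comparison of scores between two groups.

    ``pair = (g1, g2)`` selects the groups; Bonferroni multiplies the raw p
    by ``correction_factor``; the significance call uses corrected p below
    ``significance`` (default 0.001).
    """
    groups = np.asarray(groups)
    a = scores.to_numpy(float)[groups == pair[0]]
    b = scores.to_numpy(float)[groups == pair[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty group in comparison {pair}")
    method = "auto"
    if max(a.size, b.size) <= 25 and np.unique(np.concatenate([a, b])).size == a.size + b.size:
        method = "exact"  # no ties: exact null distribution is affordable
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    p_bonf = min(1.0, float(res.pvalue) * correction_factor)
    return {"u_statistic": float(res.statistic), "p_raw": float(res.pvalue),
            "p_bonf": p_bonf, "significant": bool(p_bonf < significance),
            "n1": int(a.size), "n2": int(b.size)}


def rank_regulators(tasa_scores: pd.Series, tumor_expr: ExpressionMatrix,
                    nat_meta: pd.DataFrame) -> pd.DataFrame:
    """Rank tumor-side genes by Spearman correlation with matched NAT scores.

    ``tasa_scores`` is indexed by NAT sample id; ``nat_meta`` maps those
    samples to subjects; tumor samples are matched on subject.  Constant
    tumor genes are excluded (logged).  Returns a descending table with a
    ``top_pct`` percentile column.
    """
    nat_subj = nat_meta.set_index("sample")["subject"]
    tum_subj = tumor_expr.samples.set_index("sample")["subject"]
    subj_to_tum = {s: smp for smp, s in tum_subj.items()}
    pairs = []
    for smp in tasa_scores.index:
        subj = nat_subj.get(smp)
        if subj in subj_to_tum:
            pairs.append((smp, subj_to_tum[subj]))
        else:
            log.warning("rank_regulators: NAT sample %s has no matched tumor sample; dropped", smp)
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} matched pairs; need at least 3")
    nat_ids, tum_ids = zip(*pairs)
    y = tasa_scores.loc[list(nat_ids)].to_numpy(float)
    X = tumor_expr.values.loc[:, list(tum_ids)].to_numpy(float)
    const = X.std(axis=1) == 0
    for g in tumor_expr.genes[const]:
        log.warning("rank_regulators: tumor gene %s constant across subjects; excluded", g)
    keep = ~const
    # vectorized Spearman: rank-transform then Pearson against the score ranks
    Xr = pd.DataFrame(X[keep]).rank(axis=1).to_numpy()
    yr = pd.Series(y).rank().to_numpy()
    Xc = Xr - Xr.mean(axis=1, keepdims=True)
    yc = yr - yr.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(yc)
    rho = (Xc @ yc) / np.where(denom == 0, np.nan, denom)
    out = pd.DataFrame({"gene": np.asarray(tumor_expr.genes)[keep], "spearman_rho": rho})
    out = out.dropna().sort_values("spearman_rho", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["top_pct"] = out["rank"] / len(out) * 100.0
    out.attrs["n_pairs"] = len(pairs)
    return out
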