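"""Validation scenarios: calibration and recovery measurements on synthetic data.

Each function runs one self-contained experiment — simulate data with known
truth, run the corresponding pipeline stage, and measure how well it performs.
The scenarios mirror the statistical claims the pipeline relies on: exactness
of the Poisson-Binomial sharing null, type-I error control of the NB GLM test,
recovery of planted differential effects and shared TASA genes, null
calibration of the model-enrichment fold, deconvolution accuracy,
unwanted-variation removal, scoring oracles, the NAT-specific score phenotype,
regulator ranking and tissue assignment.  All randomness flows from the
``seed`` argument.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import binom, kstest

from .comparability import assign_tissue, build_reference
from .deconvolution import deconvolve
from .diffexpr import test_de
from .enrichment import compare_scores, preranked_gsea, rank_regulators, ssgsea_score
from .matrix import ExpressionMatrix
from .pipeline import PipelineConfig, de_all_contrasts
from .preprocess import estimate_unwanted, filter_low_abundance, remove_unwanted, uq_cpm
from .synthetic import SimulationConfig, simulate_matched_pairs, simulate_triad
from .triad import assign_models, model_enrichment, poisson_binomial_tail, shared_genes


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds derived from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


# ---------------------------------------------------------------- sharing null

def sharing_oracle_errors(seed: int = 0, n_cases: int = 50) -> dict[str, float]:
    """Max deviation of the Poisson-Binomial DP from exhaustive enumeration.

    Random probability vectors of length T <= 6 are compared against the 2^T
    enumeration and, for equal probabilities, against the Binomial tail.
    """
    rng = np.random.default_rng(seed)
    worst_enum = 0.0
    worst_binom = 0.0
    for _ in range(n_cases):
        T = int(rng.integers(1, 7))
        q = rng.uniform(0, 1, T)
        k = int(rng.integers(1, T + 1))
        brute = sum(np.prod([q[t] if b[t] else 1 - q[t] for t in range(T)])
                    for b in product([0, 1], repeat=T) if sum(b) >= k)
        worst_enum = max(worst_enum, abs(poisson_binomial_tail(q, k) - brute))
        qe = float(rng.uniform(0, 1))
        worst_binom = max(worst_binom, abs(poisson_binomial_tail([qe] * T, k)
                                           - float(binom.sf(k - 1, T, qe))))
    return {"max_err_vs_enumeration": worst_enum, "max_err_vs_binomial": worst_binom}


# ---------------------------------------------------------------- type-I error

def _null_two_group(seed: int, n_genes: int = 2000, n: int = 20,
                    phi: float = 0.2) -> ExpressionMatrix:
    cfg = SimulationConfig(n_genes=n_genes, n_tissues=1,
                           samples_per_condition={"H": n, "A": n},
                           model_proportions={}, n_unwanted_factors=0,
                           libsize_by_source={"c1": (0.0, 0.1)},
                           dispersion=phi, seed=seed)
    em, _ = simulate_triad(cfg)
    return em

def type_i_error(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Empirical FPR at raw alpha=0.05 and family-wise error with Bonferroni.

    Null simulations with 2000 genes, 20 samples per group and dispersion 0.2.
    The FPR is measured on the first replicate; the FWER is the fraction of
    replicates with any Bonferroni-significant gene at 0.05.
    """
    seeds = _child_seeds(seed, n_seeds)
    fpr = None
    fwer_hits = 0
    for s in seeds:
        em = _null_two_group(s)
        de = test_de(em, em.samples["condition"].to_numpy(), contrast=("H", "A"))
        if fpr is None:
            fpr = float((de["p_raw"] < 0.05).mean())
        fwer_hits += int((de["p_bonf"] < 0.05).any())
    return {"fpr_raw_alpha05": fpr, "fwer_bonferroni": fwer_hits / n_seeds,
            "n_seeds": n_seeds}


# --------------------------------------------------- DEG / model / TASA recovery

def deg_model_recovery(seed: int = 0, n_seeds: int = 10,
                       n_genes: int = 1500) -> dict[str, float]:
    """Recovery of planted DEGs, UD assignments and shared TASA genes.

    Triads with |log2FC| = 2, 30 samples per condition, 4 tissues and 12
    planted shared TASA genes; DE runs use estimated dispersions and one
    unwanted-variation covariate, exactly as the pipeline does.
    """
    sign_rates, ud_rates, tasa_rec, tasa_spur = [], [], [], []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimulationConfig(n_genes=n_genes, n_tissues=4,
                               samples_per_condition={"H": 30, "A": 30, "T": 30},
                               n_shared_tasa=12, effect_log2fc=2.0, seed=s)
        em, truth = simulate_triad(cfg)
        filtered = filter_low_abundance(em)
        de = de_all_contrasts(filtered, truth.housekeeping, PipelineConfig())
        assignment = assign_models(de["AH"], de["TA"])
        correct = total = ud_correct = ud_total = 0
        for t in assignment.columns:
            for contrast in ("AH", "TA"):
                planted = truth.planted_status(t, contrast).reindex(de[contrast][t].index)
                deg = planted.isin(["U", "D"])
                total += int(deg.sum())
                correct += int((de[contrast][t].loc[deg, "status"] == planted[deg]).sum())
            truth_ud = truth.models[t].reindex(assignment.index) == "UD"
            ud_total += int(truth_ud.sum())
            ud_correct += int((assignment.loc[truth_ud, t] == "UD").sum())
        sign_rates.append(correct / total)
        ud_rates.append(ud_correct / ud_total)
        found = set(shared_genes(assignment, "UD", 3))
        planted_set = set(truth.tasa_shared)
        tasa_rec.append(len(found & planted_set) / len(planted_set))
        tasa_spur.append(len(found - planted_set) / max(len(found), 1))
    return {"deg_sign_recovery": float(np.mean(sign_rates)),
            "ud_model_recovery": float(np.mean(ud_rates)),
            "tasa_shared_recovery": float(np.mean(tasa_rec)),
            "tasa_spurious_fraction": float(np.mean(tasa_spur)),
            "n_seeds": n_seeds}


# ------------------------------------------------- model-enrichment calibration

def enrichment_null_fold(seed: int = 0, n_reps: int = 100,
                         n_genes: int = 2000) -> dict[str, float]:
    """Mean model-enrichment fold when statuses are independent draws."""
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_reps):
        ah = rng.choice(list("UDS"), p=[0.06, 0.08, 0.86], size=n_genes)
        ta = rng.choice(list("UDS"), p=[0.10, 0.05, 0.85], size=n_genes)
        lab = pd.Series([a + b for a, b in zip(ah, ta)],
                        index=[f"g{i}" for i in range(n_genes)])
        enr = model_enrichment(pd.DataFrame({"t": lab}), "t")
        folds.append(enr["fold"].to_numpy())
    return {"mean_fold": float(np.nanmean(folds)), "n_reps": n_reps}


# ------------------------------------------------------------- deconvolution

def deconvolution_accuracy(seed: int = 0, n_genes: int = 2000) -> dict[str, float]:
    """Exact recovery on noise-free mixtures; MAE on NB-resampled mixtures."""
    rng = np.random.default_rng(seed)
    h = rng.uniform(5, 500, n_genes)
    t = rng.uniform(5, 500, n_genes)
    sig = pd.DataFrame({"healthy": h, "tumor": t},
                       index=[f"g{i}" for i in range(n_genes)])
    fracs = np.arange(0.1, 0.95, 0.1)
    exact_err, noisy_err = [], []
    phi = 0.2
    r = 1 / phi
    for f in fracs:
        mu = (1 - f) * h + f * t
        exact_err.append(abs(deconvolve(mu, sig)["fraction_tumor"] - f))
        x = rng.negative_binomial(r, r / (r + mu)).astype(float)
        noisy_err.append(abs(deconvolve(x, sig)["fraction_tumor"] - f))
    return {"max_exact_error": float(np.max(exact_err)),
            "noisy_mae": float(np.mean(noisy_err))}


# ------------------------------------------------- unwanted-variation removal

def unwanted_variation_checks(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Noise-free factor recovery and confounded-design false-positive control.

    The confounded design shifts the latent factor scores with condition
    (shift 2.0) while all genes stay null; false positives are genes at raw
    p < 0.05.  Reports the fraction of replicates where entering the estimated
    factor as a covariate strictly reduces that count.
    """
    rng = np.random.default_rng(seed)
    n, g = 40, 80
    score = rng.normal(size=n)
    vals = 8.0 + np.outer(rng.normal(size=g), score)
    meta = pd.DataFrame({"sample": [f"s{j}" for j in range(n)], "tissue": "t1",
                         "condition": "H", "source": "c1",
                         "subject": [f"s{j}" for j in range(n)]})
    m = ExpressionMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(g)],
                                      columns=meta["sample"]), meta, scale="log2cpm")
    w = estimate_unwanted(m, list(m.genes), 1)
    noise_free_r = abs(float(np.corrcoef(w.factors.to_numpy()[:, 0], score)[0, 1]))

    wins = 0
    for s in _child_seeds(seed, n_seeds):
        cfg = SimulationConfig(n_genes=1000, n_tissues=1,
                               samples_per_condition={"H": 20, "A": 20},
                               model_proportions={}, n_unwanted_factors=1,
                               factor_sd=0.5, factor_condition_shift=2.0,
                               libsize_by_source={"c1": (0.0, 0.1)},
                               dispersion=0.2, seed=s)
        em, truth = simulate_triad(cfg)
        labels = em.samples["condition"].to_numpy()
        lc = uq_cpm(em, log2=True)
        west = estimate_unwanted(lc, truth.housekeeping, 1)
        fp_raw = int((test_de(em, labels, contrast=("H", "A"))["p_raw"] < 0.05).sum())
        fp_cor = int((test_de(em, labels, contrast=("H", "A"), w=west)["p_raw"] < 0.05).sum())
        wins += int(fp_cor < fp_raw)
    return {"noise_free_factor_correlation": noise_free_r,
            "confounded_correction_wins": wins, "n_seeds": n_seeds}


# -------------------------------------------------------------- scoring oracles

def scoring_oracles(seed: int = 0, n_reps: int = 50) -> dict[str, float]:
    """Hand-value oracles for ssGSEA and preranked ES, plus null p calibration."""
    # 4 genes, the set is the single top-ranked gene, alpha=0: score is
    # (1-0) + (1-1/3) + (1-2/3) + (1-1) = 2
    meta = pd.DataFrame({"sample": ["s0"], "tissue": ["t1"], "condition": ["H"],
                         "source": ["c1"], "subject": ["s0"]})
    m = ExpressionMatrix(pd.DataFrame({"s0": [10.0, 7.0, 5.0, 1.0]},
                                      index=list("abcd")), meta, scale="abundance")
    ss_err = abs(float(ssgsea_score(m, ["a"], alpha=0.0).iloc[0]) - 2.0)

    rk = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
    es = float(preranked_gsea(rk, {"top": ["a"]}, n_perm=20, seed=seed).loc["top", "es"])
    es_err = abs(es - 1.0)

    rng = np.random.default_rng(seed)
    hits = total = 0
    for rep in range(n_reps):
        ranking = pd.Series(rng.normal(size=150), index=[f"g{i}" for i in range(150)])
        sets = {f"s{j}": list(rng.choice(ranking.index, size=12, replace=False))
                for j in range(4)}
        res = preranked_gsea(ranking, sets, n_perm=99, seed=int(rng.integers(2 ** 31)))
        hits += int((res["p_nominal"] < 0.05).sum())
        total += len(sets)
    return {"ssgsea_hand_value_error": ss_err, "prerank_es_hand_value_error": es_err,
            "prerank_null_p05_fraction": hits / total, "n_reps": n_reps}


# --------------------------------------------------------- TASA score phenotype

def tasa_phenotype(seed: int = 0, n_seeds: int = 10) -> dict[str, float]:
    """How often the discovered TASA score is NAT-specific across tissues.

    Per replicate: discover the shared TASA set through the full DE + model
    route, ssGSEA-score all samples on factor-removed log2 CPM, and call the
    replicate a success if the NAT-vs-healthy and NAT-vs-tumor Mann-Whitney
    comparisons are Bonferroni-significant (p < 0.001) in at least 3 of the 4
    tissues — the desk-scale analogue of NAT-specific enrichment in most
    tissue types.
    """
    successes = 0
    for s in _child_seeds(seed, n_seeds):
        cfg = SimulationConfig(n_genes=1000, n_tissues=4,
                               samples_per_condition={"H": 25, "A": 25, "T": 25},
                               n_shared_tasa=15, effect_log2fc=2.0, seed=s)
        em, truth = simulate_triad(cfg)
        filtered = filter_low_abundance(em)
        de = de_all_contrasts(filtered, truth.housekeeping, PipelineConfig())
        assignment = assign_models(de["AH"], de["TA"])
        tasa = shared_genes(assignment, "UD", 3)
        if not tasa:
            continue
        lc = uq_cpm(filtered, log2=True)
        w = estimate_unwanted(lc, truth.housekeeping, 1)
        scored = remove_unwanted(lc, w)
        scores = ssgsea_score(scored, tasa)
        n_comp = 2 * 4
        ok_tissues = 0
        for t in assignment.columns:
            mask = (scored.samples["tissue"] == t).to_numpy()
            grp = scored.samples["condition"].to_numpy()[mask]
            sc = scores[mask]
            vs_h = compare_scores(sc, grp, ("H", "A"), correction_factor=n_comp)
            vs_t = compare_scores(sc, grp, ("T", "A"), correction_factor=n_comp)
            up_in_nat = (np.median(sc[grp == "A"]) > np.median(sc[grp == "H"])
                         and np.median(sc[grp == "A"]) > np.median(sc[grp == "T"]))
            ok_tissues += int(vs_h["significant"] and vs_t["significant"] and up_in_nat)
        successes += int(ok_tissues >= 3)
    return {"nat_specific_success_rate": successes / n_seeds, "n_seeds": n_seeds}


# ----------------------------------------------------------- regulator ranking

def _regulator_rank_pct(s: int, driver_effect: float) -> float:
    cfg = SimulationConfig(n_genes=800, n_tissues=1,
                           samples_per_condition={"H": 4, "A": 200, "T": 200},
                           model_proportions={"UD": 0.03}, min_shared_tissues=2,
                           effect_log2fc=2.0, driver_effect=driver_effect, seed=s)
    em, truth = simulate_matched_pairs(cfg)
    lc = uq_cpm(filter_low_abundance(em), log2=True)
    nat = lc.subset_samples(lc.condition_mask("A"))
    tum = lc.subset_samples(lc.condition_mask("T"))
    tasa = list(truth.models.index[truth.models["tissue1"] == "UD"])
    scores = ssgsea_score(nat, tasa)
    table = rank_regulators(scores, tum, nat.samples)
    row = table[table["gene"] == truth.driver_gene]
    return float(row["top_pct"].iloc[0]) if len(row) else 100.0

def regulator_ranking(seed: int = 0, n_seeds: int = 20,
                      n_null_seeds: int = 50) -> dict[str, float]:
    """Planted-driver recovery and null uniformity of the regulator ranking.

    With driver_effect = 1.0 over 200 matched subjects, counts how often the
    driver lands in the ranking's top 1%.  With driver_effect = 0 the driver's
    percentile should be uniform; reports the KS p-value over replicates.
    """
    top1 = sum(_regulator_rank_pct(s, 1.0) <= 1.0
               for s in _child_seeds(seed, n_seeds))
    null_pcts = [_regulator_rank_pct(s, 0.0)
                 for s in _child_seeds(seed + 1, n_null_seeds)]
    ks_p = float(kstest(np.array(null_pcts) / 100.0, "uniform").pvalue)
    return {"driver_top1pct_hits": top1, "n_seeds": n_seeds,
            "null_rank_ks_pvalue": ks_p, "n_null_seeds": n_null_seeds}


# ------------------------------------------------------------ tissue assignment

def tissue_assignment_accuracy(seed: int = 0, n_seeds: int = 10) -> dict[str, float]:
    """NAT tissue-assignment accuracy with well-separated tissue baselines."""
    accs = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimulationConfig(n_genes=800, n_tissues=4,
                               samples_per_condition={"H": 15, "A": 15, "T": 15},
                               seed=s)
        em, _ = simulate_triad(cfg)
        cpm = uq_cpm(filter_low_abundance(em))
        panel = build_reference(cpm)
        nat = cpm.subset_samples(cpm.condition_mask("A"))
        accs.append(float(assign_tissue(panel, nat)["correct"].mean()))
    return {"nat_assignment_accuracy": float(np.mean(accs)), "n_seeds": n_seeds}
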