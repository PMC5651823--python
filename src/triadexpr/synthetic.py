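"""Multi-tissue healthy / tumor-adjacent / tumor count simulator with known truth.

The generator emulates the statistical structure of a two-cohort triad study:
negative-binomial counts over per-tissue baselines, two source cohorts with
strongly different library sizes, latent unwanted-variation factors loading on
every gene, housekeeping genes free of condition effects, per-tissue planted
differential effects distributed over the nine expression models, a set of
tumor-adjacent-specific activation (TASA) genes shared across tissues, NAT
profiles that are convex mixtures of healthy and tumor means plus NAT-specific
components, and (optionally) subject-matched tumor/NAT pairs in which a
tumor-expressed driver gene modulates the NAT-side TASA effect.

Model labels are two letters: the first is the NAT-vs-healthy (A:H) status,
the second the tumor-vs-NAT (T:A) status, each in {U, D, S}.  ``SS`` is the
null model; ``UD`` is TASA (up in NAT vs both neighbours) and ``DU`` is TASR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

MODELS = ("SS", "SU", "SD", "US", "DS", "UU", "DD", "UD", "DU")
_STATUS_SHIFT = {"U": 1.0, "D": -1.0, "S": 0.0}


@dataclass
class SimulationConfig:
    """Parameters of the triad simulation.

    Defaults are desk-scale: 2000 genes, 4 tissues, 30 samples per condition,
    ~12% of genes carrying an effect in at least one contrast, a three-fold
    library-size gap between the two source cohorts and one latent factor.
    """

    n_genes: int = 2000
    n_tissues: int = 4
    samples_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"H": 30, "A": 30, "T": 30})
    #: log2 range of per-(gene,tissue) baseline mean counts
    baseline_log_mean_range: tuple[float, float] = (3.0, 9.0)
    #: NB dispersion phi (variance = mu + phi mu^2); scalar or (lo, hi) range
    dispersion: float | tuple[float, float] = 0.2
    #: source -> (meanlog, sdlog) of the log-normal library-size factor
    libsize_by_source: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"cohort1": (0.0, 0.1), "cohort2": (1.1, 0.1)})
    n_unwanted_factors: int = 1
    #: SD of per-gene factor loadings (log2 scale); scores are standard normal
    factor_sd: float = 0.5
    #: shift added to factor scores of T samples (and half of it for A) to
    #: emulate a design in which unwanted variation is confounded with
    #: condition; 0 keeps factors independent of condition
    factor_condition_shift: float = 0.0
    n_housekeeping: int = 50
    #: model -> fraction of genes (per tissue); remainder is the SS null model
    model_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"UD": 0.01, "DU": 0.01, "UU": 0.02, "DD": 0.02,
                                 "US": 0.02, "DS": 0.02, "SU": 0.02, "SD": 0.02})
    #: planted |log2 fold change|; scalar or (lo, hi) range
    effect_log2fc: float | tuple[float, float] = (1.0, 3.0)
    n_shared_tasa: int = 0
    min_shared_tissues: int = 3
    #: NAT mixing fraction (tumor weight) range for genes without planted
    #: NAT-specific effects
    mix_fraction_range: tuple[float, float] = (0.05, 0.25)
    #: log2-per-unit modulation of NAT TASA effects by the subject's tumor
    #: driver expression (matched-pair simulation only)
    driver_effect: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_tissues <= 0:
            raise ValueError("n_genes and n_tissues must be positive")
        for cond, n in self.samples_per_condition.items():
            if cond not in ("H", "A", "T"):
                raise ValueError(f"unknown condition {cond!r} in samples_per_condition")
            if n <= 0:
                raise ValueError(f"samples_per_condition[{cond!r}] must be positive")
        bad = set(self.model_proportions) - set(MODELS)
        if bad:
            raise ValueError(f"model_proportions contains unknown models: {sorted(bad)}")
        total = float(sum(self.model_proportions.values()))
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"model_proportions sums to {total:.4f} > 1 (the remainder must be the SS null model)")
        if any(v < 0 for v in self.model_proportions.values()):
            raise ValueError("model_proportions must be non-negative")
        if self.n_shared_tasa > 0 and not (2 <= self.min_shared_tissues <= self.n_tissues):
            raise ValueError("min_shared_tissues must lie in [2, n_tissues] when n_shared_tasa > 0")
        if self.n_housekeeping + self.n_shared_tasa + 1 > self.n_genes:
            raise ValueError("n_genes too small for housekeeping + shared TASA genes")
        lo, hi = self.mix_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("mix_fraction_range must be a sub-interval of [0, 1]")
        if self.driver_effect < 0:
            raise ValueError("driver_effect must be non-negative")
        if not self.libsize_by_source:
            raise ValueError("libsize_by_source must name at least one source")
        if self.n_unwanted_factors < 0:
            raise ValueError("n_unwanted_factors must be non-negative")


@dataclass
class SyntheticTruth:
    """Complete record of planted parameters for recovery testing."""

    #: gene x tissue frame of model labels
    models: pd.DataFrame
    tasa_shared: list[str]
    #: NAT sample -> tumor-mixture weight
    mixing_fraction: dict[str, float]
    factor_scores: pd.DataFrame
    factor_loadings: pd.DataFrame
    housekeeping: list[str]
    driver_gene: str | None = None
    #: NAT sample -> standardized tumor driver level of the matched subject
    driver_effects: dict[str, float] = field(default_factory=dict)

    def deg_membership(self, tissue: str) -> pd.Series:
        return self.models[tissue]

    def planted_status(self, tissue: str, contrast: str) -> pd.Series:
        """Planted U/D/S status for one contrast ('AH' or 'TA') in a tissue."""
        pos = {"AH": 0, "TA": 1}[contrast]
        return self.models[tissue].str[pos]


def _draw(rng: np.random.Generator, value, size):
    """Scalar -> constant array; (lo, hi) -> uniform draw."""
    if np.isscalar(value):
        return np.full(size, float(value))
    lo, hi = value
    return rng.uniform(lo, hi, size=size)


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB counts with variance mu + phi mu^2 (Poisson where phi == 0)."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[:, None], mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def _assign_models(rng: np.random.Generator, cfg: SimulationConfig,
                   genes: list[str], tissues: list[str],
                   housekeeping: set[str], tasa_shared: list[str]) -> pd.DataFrame:
    """Per-tissue model labels honouring housekeeping and shared-TASA plants."""
    models = pd.DataFrame("SS", index=pd.Index(genes, name="gene"), columns=tissues)
    # shared TASA genes: UD in a random >= min_shared_tissues subset, SS elsewhere
    for g in tasa_shared:
        n_in = int(rng.integers(cfg.min_shared_tissues, cfg.n_tissues + 1))
        chosen = rng.choice(cfg.n_tissues, size=n_in, replace=False)
        for ti in chosen:
            models.loc[g, tissues[ti]] = "UD"
    reserved = housekeeping | set(tasa_shared)
    free = [g for g in genes if g not in reserved]
    props = [(m, float(p)) for m, p in cfg.model_proportions.items() if m != "SS" and p > 0]
    for t in tissues:
        pool = np.array(free)
        rng.shuffle(pool)
        start = 0
        for m, p in props:
            n = int(round(p * cfg.n_genes))
            n = min(n, len(pool) - start)
            models.loc[pool[start:start + n], t] = m
            start += n
    return models


def _simulate(cfg: SimulationConfig, matched: bool) -> tuple[ExpressionMatrix, SyntheticTruth]:
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    ss_global, ss_counts = root.spawn(2)
    rng = np.random.default_rng(ss_global)

    width = len(str(cfg.n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    tissues = [f"tissue{t + 1}" for t in range(cfg.n_tissues)]

    perm = rng.permutation(cfg.n_genes)
    housekeeping = [genes[i] for i in perm[:cfg.n_housekeeping]]
    tasa_shared = [genes[i] for i in perm[cfg.n_housekeeping:
                                          cfg.n_housekeeping + cfg.n_shared_tasa]]
    driver_gene = genes[perm[cfg.n_housekeeping + cfg.n_shared_tasa]] if matched else None

    models = _assign_models(rng, cfg, genes, tissues, set(housekeeping), tasa_shared)
    if driver_gene is not None:
        models.loc[driver_gene, :] = "SS"  # driver carries no planted contrast effect

    phi = _draw(rng, cfg.dispersion, cfg.n_genes)
    effect = np.abs(_draw(rng, cfg.effect_log2fc, (cfg.n_genes, cfg.n_tissues)))

    # sources: healthy from the first cohort, NAT/tumor from the second when
    # two cohorts are configured (the cross-cohort design); otherwise all
    # samples share the single source
    sources = list(cfg.libsize_by_source)
    src_of = {"H": sources[0], "A": sources[-1], "T": sources[-1]}

    sample_rows = []
    for t in tissues:
        for cond in ("H", "A", "T"):
            n = cfg.samples_per_condition.get(cond, 0)
            for i in range(n):
                if matched and cond in ("A", "T"):
                    subject = f"{t}_subj{i + 1:03d}"
                else:
                    subject = f"{t}_{cond}{i + 1:03d}"
                sample_rows.append({"sample": f"{t}_{cond}{i + 1:03d}", "tissue": t,
                                    "condition": cond, "source": src_of[cond],
                                    "subject": subject})
    meta = pd.DataFrame(sample_rows)
    n_samples = len(meta)

    meanlog = meta["source"].map(lambda s: cfg.libsize_by_source[s][0]).to_numpy(float)
    sdlog = meta["source"].map(lambda s: cfg.libsize_by_source[s][1]).to_numpy(float)
    libsize = np.exp(rng.normal(meanlog, sdlog))

    k = cfg.n_unwanted_factors
    scores = rng.normal(size=(n_samples, k))
    if cfg.factor_condition_shift != 0.0 and k > 0:
        shift = meta["condition"].map({"H": 0.0, "A": 0.5, "T": 1.0}).to_numpy()
        scores = scores + cfg.factor_condition_shift * shift[:, None]
    loadings = rng.normal(scale=cfg.factor_sd, size=(cfg.n_genes, k))

    mixing: dict[str, float] = {}
    driver_effects: dict[str, float] = {}
    # standardized per-subject driver level (matched design only)
    subj_driver: dict[str, float] = {}
    if matched:
        for t in tissues:
            for i in range(cfg.samples_per_condition.get("T", 0)):
                subj_driver[f"{t}_subj{i + 1:03d}"] = float(rng.normal())

    values = np.zeros((cfg.n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    counts_streams = dict(zip(tissues, ss_counts.spawn(cfg.n_tissues)))

    for ti, t in enumerate(tissues):
        trng = np.random.default_rng(counts_streams[t])
        baseline = trng.uniform(*cfg.baseline_log_mean_range, size=cfg.n_genes)
        mlab = models[t].to_numpy()
        d_ah = np.array([_STATUS_SHIFT[m[0]] for m in mlab]) * effect[:, ti]
        d_ta = np.array([_STATUS_SHIFT[m[1]] for m in mlab]) * effect[:, ti]
        mu_h = 2.0 ** baseline
        mu_a0 = 2.0 ** (baseline + d_ah)
        mu_t = 2.0 ** (baseline + d_ah + d_ta)
        # genes eligible for NAT mixing: no planted NAT-side effect of their
        # own (first letter S and not a NAT-specific UD/DU model)
        mixable = np.array([m[0] == "S" for m in mlab])

        tmask = (meta["tissue"] == t).to_numpy()
        for j in np.flatnonzero(tmask):
            cond = meta.at[j, "condition"]
            sample_id = meta.at[j, "sample"]
            if cond == "H":
                mu0 = mu_h
            elif cond == "T":
                mu0 = mu_t.copy()
                if driver_gene is not None:
                    u = subj_driver[meta.at[j, "subject"]]
                    mu0[gene_pos[driver_gene]] = 2.0 ** (baseline[gene_pos[driver_gene]] + u)
            else:  # NAT
                m_frac = float(trng.uniform(*cfg.mix_fraction_range))
                mixing[sample_id] = m_frac
                mu0 = mu_a0.copy()
                mu0[mixable] = m_frac * mu_t[mixable] + (1.0 - m_frac) * mu_h[mixable]
                if matched and cfg.driver_effect >= 0 and driver_gene is not None:
                    u = subj_driver[meta.at[j, "subject"]]
                    driver_effects[sample_id] = u
                    tasa = np.array([m == "UD" for m in mlab])
                    if tasa.any():
                        mod = cfg.driver_effect * u
                        mu0[tasa] = 2.0 ** (baseline[tasa] + d_ah[tasa] + mod)
            log2_extra = scores[j] @ loadings.T + np.log2(libsize[j])
            mu = mu0 * 2.0 ** log2_extra
            values[:, j] = _sample_counts(trng, mu[:, None], phi)[:, 0]

    em = ExpressionMatrix(values=pd.DataFrame(values.astype(np.int64), index=genes,
                                              columns=meta["sample"].tolist()),
                          samples=meta, scale="counts")
    truth = SyntheticTruth(
        models=models, tasa_shared=tasa_shared, mixing_fraction=mixing,
        factor_scores=pd.DataFrame(scores, index=meta["sample"].tolist(),
                                   columns=[f"W{i + 1}" for i in range(k)]),
        factor_loadings=pd.DataFrame(loadings, index=genes,
                                     columns=[f"W{i + 1}" for i in range(k)]),
        housekeeping=housekeeping, driver_gene=driver_gene,
        driver_effects=driver_effects)
    return em, truth


def simulate_triad(cfg: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate an unmatched three-condition, multi-tissue count dataset.

    Counts are NB(mu, phi) with
    ``log2 mu = baseline(tissue, gene) + condition effect + factor term +
    log2 library size``; NAT means of genes without NAT-specific effects are
    convex mixtures of the healthy and tumor means.  The same seed always
    yields bitwise-identical output.
    """
    return _simulate(cfg, matched=False)


def simulate_matched_pairs(cfg: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate subject-matched tumor/NAT samples with a tumor-side driver.

    Each subject contributes one tumor and one NAT sample.  The driver gene's
    tumor log2 level varies across subjects (standard-normal deviations) and
    linearly modulates that subject's NAT-side TASA effect sizes with strength
    ``driver_effect`` (log2 per unit).
    """
    if cfg.samples_per_condition.get("A", 0) != cfg.samples_per_condition.get("T", 0):
        raise ValueError("matched-pair simulation needs equal A and T sample counts")
    return _simulate(cfg, matched=True)
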