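"""End-to-end orchestration of the triad analysis.

Stages (per tissue unless noted): low-abundance filtering, upper-quartile CPM,
control-gene factor estimation per condition pair, NB GLM differential
expression for the A:H, T:A and T:H contrasts, nine-model assignment, model
enrichment, cross-tissue sharing statistics, TASA gene-set extraction, TASA
ssGSEA scoring with Mann-Whitney group comparisons, two-reference
deconvolution and the tumor-control comparison.  Every stage writes its
artifact to the output directory and the manifest records parameters and
seeds so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparability import assign_tissue, build_reference, housekeeping_concordance
from .control import compare_controls
from .deconvolution import build_signature, deconvolve_matrix
from .diffexpr import estimate_dispersion, test_de
from .enrichment import compare_scores, ssgsea_score
from .io import write_gmt, write_json, write_matrix
from .matrix import ExpressionMatrix
from .preprocess import estimate_unwanted, filter_low_abundance, remove_unwanted, rle, uq_cpm
from .triad import (assign_models, directional_consistency, model_enrichment,
                    model_sharing, shared_genes, status_sharing)

log = logging.getLogger(__name__)

#: contrast name -> (reference condition, alternative condition)
CONTRASTS = {"AH": ("H", "A"), "TA": ("A", "T"), "TH": ("H", "T")}


@dataclass
class PipelineConfig:
    """Stage parameters of a pipeline run; unknown keys are rejected."""

    #: number of unwanted-variation factors per contrast
    k: int = 1
    #: DE significance level (Bonferroni-corrected)
    alpha: float = 0.05
    lfc_gate: float = 1.0
    abundance_gate: float = 3.0
    min_reads: int = 10
    min_samples: int = 2
    #: tissue-sharing threshold for the TASA set
    min_tissues: int = 3
    ssgsea_alpha: float = 0.25
    #: Bonferroni level for score comparisons
    score_significance: float = 0.001
    dispersion_prior_df: float = 10.0
    seed: int = 0

    def validate(self, n_tissues: int | None = None) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        for name in ("alpha", "score_significance"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.lfc_gate < 0 or self.abundance_gate != self.abundance_gate:
            raise ValueError("lfc_gate must be non-negative")
        if self.min_tissues < 1:
            raise ValueError("min_tissues must be >= 1")
        if n_tissues is not None and self.min_tissues > n_tissues:
            raise ValueError(f"min_tissues={self.min_tissues} exceeds the "
                             f"{n_tissues} tissues in the data")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def de_all_contrasts(counts: ExpressionMatrix, housekeeping, cfg: PipelineConfig
                     ) -> dict[str, dict[str, pd.DataFrame]]:
    """Run the three condition contrasts in every tissue.

    Normalization and factor estimation are performed between each pair of
    conditions in each tissue independently; the factors enter the NB GLM as
    covariates.  Returns ``{contrast: {tissue: DE table}}``.
    """
    results: dict[str, dict[str, pd.DataFrame]] = {c: {} for c in CONTRASTS}
    for tissue in counts.tissues():
        for cname, (ref, alt) in CONTRASTS.items():
            sub = counts.subset_samples(
                (counts.samples["tissue"] == tissue).to_numpy()
                & counts.samples["condition"].isin([ref, alt]).to_numpy())
            if (sub.condition_mask(ref).sum() < 2) or (sub.condition_mask(alt).sum() < 2):
                log.warning("skipping %s in %s: a condition has <2 samples", cname, tissue)
                continue
            labels = sub.samples["condition"].to_numpy()
            w = None
            if cfg.k > 0:
                logcpm = uq_cpm(sub, log2=True)
                w = estimate_unwanted(logcpm, housekeeping, cfg.k)
            phi = estimate_dispersion(sub, labels, prior_df=cfg.dispersion_prior_df)
            results[cname][tissue] = test_de(
                sub, labels, contrast=(ref, alt), w=w, phi=phi, alpha=cfg.alpha,
                lfc_gate=cfg.lfc_gate, abundance_gate=cfg.abundance_gate)
    return results


def run_pipeline(counts: ExpressionMatrix, housekeeping: list[str],
                 cfg: PipelineConfig, outdir) -> dict:
    """Run every stage and write artifacts plus a manifest under ``outdir``."""
    cfg.validate(n_tissues=len(counts.tissues()))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(cfg),
                      "n_genes_input": counts.n_genes, "n_samples": counts.n_samples,
                      "artifacts": {}}

    def emit(name, path):
        # paths relative to outdir so identical runs are byte-identical
        manifest["artifacts"][name] = Path(path).name

    filtered = filter_low_abundance(counts, cfg.min_reads, cfg.min_samples)
    manifest["n_genes_filtered"] = filtered.n_genes
    write_matrix(filtered, outdir / "counts_filtered.tsv", outdir / "metadata.tsv")
    emit("counts_filtered", outdir / "counts_filtered.tsv")

    cpm = uq_cpm(filtered)
    logcpm = uq_cpm(filtered, log2=True)
    rle_summary = rle(logcpm)
    rle_summary.to_csv(outdir / "rle.tsv", sep="\t")
    emit("rle", outdir / "rle.tsv")

    # comparability: assign NAT samples against healthy medians, housekeeping concordance
    panel = build_reference(cpm)
    nat = cpm.subset_samples(cpm.condition_mask("A"))
    comp = {}
    if nat.n_samples:
        assigned = assign_tissue(panel, nat)
        assigned.to_csv(outdir / "tissue_assignment.tsv", sep="\t", index=False)
        emit("tissue_assignment", outdir / "tissue_assignment.tsv")
        comp["tissue_assignment_accuracy"] = float(assigned["correct"].mean())
    hk_present = [g for g in housekeeping if g in set(logcpm.genes)]
    if hk_present:
        mh = logcpm.subset_samples(logcpm.condition_mask("H"))
        ma = logcpm.subset_samples(logcpm.condition_mask("A"))
        if mh.n_samples and ma.n_samples:
            comp["housekeeping"] = housekeeping_concordance(mh, ma, hk_present)
    write_json(comp, outdir / "comparability.json")
    emit("comparability", outdir / "comparability.json")

    de = de_all_contrasts(filtered, housekeeping, cfg)
    for cname, per_tissue in de.items():
        for tissue, table in per_tissue.items():
            p = outdir / f"de_{cname}_{tissue}.tsv"
            table.to_csv(p, sep="\t")
            emit(f"de_{cname}_{tissue}", p)

    tissues_with_both = sorted(set(de["AH"]) & set(de["TA"]))
    assignment = assign_models({t: de["AH"][t] for t in tissues_with_both},
                               {t: de["TA"][t] for t in tissues_with_both})
    long = assignment.stack().rename("model").rename_axis(["gene", "tissue"]).reset_index()
    long.to_csv(outdir / "models.tsv", sep="\t", index=False)
    emit("models", outdir / "models.tsv")

    enr = {t: model_enrichment(assignment, t).drop(columns="degenerate").to_dict("index")
           for t in tissues_with_both}
    sharing = {}
    n_t = len(tissues_with_both)
    for k_shared in range(2, n_t + 1):
        for status, key in (("U", "up_AH"), ("D", "down_AH")):
            r = status_sharing(de["AH"], status, k_shared)
            sharing[f"{key}_ge{k_shared}"] = asdict(r)
    if cfg.min_tissues <= n_t:
        sharing["tasa_UD"] = asdict(model_sharing(assignment, "UD", cfg.min_tissues))
    write_json({"model_enrichment": enr, "sharing": sharing}, outdir / "sharing.json")
    emit("sharing", outdir / "sharing.json")

    tasa_genes = shared_genes(assignment, "UD", cfg.min_tissues)
    tasr_genes = shared_genes(assignment, "DU", cfg.min_tissues)
    sets = {}
    if tasa_genes:
        sets["TASA_shared"] = tasa_genes
    if tasr_genes:
        sets["TASR_shared"] = tasr_genes
    if sets:
        write_gmt(sets, outdir / "shared_sets.gmt", description="shared-by-tissue sets")
        emit("shared_sets", outdir / "shared_sets.gmt")

    consistency = {}
    up_shared = set()
    for t in tissues_with_both:
        up_shared |= set(de["AH"][t].index[de["AH"][t]["status"] == "U"])
    down_shared = set()
    for t in tissues_with_both:
        down_shared |= set(de["AH"][t].index[de["AH"][t]["status"] == "D"])
    if up_shared:
        consistency["up_AH"] = directional_consistency(de["AH"], sorted(up_shared))
    if down_shared:
        consistency["down_AH"] = directional_consistency(de["AH"], sorted(down_shared))

    scores_summary = {}
    if tasa_genes:
        w_all = estimate_unwanted(logcpm, housekeeping, cfg.k) if cfg.k > 0 else None
        scored = remove_unwanted(logcpm, w_all) if w_all is not None else logcpm
        scores = ssgsea_score(scored, tasa_genes, alpha=cfg.ssgsea_alpha)
        pd.DataFrame({"sample": scores.index, "tasa_score": scores.to_numpy()}) \
            .to_csv(outdir / "tasa_scores.tsv", sep="\t", index=False)
        emit("tasa_scores", outdir / "tasa_scores.tsv")
        n_comparisons = 2 * len(tissues_with_both)
        for t in tissues_with_both:
            mask = (scored.samples["tissue"] == t).to_numpy()
            grp = scored.samples["condition"].to_numpy()[mask]
            sc = scores[mask]
            for other in ("H", "T"):
                if (grp == "A").any() and (grp == other).any():
                    scores_summary[f"{t}_A_vs_{other}"] = compare_scores(
                        sc, grp, (other, "A"), correction_factor=n_comparisons,
                        significance=cfg.score_significance)
    write_json({"directional_consistency": consistency,
                "tasa_score_comparisons": scores_summary},
               outdir / "scores_summary.json")
    emit("scores_summary", outdir / "scores_summary.json")

    deconv_frames = []
    for t in cpm.tissues():
        tsub = cpm.select(tissue=t)
        if tsub.condition_mask("H").any() and tsub.condition_mask("T").any():
            sig = build_signature(tsub, t)
            deconv_frames.append(deconvolve_matrix(tsub, sig))
    if deconv_frames:
        pd.concat(deconv_frames).to_csv(outdir / "deconvolution.tsv", sep="\t")
        emit("deconvolution", outdir / "deconvolution.tsv")

    control = {}
    for t in sorted(set(de["TH"]) & set(de["TA"])):
        control[t] = compare_controls(de["TH"][t], de["TA"][t]).as_dict()
    write_json(control, outdir / "control_comparison.json")
    emit("control_comparison", outdir / "control_comparison.json")

    manifest["seed"] = cfg.seed
    manifest["tissues"] = tissues_with_both
    manifest["n_tasa_genes"] = len(tasa_genes)
    write_json(manifest, outdir / "manifest.json")
    return manifest
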