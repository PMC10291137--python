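"""End-to-end pipeline: simulate (or load) a cohort and run every stage.

Stages: variant filtering + Jaccard + conservation -> CNA
categorisation + gene annotation + Jaccard -> fusion consensus +
validation + conservation -> ME-gene deconvolution + tumor matrix +
cross-species ME matrix -> PCA decomposition + component selection ->
growth doubling times.  A JSON manifest records parameters and sha256
checksums of every output, so identical config + inputs reproduce
identical checksums.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cna, components, deconvolution, fusions, growth, io, synthetic, variants

logger = logging.getLogger("pdxplore")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults."""

    seed: int = 0
    n_patients: int = 8
    n_genes: int = 2000
    n_me_genes: int = 200
    n_variants_shared: int = 30
    n_variants_relapse_gained: int = 15
    n_variants_pdx_private: int = 5
    # variant filter
    min_alt_reads: int = 5
    min_vaf: float = 0.05
    max_popaf: float = 0.01
    # cna
    focal_threshold: int = 5_000_000
    neutral_cn: int = 2
    cna_as_printed: bool = False
    # fusions
    min_tools: int = 3
    min_junction_reads: int = 1
    # deconvolution
    alpha: float = 0.05
    min_fold: float = 4.0
    absent_max_mean: float = 3.0
    # components
    min_var: float = 0.05
    selection_alpha: float = 0.05
    # proteomics
    max_missing: float = 0.34
    impute_rank: int = 2
    # growth
    growth_window: tuple = (200.0, 400.0)
    growth_td_days: float = 5.0
    growth_noise_cv: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["growth_window"] = list(d["growth_window"])
        return d


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a simulated cohort; write outputs + manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.CohortSpec(
        n_patients=config.n_patients,
        n_genes=config.n_genes,
        n_me_genes=config.n_me_genes,
        n_variants_shared=config.n_variants_shared,
        n_variants_relapse_gained=config.n_variants_relapse_gained,
        n_variants_pdx_private=config.n_variants_pdx_private,
        seed=config.seed,
    )
    written: list[Path] = []

    def _save(df: pd.DataFrame, name: str, index: bool = False):
        path = out / name
        if index:
            df.to_csv(path, sep="\t", index=True, index_label=df.index.name or "id")
        else:
            df.to_csv(path, sep="\t", index=False)
        written.append(path)
        return path

    # --- somatic variants -------------------------------------------------
    logger.info("variants: simulate + filter + jaccard + conservation")
    calls, _vtruth = synthetic.simulate_variant_cohort(spec)
    _save(calls, "variant_calls.tsv")
    thresholds = variants.FilterThresholds(
        min_alt_reads=config.min_alt_reads,
        min_vaf=config.min_vaf,
        max_popaf=config.max_popaf,
    )
    kept, log = variants.filter_variants(calls, thresholds)
    _save(kept, "variants_kept.tsv")
    _save(log, "variants_rejected.tsv")
    sets = variants.variant_key_sets(kept)
    _save(variants.pairwise_jaccard_matrix(sets), "variant_jaccard.tsv", index=True)
    _save(variants.classify_conservation(kept), "variant_conservation.tsv")
    gains = variants.mutation_gain_ratio(sets, kept[["sample", "patient", "timepoint"]].drop_duplicates())
    _save(gains, "mutation_gain.tsv")

    # --- copy number ------------------------------------------------------
    logger.info("cna: simulate + classify + annotate + jaccard")
    segments, gene_intervals, _ctruth = synthetic.simulate_cna_profiles(spec)
    _save(segments, "cna_segments.tsv")
    classified = cna.classify_segments(
        segments,
        focal_threshold=config.focal_threshold,
        neutral_cn=config.neutral_cn,
        as_printed=config.cna_as_printed,
    )
    _save(classified, "cna_classified.tsv")
    gene_calls = cna.annotate_genes(classified, gene_intervals)
    _save(gene_calls, "cna_gene_calls.tsv")
    _save(cna.cna_jaccard_matrix(cna.cna_alteration_sets(gene_calls)), "cna_jaccard.tsv", index=True)

    # --- fusions ----------------------------------------------------------
    logger.info("fusions: simulate + consensus + validate + conservation")
    fusion_calls, evidence, _ftruth = synthetic.simulate_fusion_calls(spec)
    _save(fusion_calls, "fusion_calls.tsv")
    _save(evidence, "fusion_evidence.tsv")
    consensus = fusions.consensus_filter(fusion_calls, min_tools=config.min_tools)
    _save(consensus, "fusion_consensus.tsv")
    validated = fusions.validate_breakpoint(
        consensus, evidence, min_junction_reads=config.min_junction_reads
    )
    _save(validated, "fusion_validated.tsv")
    sample_meta_f = pd.DataFrame(
        [
            (spec.sample_id(p, tp), p, tp)
            for p in spec.patients
            for tp in spec.timepoints
        ],
        columns=["sample", "patient", "timepoint"],
    )
    per_fusion, fsummary = fusions.conservation_counts(validated, sample_meta_f)
    _save(per_fusion, "fusion_conservation.tsv")
    _save(fsummary, "fusion_conservation_summary.tsv")

    # --- expression deconvolution ----------------------------------------
    logger.info("deconvolution: ME genes + tumor matrix + cross-species matrix")
    counts_h, counts_m, sample_meta, ortho, etruth = synthetic.simulate_expression_cohort(spec)
    io.write_counts(counts_h, out / "counts_human.tsv")
    io.write_counts(counts_m, out / "counts_mouse.tsv")
    written += [out / "counts_human.tsv", out / "counts_mouse.tsv"]
    _save(sample_meta, "sample_meta.tsv")
    _save(ortho, "ortholog_map.tsv")
    pat_samples = sample_meta.loc[sample_meta.fraction == "patient", "sample"]
    pdxh_samples = sample_meta.loc[sample_meta.fraction == "pdx_human", "sample"]
    me = deconvolution.identify_me_genes(
        counts_h[list(pat_samples)],
        counts_h[list(pdxh_samples)],
        alpha=config.alpha,
        min_fold=config.min_fold,
        absent_max_mean=config.absent_max_mean,
    )
    me.table.index.name = "gene"
    _save(me.table, "me_gene_table.tsv", index=True)
    tumor = me.tumor_matrix
    io.write_counts(tumor, out / "tumor_matrix.tsv")
    written.append(out / "tumor_matrix.tsv")
    if me.me_genes:
        merged, dropped = deconvolution.build_cross_species_me_matrix(
            counts_h.loc[sorted(me.me_genes), list(pat_samples)], counts_m, ortho
        )
        merged.index.name = "gene"
        _save(merged, "cross_species_me_matrix.tsv", index=True)
        _save(dropped, "cross_species_dropped.tsv")

    # --- component analysis ----------------------------------------------
    logger.info("components: decompose + select")
    logx = deconvolution.cpm_log1p(tumor)
    dec = components.decompose(logx)
    groups = {
        s: ("patient" if f == "patient" else "pdx")
        for s, f in zip(sample_meta["sample"], sample_meta["fraction"])
        if s in set(logx.columns)
    }
    components.select_components(
        dec, groups, min_var=config.min_var, alpha=config.selection_alpha
    )
    dec.scores.index.name = "sample"
    dec.loadings.index.name = "gene"
    _save(dec.scores, "component_scores.tsv", index=True)
    _save(dec.loadings.iloc[:, : min(10, dec.loadings.shape[1])], "component_loadings.tsv", index=True)
    _save(
        pd.DataFrame(
            {
                "component": dec.component_names,
                "var_fraction": dec.var_fraction,
                "selected": dec.selected,
                "rejection_reason": dec.rejection_reason,
            }
        ),
        "component_selection.tsv",
    )

    # --- proteomics -------------------------------------------------------
    logger.info("proteomics: missingness filter + imputation")
    prot, _complete = synthetic.simulate_protein_matrix(seed=config.seed)
    kept_prot, dropped_prot = components.filter_by_missingness(prot, config.max_missing)
    imputed, _, _ = components.pca_impute(kept_prot, rank=config.impute_rank)
    imputed.index.name = "protein"
    _save(imputed, "proteins_imputed.tsv", index=True)
    _save(dropped_prot, "proteins_dropped.tsv")

    # --- growth -----------------------------------------------------------
    logger.info("growth: doubling-time estimation")
    rows = []
    for i in range(config.n_patients):
        curve = synthetic.simulate_growth_curve(
            150.0, config.growth_td_days, config.growth_noise_cv,
            np.arange(0, 12.2, 0.2), seed=config.seed + 100 + i,
        )
        curve.insert(0, "mouse_id", f"M{i:02d}")
        rows.append(curve)
    measurements = pd.concat(rows, ignore_index=True)
    _save(measurements, "growth_curves.tsv")
    td = growth.doubling_time_table(measurements, window=tuple(config.growth_window))
    _save(td, "growth_td.tsv")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "outputs": io.checksum_tree(written),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("wrote %d outputs + manifest to %s", len(written), out)
    return manifest
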