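"""Seeded end-to-end driver: simulate -> ancestry -> associate -> d-QTL ->
mismatches -> correct -> re-associate -> design.

The driver exists to exercise every stage on one coherent synthetic cohort
and to emit per-stage tables plus a machine-readable summary; rerunning
with the same configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, correction, design, dqtl, io, mismatch
from .ancestry import (build_windows, global_ancestry_fractions,
                       infer_local_ancestry)
from .config import PipelineConfig, SimConfig
from .simulate import (ArtifactSpec, simulate_candidates, simulate_cohort)

logger = logging.getLogger(__name__)


def default_demo_sim_config(seed: int) -> tuple[SimConfig,
                                                list[ArtifactSpec]]:
    """A small three-population cohort with planted artifacts and one
    genuine ancestry-linked dependency, sized to run in seconds."""
    n_samples = 120
    n_pop = 3
    q = np.full((n_samples, n_pop), 0.03)
    for i in range(n_samples):
        q[i, i % n_pop] = 1.0 - 0.03 * (n_pop - 1)
    cfg = SimConfig(
        n_populations=n_pop, fst=0.15, n_samples=n_samples,
        n_chromosomes=2, n_variants_per_chrom=3000,
        chrom_length_bp=10_000_000,
        cm_per_chrom=10.0, admixture_proportions=q,
        n_genes=30, guides_per_gene=4, noise_sd=0.4,
        gene_effect_mean=-1.0, gene_effect_sd=0.25,
        n_lineages=3, lineage_effect_sd=0.25,
        injected_true_dependency_effects=[("GENE0020", "AFR", -1.0)],
        seed=seed)
    hi, lo = 0.7, 0.02
    specs = [ArtifactSpec(f"GENE{g:04d}", 0, 1,
                          {"AFR": hi, "AMR": lo, "EAS": lo})
             for g in range(6)]
    # background of common, PAM-distal (well tolerated) in-guide variants,
    # mildly AFR-enriched as real variation is
    specs += [ArtifactSpec(f"GENE{g:04d}", 2, 18,
                           {"AFR": 0.3, "AMR": 0.12, "EAS": 0.12})
              for g in range(6, 30)]
    return cfg, specs


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 sim_config: SimConfig | None = None,
                 artifact_specs: list[ArtifactSpec] | None = None) -> dict:
    """Execute every stage on a synthetic cohort and write a report bundle.

    Returns the summary dict (also written to ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim_config is None:
        sim_config, default_specs = default_demo_sim_config(config.seed)
        if artifact_specs is None:
            artifact_specs = default_specs

    stage = "simulate"
    try:
        cohort = simulate_cohort(sim_config, artifact_specs)
        io.write_fixtures(cohort.genotypes, cohort.library,
                          cohort.screen.guide_lfc,
                          cohort.screen.gene_dependency, cohort.tss,
                          cohort.metadata, outdir, panel=cohort.panel,
                          gmap=cohort.gmap)

        stage = "ancestry"
        windows = build_windows(cohort.gmap, config.window_cm)
        track = infer_local_ancestry(cohort.genotypes, cohort.panel,
                                     windows, cohort.gmap)
        glob = global_ancestry_fractions(track, windows,
                                         config.predominance_threshold)
        io.write_track(track, windows, outdir / "local_ancestry.tsv")
        io.write_matrix(glob.fractions, outdir / "global_ancestry.csv",
                        "global ancestry fractions")

        stage = "associate"
        labels = association.bin_samples_by_locus_ancestry(
            cohort.tss, track, windows, cohort.gmap, glob)
        groups = sorted(set(np.unique(labels.to_numpy())))
        pre = association.test_all_groups(cohort.screen, labels, groups,
                                          config.fdr_q)
        pre.to_csv(outdir / "association_pre.tsv", sep="\t", index=False)

        stage = "mismatch"
        mm = mismatch.map_variants_to_guides(cohort.genotypes,
                                             cohort.library)
        fractions = mismatch.per_sample_affected_fraction(
            mm, cohort.library, cohort.genotypes.samples,
            config.include_pam_n)
        recurrent = mismatch.guides_affected_in_k_samples(
            mm, config.min_affected_lines, config.include_pam_n)
        hist = mismatch.per_gene_affected_guide_histogram(
            mm, cohort.library, config.include_pam_n)
        pos_eff = mismatch.positional_effects(mm, cohort.screen.guide_lfc)
        mm.to_csv(outdir / "mismatch_table.tsv", sep="\t", index=False)
        pos_eff.to_csv(outdir / "positional_effects.tsv", sep="\t",
                       index=False)
        burden = mismatch.afr_burden_ratio(fractions, glob.predominant) \
            if (glob.predominant == "AFR").any() else float("nan")

        stage = "dqtl"
        flagged = sorted(pre.loc[pre["significant"], "gene"].unique())
        filtered = dqtl.filter_by_maf(cohort.genotypes, config.maf_min)
        dq = dqtl.scan_genes(cohort.screen.gene_dependency, flagged,
                             filtered, cohort.screen.lineage,
                             glob.predominant, cohort.tss, config.fdr_q,
                             config.differential_maf, config.proximal_bp)
        dq.to_csv(outdir / "dqtl_markers.tsv", sep="\t", index=False)

        stage = "correct"
        corrected = correction.correct_gene_scores(
            cohort.screen.guide_lfc, cohort.library, mm,
            include_pam_n=config.include_pam_n)
        io.write_matrix(corrected, outdir / "gene_dependency_corrected.csv",
                        "corrected gene dependency")
        diff = correction.pre_post_differential(
            cohort.screen.gene_dependency, corrected, config.fdr_q)
        diff.to_csv(outdir / "pre_post_differential.tsv", sep="\t",
                    index=False)
        paired = correction.rerun_association_post_correction(
            cohort.screen, corrected, labels, groups, config.fdr_q)
        paired.to_csv(outdir / "association_pre_post.tsv", sep="\t",
                      index=False)

        stage = "design"
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])
        candidates = simulate_candidates(sim_config, rng)
        des = design.design_library(
            candidates, config.maf_min, config.afr_ratio_max,
            config.afr_rate_floor, config.guides_per_gene)
        bench = design.design_quality_benchmark(des, candidates)
        des.per_gene.to_csv(outdir / "library_design.tsv", sep="\t",
                            index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    post_sig = paired.loc[paired["significant_post"].fillna(False), "gene"]
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": int(len(cohort.genotypes.samples)),
        "n_genes": int(len(cohort.tss)),
        "n_guides": int(len(cohort.library)),
        "n_variants": int(cohort.genotypes.n_variants),
        "predominant_counts": glob.predominant.value_counts().to_dict(),
        "n_significant_pre": int(pre["significant"].sum()),
        "n_significant_post": int(post_sig.nunique()),
        "n_dqtl_markers": int(dq["marker_significant"].sum())
        if len(dq) else 0,
        "n_ancestry_associated_markers": int(dq["ancestry_associated"].sum())
        if len(dq) else 0,
        "n_proximal_markers": int(dq["proximal"].sum()) if len(dq) else 0,
        "median_affected_fraction": float(fractions.median()),
        "afr_burden_ratio": burden,
        "n_recurrent_guides": int(len(recurrent)),
        "affected_guide_histogram": {int(k): int(v)
                                     for k, v in hist.items()},
        "n_prepost_changed_genes": int(diff["significant"].sum()),
        "design_mean_score_delta": bench["mean_delta_all"],
        "design_unconstrained_identical": int(
            des.per_gene["unconstrained_top4_identical"].sum()),
    }
    summary = {k: (None if isinstance(v, float) and np.isnan(v) else v)
               for k, v in summary.items()}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
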