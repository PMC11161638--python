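"""Benchmark scenarios: fixed synthetic study conditions with known truth.

Each function builds one cohort (or replicate set), runs the relevant part
of the analysis, and returns the measured quantities.  The conditions —
sample sizes, divergence, noise levels, planted effect sizes — are the
package's reference operating points; the power behind each one is derived
in the methods note.  All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import correction, dqtl, mismatch
from .ancestry import (build_windows, global_ancestry_fractions,
                       infer_local_ancestry)
from .association import bin_samples_by_locus_ancestry, power_simulation
from .config import SimConfig
from .simulate import ArtifactSpec, simulate_cohort

#: group sizes of the screened cell-line collection by predominant ancestry
COHORT_GROUP_SIZES = {"AFR": 26, "AMR": 6, "EAS": 203, "EUR": 373, "SAS": 4}


def measure_window_recovery(seed: int, n_samples: int = 50,
                            fst: float = 0.1,
                            variants_per_window: int = 200) -> dict:
    """Local-ancestry recovery: fraction of windows matching the painting.

    Three populations at the given divergence, one 10 cM chromosome tiled
    into 0.2 cM windows with ``variants_per_window`` panel variants each.
    """
    n_windows = 50
    cfg = SimConfig(n_populations=3, fst=fst, n_samples=n_samples,
                    n_chromosomes=1,
                    n_variants_per_chrom=n_windows * variants_per_window,
                    cm_per_chrom=10.0, seed=seed)
    c = simulate_cohort(cfg)
    track = infer_local_ancestry(c.genotypes, c.panel, c.windows, c.gmap)
    truth = np.sort(c.truth.ancestry_painting.transpose(0, 2, 1), axis=-1)
    acc = float((track.pair == truth).all(axis=-1).mean())
    return {"accuracy": acc, "n_windows": int(track.pair[:, :, 0].size)}


def measure_power(seed: int, reps: int = 1000,
                  effect_grid=None) -> pd.DataFrame:
    """Power curves at the collection's group sizes (lineage-adjusted)."""
    if effect_grid is None:
        effect_grid = np.round(np.arange(0.0, 1.01, 0.1), 2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    return power_simulation(COHORT_GROUP_SIZES, effect_grid=effect_grid,
                            reps=reps,
                            lineage_freqs={"a": 0.5, "b": 0.3, "c": 0.2},
                            rng=rng)


def _two_group_proportions(n_samples: int) -> np.ndarray:
    q = np.zeros((n_samples, 2))
    q[: n_samples // 2, 0] = 1.0
    q[n_samples // 2:, 1] = 1.0
    return q


def dqtl_recovery_replicate(seed: int) -> bool:
    """One replicate: is the planted in-guide SNP the marker d-QTL
    (or in tight LD, r^2 >= 0.8, with it)?

    100 samples in two equal groups; one fully attenuating SNP planted in
    the first guide of one gene at frequency 0.5 vs 0.05, intermediate in
    the carrier group so that carrier status varies within ancestry and
    the causal variant outranks mere ancestry proxies.
    """
    cfg = SimConfig(n_populations=2, fst=0.1, n_samples=100,
                    n_chromosomes=1, n_variants_per_chrom=800,
                    cm_per_chrom=10.0,
                    admixture_proportions=_two_group_proportions(100),
                    n_genes=10, noise_sd=0.2, gene_effect_mean=-1.0,
                    gene_effect_sd=0.2, n_lineages=2, seed=seed)
    specs = [ArtifactSpec("GENE0000", 0, 1, {"AFR": 0.5, "AMR": 0.05})]
    c = simulate_cohort(cfg, specs)
    planted = c.truth.causal_artifact_table["variant_id"].iloc[0]
    filtered = dqtl.filter_by_maf(c.genotypes, 0.01)
    res = dqtl.dqtl_scan(c.screen.gene_dependency["GENE0000"], filtered,
                         c.screen.lineage)
    marker = dqtl.select_marker(res)
    if marker is None:
        return False
    if marker["variant_id"] == planted:
        return True
    if planted not in c.genotypes.dosages.columns:
        return False
    r2 = dqtl.ld_r2(c.genotypes.dosages[planted],
                    c.genotypes.dosages[marker["variant_id"]])
    return bool(np.isfinite(r2) and r2 >= 0.8)


def measure_dqtl_recovery(seed: int, replicates: int = 50) -> dict:
    seeds = np.random.SeedSequence([seed, 2]).generate_state(replicates)
    hits = sum(dqtl_recovery_replicate(int(s) % (2 ** 31))
               for s in seeds)
    return {"recovery_rate": hits / replicates, "n": replicates}


def build_headline_cohort(seed: int, n_artifact: int = 10,
                          true_effects: list | None = None):
    """The artifact-correction cohort: 200 samples in two groups, 50
    genes with 4 guides each, ``n_artifact`` genes carrying one fully
    attenuating PAM-proximal SNP at strongly differential frequency.

    Depletion noise is 0.4 LFC so the planted quarter-guide shift is
    detectable at the cohort size (see the methods note).
    """
    cfg = SimConfig(n_populations=2, fst=0.1, n_samples=200,
                    n_chromosomes=1, n_variants_per_chrom=3000,
                    cm_per_chrom=10.0,
                    admixture_proportions=_two_group_proportions(200),
                    n_genes=50, noise_sd=0.4, gene_effect_mean=-1.0,
                    gene_effect_sd=0.25, n_lineages=3,
                    injected_true_dependency_effects=true_effects or [],
                    seed=seed)
    specs = [ArtifactSpec(f"GENE{g:04d}", 0, 1,
                          {"AFR": 0.9, "AMR": 0.02})
             for g in range(n_artifact)]
    return simulate_cohort(cfg, specs)


def artifact_correction_replicate(seed: int,
                                  with_true_effects: bool = False) -> dict:
    """Pre/post significant counts among planted artifact genes (and,
    optionally, persistence of genuinely ancestry-linked genes)."""
    true_effects = [("GENE0047", "AFR", -1.0), ("GENE0048", "AMR", -1.0),
                    ("GENE0049", "AFR", -1.0)] if with_true_effects else []
    c = build_headline_cohort(seed, true_effects=true_effects)
    windows = build_windows(c.gmap, 0.2)
    track = infer_local_ancestry(c.genotypes, c.panel, windows, c.gmap)
    glob = global_ancestry_fractions(track, windows)
    labels = bin_samples_by_locus_ancestry(c.tss, track, windows, c.gmap,
                                           glob)
    table = mismatch.map_variants_to_guides(c.genotypes, c.library)
    corrected = correction.correct_gene_scores(c.screen.guide_lfc,
                                               c.library, table)
    paired = correction.rerun_association_post_correction(
        c.screen, corrected, labels, ["AFR", "AMR"])
    art = set(c.truth.causal_artifact_table["gene"])
    pre = set(paired.loc[paired["significant"].fillna(False), "gene"])
    post = set(paired.loc[paired["significant_post"].fillna(False), "gene"])
    out = {"artifact_pre": len(art & pre), "artifact_post": len(art & post),
           "n_artifact": len(art)}
    if with_true_effects:
        true_genes = set(g for g, _, _ in true_effects)
        out["true_pre"] = len(true_genes & pre)
        out["true_post"] = len(true_genes & post)
        out["n_true"] = len(true_genes)
    return out


def measure_artifact_correction(seed: int, replicates: int = 10) -> dict:
    """Median pre/post artifact recovery over seeds, plus persistence of
    genuine effects from one cohort that carries them."""
    seeds = np.random.SeedSequence([seed, 3]).generate_state(replicates)
    runs = [artifact_correction_replicate(int(s) % (2 ** 31))
            for s in seeds]
    persist = artifact_correction_replicate(int(seeds[0]) % (2 ** 31),
                                            with_true_effects=True)
    return {
        "median_artifact_pre": float(np.median([r["artifact_pre"]
                                                for r in runs])),
        "median_artifact_post": float(np.median([r["artifact_post"]
                                                 for r in runs])),
        "n_artifact": runs[0]["n_artifact"],
        "n_replicates": replicates,
        "true_effect_pre": persist["true_pre"],
        "true_effect_post": persist["true_post"],
        "n_true": persist["n_true"],
    }


def build_positional_cohort(seed: int):
    """One variant planted per guide, positions cycling 1..20, equal
    frequency (0.3) in both populations, under a linearly decaying
    positional tolerance profile (1.0 PAM-proximal to 0.05 distal)."""
    weights = np.linspace(1.0, 0.05, 20)
    cfg = SimConfig(n_populations=2, fst=0.1, n_samples=150,
                    n_chromosomes=2, n_variants_per_chrom=300,
                    cm_per_chrom=10.0, n_genes=40, noise_sd=0.3,
                    gene_effect_mean=-1.0, gene_effect_sd=0.1,
                    positional_weights=weights, seed=seed)
    specs = []
    for g in range(cfg.n_genes):
        for j in range(cfg.guides_per_gene):
            pos = (g * cfg.guides_per_gene + j) % 20 + 1
            specs.append(ArtifactSpec(f"GENE{g:04d}", j, pos,
                                      {"AFR": 0.3, "AMR": 0.3}))
    return simulate_cohort(cfg, specs), weights


def measure_positional_gradient(seed: int) -> dict:
    cohort, weights = build_positional_cohort(seed)
    table = mismatch.map_variants_to_guides(cohort.genotypes,
                                            cohort.library)
    eff = mismatch.positional_effects(table, cohort.screen.guide_lfc)
    eff = eff.set_index("position").reindex(range(1, 21))
    rho = stats.spearmanr(eff["effect"].to_numpy(), weights).statistic
    protective = float((eff["effect"] > 0).mean())
    return {"spearman": float(rho), "protective_fraction": protective,
            "n_positions": int(eff["effect"].notna().sum())}
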