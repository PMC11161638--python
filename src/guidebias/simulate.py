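"""Synthetic cohort generator with known ground truth.

The generator emulates the inputs of the real analysis: a reference panel of
per-population allele frequencies (Balding-Nichols differentiation), admixed
diploid genomes painted block-wise on a genetic map, a tiled guide library
with 4 guides per gene, and a viability screen whose guide-level depletion is
attenuated when a sample carries a variant inside a guide's targeting
sequence, with the attenuation strongest next to the PAM.

Every stochastic step takes an explicit :class:`numpy.random.Generator`;
:func:`simulate_cohort` expands one seed into independent per-stage streams
so identical configurations give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import WindowSet, build_windows
from .config import ConfigurationError, InputError, SimConfig
from .types import (AncestryPanel, GeneticMap, ScreenData, TruthSet,
                    VariantGenotypes)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: attenuation weight applied to variants in the two required PAM "GG" bases
PAM_GG_WEIGHT = 1.0


@dataclass
class ArtifactSpec:
    """A variant planted inside one guide of one gene.

    ``freqs`` gives the per-population alternate-allele frequency of the
    planted variant; an ancestry-differential artifact uses frequencies that
    differ strongly between populations.
    """

    gene: str
    guide_index: int
    position_from_pam: int
    freqs: dict[str, float]


@dataclass
class SimulatedCohort:
    """Everything one synthetic run produces, truth included."""

    config: SimConfig
    gmap: GeneticMap
    windows: WindowSet
    panel: AncestryPanel
    genotypes: VariantGenotypes
    truth: TruthSet
    library: pd.DataFrame
    tss: pd.DataFrame
    screen: ScreenData
    metadata: pd.DataFrame
    mismatch_table: pd.DataFrame = field(default=None)


def simulate_panel(config: SimConfig, rng: np.random.Generator,
                   gmap: GeneticMap | None = None) -> AncestryPanel:
    """Draw per-population allele frequencies under Balding-Nichols.

    Ancestral frequencies are Uniform(0.05, 0.95); each population draws
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p with its own
    divergence F (F = 0 collapses to the ancestral frequency exactly).
    Frequencies are clipped to [0.001, 0.999].
    """
    if config.n_populations < 2:
        raise ConfigurationError("panel needs at least 2 populations")
    if gmap is None:
        gmap = uniform_map(config)
    rows = []
    for chrom in gmap.chroms:
        end = gmap.chrom_end(chrom)
        pos = rng.choice(np.arange(100, end - 100),
                         size=config.n_variants_per_chrom, replace=False)
        pos.sort()
        ref_idx = rng.integers(0, 4, size=pos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
        for p0, r, a in zip(pos, ref_idx, alt_idx):
            rows.append((chrom, int(p0), _BASES[r], _BASES[a]))
    variants = pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt"])
    variants.index = pd.Index(
        [f"{c}:{p + 1}:{r}:{a}" for c, p, r, a in rows], name="variant_id")

    n_var = len(variants)
    p_anc = rng.uniform(0.05, 0.95, size=n_var)
    freqs = np.empty((n_var, config.n_populations))
    for k, f in enumerate(np.asarray(config.fst)):
        if f == 0:
            freqs[:, k] = p_anc
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            freqs[:, k] = rng.beta(a, b)
    freqs = np.clip(freqs, 0.001, 0.999)
    freq_df = pd.DataFrame(freqs, index=variants.index,
                           columns=list(config.populations))
    return AncestryPanel(variants=variants, freqs=freq_df)


def uniform_map(config: SimConfig) -> GeneticMap:
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    return GeneticMap.uniform(chroms, config.chrom_length_bp,
                              config.cm_per_chrom)


def _admixture(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.admixture_proportions is not None:
        return config.admixture_proportions
    # mostly-homogeneous cohort with a tail of admixed samples
    return rng.dirichlet(np.full(config.n_populations, 0.3),
                         size=config.n_samples)


def simulate_admixed_genomes(panel: AncestryPanel, gmap: GeneticMap,
                             config: SimConfig, rng: np.random.Generator,
                             windows: WindowSet | None = None,
                             ) -> tuple[VariantGenotypes, TruthSet]:
    """Paint haplotypes block-wise and draw alleles from the painted panel.

    Each haplotype is a sequence of ancestry blocks whose breakpoints form a
    Poisson process on the centimorgan scale with mean block length
    ``config.mean_block_cm`` (default 5 cM), realised at window resolution:
    crossing a window boundary of genetic length d switches ancestry with
    probability 1 - exp(-d / mean_block_cm), redrawing from the sample's
    admixture proportions.  Alleles are Bernoulli(population frequency of
    the window's painted ancestry); diploid dosage is the haplotype sum.
    """
    if not gmap.tables:
        raise InputError("empty genetic map")
    if windows is None:
        windows = build_windows(gmap, 0.2)
    q = _admixture(config, rng)
    n_s, n_pop = q.shape
    n_w = windows.n_windows

    painting = np.empty((n_s, 2, n_w), dtype=np.int64)
    cmtab = windows.table
    for chrom in gmap.chroms:
        sl = windows.chrom_slice(chrom)
        spans = (cmtab["cm_end"] - cmtab["cm_start"]).to_numpy()[sl]
        switch_p = 1.0 - np.exp(-spans[:-1] / config.mean_block_cm)
        for s in range(n_s):
            for h in range(2):
                anc = rng.choice(n_pop, p=q[s])
                out = np.empty(len(spans), dtype=np.int64)
                out[0] = anc
                switches = rng.random(len(spans) - 1) < switch_p
                for i, sw in enumerate(switches, start=1):
                    if sw:
                        anc = rng.choice(n_pop, p=q[s])
                    out[i] = anc
                painting[s, h, sl] = out

    widx = windows.assign_variants(gmap, panel.variants)
    freqs = panel.freqs.to_numpy()
    n_v = len(panel.variants)
    var_pop = painting[:, :, widx]                      # (S, 2, V)
    site_freq = freqs[np.arange(n_v)[None, None, :], var_pop]
    hap = (rng.random((n_s, 2, n_v)) < site_freq)
    dosage = hap.sum(axis=1).astype(float)

    samples = pd.Index([f"S{i:04d}" for i in range(n_s)], name="sample_id")
    dosages = pd.DataFrame(dosage, index=samples, columns=panel.variants.index)
    genotypes = VariantGenotypes(variants=panel.variants.copy(),
                                 dosages=dosages)
    truth = TruthSet(ancestry_painting=painting)
    return genotypes, truth


def true_global_fractions(truth: TruthSet, windows: WindowSet,
                          populations: list[str],
                          samples: pd.Index) -> pd.DataFrame:
    """Genome-wide painted fraction per population (equal chromosome weight)."""
    chroms = windows.table["chrom"].unique()
    acc = np.zeros((len(samples), len(populations)))
    for chrom in chroms:
        sl = windows.chrom_slice(str(chrom))
        sub = truth.ancestry_painting[:, :, sl]
        for p in range(len(populations)):
            acc[:, p] += (sub == p).mean(axis=(1, 2))
    acc /= len(chroms)
    return pd.DataFrame(acc, index=samples, columns=populations)


def simulate_guide_library(config: SimConfig, gmap: GeneticMap,
                           rng: np.random.Generator,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place genes at distinct TSS positions and tile 4 guides over each.

    Guides get random 20-nt protospacers, NGG PAMs and mixed strands; their
    23-bp targeting intervals stay inside the chromosome and do not overlap
    each other within a gene.
    """
    chroms = gmap.chroms
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    locus_bp = 200  # footprint reserved per gene
    guide_rows, tss_rows = [], []
    g = 0
    for chrom in chroms:
        end = gmap.chrom_end(chrom)
        if per_chrom * locus_bp * 2 > end:
            raise InputError("chromosome too short for requested gene count")
        starts = np.linspace(end * 0.05, end * 0.9, per_chrom).astype(int)
        for s0 in starts:
            if g >= config.n_genes:
                break
            gene = f"GENE{g:04d}"
            tss = int(s0)
            tss_rows.append((gene, chrom, tss))
            for j in range(config.guides_per_gene):
                start = tss + 10 + j * 40  # disjoint 23-bp intervals
                strand = "+" if rng.random() < 0.5 else "-"
                proto = "".join(rng.choice(_BASES, size=20))
                pam = rng.choice(_BASES) + "GG"
                guide_rows.append((f"{gene}_g{j + 1}", gene, chrom, start,
                                   start + 23, strand, proto, pam))
            g += 1
    if g < config.n_genes:
        raise InputError("could not place all genes")
    library = pd.DataFrame(guide_rows, columns=[
        "guide_id", "gene", "chrom", "start", "end", "strand",
        "protospacer", "pam"])
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss0"])
    return library, tss


def variant_position_in_guide(guide: pd.Series, position_from_pam: int) -> int:
    """Genomic 0-based position of a protospacer base, counted from the PAM."""
    if not 1 <= position_from_pam <= 20:
        raise ConfigurationError("position_from_pam must be in 1..20")
    if guide["strand"] == "+":
        pam_n = guide["start"] + 20
        return int(pam_n - position_from_pam)
    pam_n = guide["start"] + 2
    return int(pam_n + position_from_pam)


def inject_guide_variants(panel: AncestryPanel, library: pd.DataFrame,
                          specs: list[ArtifactSpec]) -> tuple[AncestryPanel,
                                                              pd.DataFrame]:
    """Plant variants inside chosen guides, with chosen panel frequencies.

    Returns the augmented panel (variants re-sorted by position) and a truth
    table [gene, guide_id, variant_id, position_from_pam].
    """
    variants = panel.variants.copy()
    freqs = panel.freqs.copy()
    records = []
    for spec in specs:
        sub = library[library["gene"] == spec.gene].reset_index(drop=True)
        if spec.guide_index >= len(sub):
            raise ConfigurationError(
                f"gene {spec.gene} has no guide {spec.guide_index}")
        guide = sub.iloc[spec.guide_index]
        pos0 = variant_position_in_guide(guide, spec.position_from_pam)
        offset = 20 - spec.position_from_pam
        base = guide["protospacer"][offset]
        ref = base if guide["strand"] == "+" else base.translate(_COMPLEMENT)
        alt = "A" if ref != "A" else "G"
        vid = f"{guide['chrom']}:{pos0 + 1}:{ref}:{alt}"
        clash = (variants["chrom"] == guide["chrom"]) & \
                (variants["pos0"] == pos0)
        variants = variants[~clash]
        freqs = freqs.loc[variants.index]
        variants.loc[vid] = [guide["chrom"], pos0, ref, alt]
        fvals = [spec.freqs[p] for p in freqs.columns]
        if any(not (0 < f < 1) for f in fvals):
            raise ConfigurationError("planted frequencies must be in (0,1)")
        freqs.loc[vid] = fvals
        records.append((spec.gene, guide["guide_id"], vid,
                        spec.position_from_pam))
    order = np.lexsort((variants["pos0"].to_numpy(),
                        variants["chrom"].to_numpy()))
    variants = variants.iloc[order]
    freqs = freqs.loc[variants.index]
    truth = pd.DataFrame(records, columns=["gene", "guide_id", "variant_id",
                                           "position_from_pam"])
    return AncestryPanel(variants=variants, freqs=freqs), truth


def simulate_screen(library: pd.DataFrame, tss: pd.DataFrame,
                    genotypes: VariantGenotypes, truth: TruthSet,
                    config: SimConfig, windows: WindowSet, gmap: GeneticMap,
                    rng: np.random.Generator) -> ScreenData:
    """Draw guide-level log-fold-changes with mismatch attenuation.

    LFC(g, c) = effect(gene(g), c) * activity(g, c) + Normal(0, noise_sd^2)

    where effect is the gene's base effect plus a lineage offset plus any
    injected ancestry effect (scaled by the fraction of the sample's two
    haplotypes painted with that ancestry at the gene's TSS), and activity
    multiplies (1 - w_position * d) over in-guide variants the sample
    carries (d = 1 when homozygous alternate, ``het_attenuation_factor``
    when heterozygous).  Variants in the PAM "GG" bases attenuate fully;
    the degenerate "N" base does not attenuate.  Gene-level dependency is
    the per-gene mean of guide LFCs (uncorrected).
    """
    from .mismatch import map_variant_guide_overlaps

    samples = genotypes.samples
    n_s = len(samples)
    genes = tss["gene"].tolist()

    lineages = pd.Series(
        [f"L{j}" for j in rng.integers(0, config.n_lineages, size=n_s)],
        index=samples, name="lineage")

    base = rng.normal(config.gene_effect_mean, config.gene_effect_sd,
                      size=len(genes))
    lin_levels = sorted(lineages.unique())
    lin_off = rng.normal(0.0, config.lineage_effect_sd,
                         size=(len(genes), len(lin_levels)))
    lin_idx = lineages.map({lv: i for i, lv in enumerate(lin_levels)})
    effect = base[:, None] + lin_off[:, lin_idx.to_numpy()]  # (G, S)

    pops = list(config.populations)
    for gene, ancestry, eff in config.injected_true_dependency_effects:
        gi = genes.index(gene)
        row = tss[tss["gene"] == gene].iloc[0]
        w = windows.locate(gmap, row["chrom"], int(row["tss0"]))
        match = (truth.ancestry_painting[:, :, w] == pops.index(ancestry))
        effect[gi] += eff * match.mean(axis=1)

    overlaps = map_variant_guide_overlaps(genotypes.variants, library)
    weights = np.zeros(len(overlaps))
    w20 = config.positional_weights
    for i, p in enumerate(overlaps["position_from_pam"].to_numpy()):
        if 1 <= p <= 20:
            weights[i] = w20[p - 1]
        elif p in (-1, -2):
            weights[i] = PAM_GG_WEIGHT
    activity = np.ones((len(library), n_s))
    guide_pos = {gid: i for i, gid in enumerate(library["guide_id"])}
    dos = genotypes.dosages
    for (gid, vid), wgt in zip(
            overlaps[["guide_id", "variant_id"]].itertuples(index=False),
            weights):
        if wgt == 0:
            continue
        d = dos[vid].to_numpy()
        carrier = np.where(np.isnan(d), 0.0,
                           np.where(d >= 2, 1.0,
                                    np.where(d >= 1,
                                             config.het_attenuation_factor,
                                             0.0)))
        activity[guide_pos[gid]] *= 1.0 - wgt * carrier

    gene_of_guide = library["gene"].map({g: i for i, g in enumerate(genes)})
    eff_guides = effect[gene_of_guide.to_numpy()]        # (n_guides, S)
    noise = rng.normal(0.0, config.noise_sd, size=eff_guides.shape)
    lfc = eff_guides * activity + noise

    guide_lfc = pd.DataFrame(lfc.T, index=samples,
                             columns=library["guide_id"].tolist())
    gene_dep = guide_lfc.T.groupby(gene_of_guide.to_numpy()).mean().T
    gene_dep.columns = [genes[i] for i in gene_dep.columns]
    gene_dep = gene_dep[genes]
    truth.positional_weights_used = w20.copy()
    return ScreenData(guide_lfc=guide_lfc, gene_dependency=gene_dep,
                      lineage=lineages)


def simulate_candidates(config: SimConfig, rng: np.random.Generator,
                        n_candidates_per_gene: int = 8,
                        p_variant: float = 0.3) -> pd.DataFrame:
    """Candidate guides with on-target scores and overlapping variants.

    Each gene gets ``n_candidates_per_gene`` candidates with Uniform(0.4, 1)
    on-target scores; a candidate carries an in-interval variant with
    probability ``p_variant``, with AFR and non-AFR allele frequencies drawn
    so that common variants and AFR-skewed variants both occur.
    """
    rows = []
    for g in range(config.n_genes):
        gene = f"GENE{g:04d}"
        scores = rng.uniform(0.4, 1.0, size=n_candidates_per_gene)
        for j in range(n_candidates_per_gene):
            variants = []
            while rng.random() < p_variant:
                f_afr = float(rng.choice([rng.uniform(0.0005, 0.005),
                                          rng.uniform(0.005, 0.2)]))
                skew = float(rng.choice([1.0, 0.2]))
                f_non = f_afr * skew
                variants.append({
                    "freq_AFR": f_afr,
                    "freq_nonAFR": f_non,
                    "freq_all": 0.25 * f_afr + 0.75 * f_non,
                })
            rows.append((gene, f"{gene}_c{j + 1}", float(scores[j]),
                         variants))
    return pd.DataFrame(rows, columns=["gene", "guide_id",
                                       "on_target_score", "variants"])


def simulate_cohort(config: SimConfig,
                    artifact_specs: list[ArtifactSpec] | None = None,
                    ) -> SimulatedCohort:
    """Run the full generator from one seed.

    The seed is expanded into independent streams for the panel, the
    genomes, the library and the screen, so adding draws to one stage never
    perturbs another.
    """
    ss = np.random.SeedSequence(config.seed)
    r_panel, r_genome, r_lib, r_screen = [np.random.default_rng(c)
                                          for c in ss.spawn(4)]
    gmap = uniform_map(config)
    windows = build_windows(gmap, 0.2)
    panel = simulate_panel(config, r_panel, gmap)
    library, tss = simulate_guide_library(config, gmap, r_lib)
    specs = artifact_specs if artifact_specs is not None else [
        ArtifactSpec(*s) if not isinstance(s, ArtifactSpec) else s
        for s in config.injected_artifact_genes]
    artifact_truth = pd.DataFrame(
        columns=["gene", "guide_id", "variant_id", "position_from_pam"])
    if specs:
        panel, artifact_truth = inject_guide_variants(panel, library, specs)
    genotypes, truth = simulate_admixed_genomes(panel, gmap, config,
                                                r_genome, windows)
    truth.causal_artifact_table = artifact_truth
    truth.true_effects = pd.DataFrame(
        config.injected_true_dependency_effects,
        columns=["gene", "ancestry", "effect"]) \
        if config.injected_true_dependency_effects else pd.DataFrame(
            columns=["gene", "ancestry", "effect"])
    screen = simulate_screen(library, tss, genotypes, truth, config,
                             windows, gmap, r_screen)
    tgf = true_global_fractions(truth, windows, list(config.populations),
                                genotypes.samples)
    metadata = pd.DataFrame({
        "sample_id": genotypes.samples,
        "lineage": screen.lineage.to_numpy(),
        "true_global_ancestry": tgf.idxmax(axis=1).to_numpy(),
    }).set_index("sample_id")
    for p in config.populations:
        metadata[f"true_frac_{p}"] = tgf[p].to_numpy()
    return SimulatedCohort(config=config, gmap=gmap, windows=windows,
                           panel=panel, genotypes=genotypes, truth=truth,
                           library=library, tss=tss, screen=screen,
                           metadata=metadata)
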