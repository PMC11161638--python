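"""Shared fixtures: small synthetic cohorts and a sequence-anchored guide
fixture whose guides are cut from an explicit reference, so mapping results
can be checked against brute-force sequence reconstruction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from guidebias.config import SimConfig
from guidebias.simulate import ArtifactSpec, simulate_cohort

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_reference(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def guides_from_reference(ref: dict[str, str], rng: np.random.Generator,
                          n_guides: int) -> pd.DataFrame:
    """Sample valid NGG guide loci (both strands) from a reference."""
    rows = []
    chroms = list(ref)
    tries = 0
    while len(rows) < n_guides and tries < 100 * n_guides:
        tries += 1
        chrom = chroms[rng.integers(len(chroms))]
        seq = ref[chrom]
        start = int(rng.integers(0, len(seq) - 23))
        window = seq[start:start + 23]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+" and window[21:23] == "GG":
            proto, pam = window[:20], window[20:]
        elif strand == "-" and window[0:2] == "CC":
            rc = revcomp(window)
            proto, pam = rc[:20], rc[20:]
        else:
            continue
        gid = f"g{len(rows):05d}"
        rows.append((gid, f"GENE{len(rows) // 4:04d}", chrom, start,
                     start + 23, strand, proto, pam))
    assert len(rows) == n_guides, "reference too short for guide count"
    return pd.DataFrame(rows, columns=["guide_id", "gene", "chrom", "start",
                                       "end", "strand", "protospacer",
                                       "pam"])


def random_snvs(ref: dict[str, str], rng: np.random.Generator,
                n_snvs: int) -> pd.DataFrame:
    """Random SNVs with ref alleles taken from the reference sequence."""
    bases = "ACGT"
    rows, seen = [], set()
    chroms = list(ref)
    while len(rows) < n_snvs:
        chrom = chroms[rng.integers(len(chroms))]
        pos0 = int(rng.integers(0, len(ref[chrom])))
        if (chrom, pos0) in seen:
            continue
        seen.add((chrom, pos0))
        r = ref[chrom][pos0]
        alt = bases[(bases.index(r) + 1 + rng.integers(3)) % 4]
        rows.append((chrom, pos0, r, alt))
    var = pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt"])
    var = var.sort_values(["chrom", "pos0"]).reset_index(drop=True)
    var.index = pd.Index([f"{c}:{p + 1}:{r}:{a}" for c, p, r, a in
                          var.itertuples(index=False)], name="variant_id")
    return var


def oracle_map(ref: dict[str, str], library: pd.DataFrame,
               variants: pd.DataFrame) -> set[tuple]:
    """Brute-force mapping oracle by sequence reconstruction.

    For each (guide, variant) pair, rebuild the 23-bp targeting sequence
    from the reference, substitute the alternate allele on the '+' strand,
    and report any base change as (guide_id, variant_id, position_from_pam)
    with position counted from the PAM on the guide strand.
    """
    out = set()
    for g in library.itertuples(index=False):
        seq = ref[g.chrom]
        window = seq[g.start:g.end]
        for vid, v in variants.iterrows():
            if v["chrom"] != g.chrom or not g.start <= v["pos0"] < g.end:
                continue
            off = v["pos0"] - g.start
            mutated = window[:off] + v["alt"] + window[off + 1:]
            ts_ref = window if g.strand == "+" else revcomp(window)
            ts_mut = mutated if g.strand == "+" else revcomp(mutated)
            changed = [i for i in range(23) if ts_ref[i] != ts_mut[i]]
            assert len(changed) == 1
            out.add((g.guide_id, vid, 20 - changed[0]))
    return out


@pytest.fixture(scope="session")
def seq_fixture():
    """Reference + guides + SNVs anchored to the same sequences."""
    rng = np.random.default_rng(42)
    ref = {"chr1": random_reference(rng, 30_000),
           "chr2": random_reference(rng, 30_000)}
    library = guides_from_reference(ref, rng, 60)
    variants = random_snvs(ref, rng, 800)
    return ref, library, variants


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 60-sample, 2-population cohort with two artifacts."""
    q = np.zeros((60, 2))
    q[:30, 0] = 1.0
    q[30:, 1] = 1.0
    cfg = SimConfig(n_populations=2, fst=0.15, n_samples=60,
                    n_chromosomes=1, n_variants_per_chrom=2500,
                    cm_per_chrom=10.0, admixture_proportions=q,
                    n_genes=12, noise_sd=0.3, gene_effect_mean=-1.0,
                    gene_effect_sd=0.2, n_lineages=2, seed=11)
    specs = [ArtifactSpec("GENE0000", 0, 1, {"AFR": 0.8, "AMR": 0.02}),
             ArtifactSpec("GENE0001", 1, 5, {"AFR": 0.02, "AMR": 0.8})]
    return simulate_cohort(cfg, specs)
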