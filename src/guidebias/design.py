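"""Ancestry-aware guide selection.

Candidates per gene are ranked by a supplied on-target score.  Selection
drops candidates whose targeting interval carries a variant above an
overall population-frequency ceiling, and candidates whose per-individual
mismatch carrier rate in AFR exceeds a fixed multiple of the non-AFR rate
(carrier rates computed under Hardy-Weinberg from group allele
frequencies, since individual genotypes are unavailable at design time).
If fewer than the target number survive, the best excluded candidates fill
the remainder and the gene is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import InputError


@dataclass
class LibraryDesign:
    """Selected guides per gene plus selection diagnostics."""

    selected: pd.DataFrame  # candidate rows + [selected_rank, fallback]
    per_gene: pd.DataFrame  # gene, flags, mean scores pre/post constraints


def scan_pam_sites(seq: str, strand: str) -> list[int]:
    """0-based start offsets of PAM 3-mers on one strand of ``seq``.

    '+' sites read NGG in ``seq``; '-' sites read CCN in ``seq`` (NGG on
    the reverse complement, with the degenerate N at offset+2).
    """
    seq = seq.upper()
    out = []
    for i in range(len(seq) - 2):
        tri = seq[i:i + 3]
        if strand == "+" and tri[1:] == "GG":
            out.append(i)
        elif strand == "-" and tri[:2] == "CC":
            out.append(i)
    return out


def enumerate_pam_sites(sequences: dict[str, str],
                        regions: pd.DataFrame | None = None,
                        require_fit: bool = True,
                        sample_n: int | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> pd.DataFrame:
    """All candidate guide loci with a canonical NGG PAM, both strands.

    ``regions`` (columns chrom, start, end; 0-based half-open) restricts
    the scan; ``require_fit`` additionally demands that the full 23-bp
    targeting interval fits inside the region.  With ``sample_n`` a seeded
    random subsample is returned.

    The returned table has [chrom, pam_start, strand, start, end] where
    start/end is the targeting interval.
    """
    rows = []
    if regions is None:
        regions = pd.DataFrame(
            [(c, 0, len(s)) for c, s in sequences.items()],
            columns=["chrom", "start", "end"])
    for chrom, r_start, r_end in regions[["chrom", "start", "end"]] \
            .itertuples(index=False):
        seq = sequences[chrom]
        if r_end > len(seq) or r_start < 0:
            raise InputError(f"region beyond end of {chrom}")
        sub = seq[r_start:r_end]
        for strand in "+-":
            for off in scan_pam_sites(sub, strand):
                pam_start = r_start + off
                if strand == "+":
                    start, end = pam_start - 20, pam_start + 3
                else:
                    start, end = pam_start, pam_start + 23
                if require_fit and not (r_start <= start and end <= r_end):
                    continue
                rows.append((chrom, pam_start, strand, start, end))
    sites = pd.DataFrame(rows, columns=["chrom", "pam_start", "strand",
                                        "start", "end"])
    if sample_n is not None and len(sites) > sample_n:
        rng = rng or np.random.default_rng()
        keep = np.sort(rng.choice(len(sites), size=sample_n, replace=False))
        sites = sites.iloc[keep].reset_index(drop=True)
    return sites


def carrier_rate(freqs: np.ndarray) -> float:
    """P(individual carries >= 1 alt allele over the guide's variants).

    Hardy-Weinberg and independence across variants: 1 - prod (1-f)^2.
    """
    freqs = np.asarray(freqs, dtype=float)
    return float(1.0 - np.prod((1.0 - freqs) ** 2))


def _candidate_flags(cand: pd.DataFrame, maf_threshold: float,
                     afr_ratio_max: float, afr_rate_floor: float,
                     ) -> pd.DataFrame:
    """Add violates_maf / violates_afr columns to a candidate table.

    ``cand`` needs a ``variants`` column: a list per row of dicts with keys
    ``freq_all``, ``freq_AFR``, ``freq_nonAFR``.
    """
    v_maf, v_afr, afr_rates, non_rates = [], [], [], []
    for variants in cand["variants"]:
        variants = variants or []
        v_maf.append(any(v["freq_all"] > maf_threshold for v in variants))
        r_afr = carrier_rate([v["freq_AFR"] for v in variants])
        r_non = carrier_rate([v["freq_nonAFR"] for v in variants])
        afr_rates.append(r_afr)
        non_rates.append(r_non)
        v_afr.append(r_afr > afr_rate_floor and r_afr > afr_ratio_max * r_non)
    out = cand.copy()
    out["violates_maf"] = v_maf
    out["violates_afr"] = v_afr
    out["carrier_rate_AFR"] = afr_rates
    out["carrier_rate_nonAFR"] = non_rates
    return out


def design_library(candidates: pd.DataFrame, maf_threshold: float = 0.01,
                   afr_ratio_max: float = 2.5, afr_rate_floor: float = 1e-4,
                   guides_per_gene: int = 4,
                   apply_constraints: bool = True) -> LibraryDesign:
    """Select the top-scoring constraint-satisfying guides per gene.

    ``candidates`` needs columns [gene, guide_id, on_target_score,
    variants] (see :func:`_candidate_flags` for the variant payload).
    """
    required = {"gene", "guide_id", "on_target_score", "variants"}
    missing = required - set(candidates.columns)
    if missing:
        raise InputError(f"candidate table lacks columns: {sorted(missing)}")
    flagged = _candidate_flags(candidates, maf_threshold, afr_ratio_max,
                               afr_rate_floor)
    selected_rows, gene_rows = [], []
    for gene, grp in flagged.groupby("gene", sort=True):
        grp = grp.sort_values(["on_target_score", "guide_id"],
                              ascending=[False, True], kind="mergesort")
        if grp.empty:
            raise InputError(f"gene {gene} has no candidates")
        top_unconstrained = grp.head(guides_per_gene)
        if apply_constraints:
            ok = grp[~(grp["violates_maf"] | grp["violates_afr"])]
        else:
            ok = grp
        picked = ok.head(guides_per_gene).copy()
        picked["fallback"] = False
        fallback_used = False
        if len(picked) < guides_per_gene:
            fallback_used = True
            fill = grp[~grp["guide_id"].isin(picked["guide_id"])] \
                .head(guides_per_gene - len(picked)).copy()
            fill["fallback"] = True
            picked = pd.concat([picked, fill])
        picked = picked.assign(
            selected_rank=np.arange(1, len(picked) + 1))
        identical = set(picked["guide_id"]) == \
            set(top_unconstrained["guide_id"])
        selected_rows.append(picked)
        gene_rows.append((gene, identical, fallback_used,
                          float(top_unconstrained["on_target_score"].mean()),
                          float(picked["on_target_score"].mean())))
    selected = pd.concat(selected_rows, ignore_index=True)
    per_gene = pd.DataFrame(gene_rows, columns=[
        "gene", "unconstrained_top4_identical", "fallback_used",
        "mean_score_unconstrained", "mean_score_selected"])
    return LibraryDesign(selected=selected, per_gene=per_gene)


def design_quality_benchmark(design: LibraryDesign,
                             candidates: pd.DataFrame) -> dict:
    """Mean on-target score deltas: constrained selection vs top-4.

    Reported overall and restricted to genes with at least one
    variant-carrying candidate.
    """
    pg = design.per_gene
    delta = pg["mean_score_selected"] - pg["mean_score_unconstrained"]
    has_var = candidates.assign(
        hit=[bool(v) for v in candidates["variants"]]) \
        .groupby("gene")["hit"].any()
    restricted = delta[pg["gene"].map(has_var).fillna(False).to_numpy()]
    return {
        "mean_delta_all": float(delta.mean()),
        "mean_delta_variant_genes": float(restricted.mean())
        if len(restricted) else float("nan"),
        "per_gene_delta": pd.Series(delta.to_numpy(),
                                    index=pg["gene"]).to_dict(),
    }
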