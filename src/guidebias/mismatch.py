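"""Mapping variants onto sgRNA targeting sequences and quantifying burden.

A guide's targeting sequence is the 23-bp genomic interval spanning the
20-nt protospacer plus the NGG PAM.  Positions are counted from the PAM:
protospacer base adjacent to the PAM is position 1, the PAM-distal base is
position 20; the PAM bases N/G/G get positions 0/-1/-2.  On the reference
'+' strand a '-'-strand guide's PAM reads CCN, with the degenerate N at the
third base of the interval.

Variants falling on the degenerate PAM "N" base are always *recorded*
(position 0) but excluded by default from affected-guide counts, since an N
mismatch cannot disrupt NGG recognition; ``include_pam_n=True`` restores the
literal 23-bp definition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import InputError
from .types import VariantGenotypes, validate_guide_table

MISMATCH_COLUMNS = ["guide_id", "sample", "variant_id", "chrom", "pos0",
                    "ref", "alt", "position_from_pam", "zygosity"]


def targeting_interval(guide: pd.Series) -> tuple[int, int]:
    """Validated 0-based half-open targeting interval of one guide record."""
    if guide["strand"] not in ("+", "-"):
        raise InputError(f"bad strand {guide['strand']!r}")
    if len(guide["protospacer"]) != 20:
        raise InputError("protospacer must be 20 nt")
    if len(guide["pam"]) != 3 or guide["pam"][1:] != "GG":
        raise InputError("PAM must match NGG on the guide strand")
    start = int(guide["start"])
    if start < 0:
        raise InputError("interval before chromosome start")
    return start, start + 23


def position_from_pam(start: int, strand: str, pos0: int) -> int | None:
    """Position of genomic ``pos0`` counted from the PAM, or None if outside.

    Returns 1..20 for protospacer bases (1 = PAM-proximal) and 0/-1/-2 for
    the PAM N/G/G bases.
    """
    off = pos0 - start
    if not 0 <= off < 23:
        return None
    if strand == "+":
        return 20 - off  # off 19 -> 1, off 20 -> 0 (N), off 22 -> -2
    return off - 2       # off 3 -> 1, off 2 -> 0 (N), off 0 -> -2


def map_variant_guide_overlaps(variants: pd.DataFrame,
                               library: pd.DataFrame) -> pd.DataFrame:
    """Coordinate-level (guide, variant) overlap table with PAM positions."""
    validate_guide_table(library)
    lib_chroms = set(library["chrom"])
    var_chroms = set(variants["chrom"])
    rows = []
    for chrom in sorted(lib_chroms & var_chroms):
        lib = library[library["chrom"] == chrom].sort_values("start")
        starts = lib["start"].to_numpy()
        var = variants[variants["chrom"] == chrom]
        pos = var["pos0"].to_numpy()
        lo = np.searchsorted(starts, pos - 22, side="left")
        hi = np.searchsorted(starts, pos, side="right")
        for vi, (l, h) in enumerate(zip(lo, hi)):
            for gi in range(l, h):
                g = lib.iloc[gi]
                p = position_from_pam(int(g["start"]), g["strand"],
                                      int(pos[vi]))
                if p is None:
                    continue
                v = var.iloc[vi]
                rows.append((g["guide_id"], var.index[vi], chrom,
                             int(pos[vi]), v["ref"], v["alt"], p))
    return pd.DataFrame(rows, columns=["guide_id", "variant_id", "chrom",
                                       "pos0", "ref", "alt",
                                       "position_from_pam"])


def map_variants_to_guides(genotypes: VariantGenotypes,
                           library: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mismatch records for every carried in-guide variant.

    A record is emitted for every (sample, guide, variant) where the sample
    carries at least one alternate allele (dosage >= 1) at a position inside
    the guide's targeting interval.  Missing genotypes produce no record.
    """
    if not set(library["chrom"]) & set(genotypes.variants["chrom"]):
        raise InputError(
            "no shared chromosome names between library "
            f"({sorted(set(library['chrom']))[:3]}...) and variants")
    overlaps = map_variant_guide_overlaps(genotypes.variants, library)
    if overlaps.empty:
        return pd.DataFrame(columns=MISMATCH_COLUMNS)
    rows = []
    dos = genotypes.dosages
    for rec in overlaps.itertuples(index=False):
        d = dos[rec.variant_id]
        carriers = d[d >= 1]
        for sample, dv in carriers.items():
            zyg = "hom" if dv >= 2 else "het"
            rows.append((rec.guide_id, sample, rec.variant_id, rec.chrom,
                         rec.pos0, rec.ref, rec.alt, rec.position_from_pam,
                         zyg))
    return pd.DataFrame(rows, columns=MISMATCH_COLUMNS)


def map_variant_table(variant_table: pd.DataFrame,
                      library: pd.DataFrame) -> pd.DataFrame:
    """Map a generic per-sample variant table (e.g. somatic calls).

    ``variant_table`` needs columns [chrom, pos0, ref, alt, sample]; every
    listed variant counts as present in its sample (zygosity "het" unless a
    ``zygosity`` column is supplied).
    """
    var = variant_table.reset_index(drop=True)
    uniq = var[["chrom", "pos0", "ref", "alt"]].drop_duplicates()
    uniq.index = pd.Index([f"{c}:{p + 1}:{r}:{a}" for c, p, r, a in
                           uniq.itertuples(index=False)], name="variant_id")
    overlaps = map_variant_guide_overlaps(uniq, library)
    key = var["chrom"].astype(str) + ":" + (var["pos0"] + 1).astype(str) \
        + ":" + var["ref"] + ":" + var["alt"]
    var = var.assign(variant_id=key)
    merged = overlaps.merge(var[["variant_id", "sample"] +
                                (["zygosity"] if "zygosity" in var else [])],
                            on="variant_id")
    if "zygosity" not in merged:
        merged["zygosity"] = "het"
    return merged[MISMATCH_COLUMNS]


def affected_records(table: pd.DataFrame,
                     include_pam_n: bool = False) -> pd.DataFrame:
    """Records that count toward affected-guide statistics."""
    if table.empty or include_pam_n:
        return table
    return table[table["position_from_pam"] != 0]


def per_sample_affected_fraction(table: pd.DataFrame, library: pd.DataFrame,
                                 samples: pd.Index,
                                 include_pam_n: bool = False) -> pd.Series:
    """Fraction of library guides with >= 1 mismatch record per sample."""
    tab = affected_records(table, include_pam_n)
    n_guides = library["guide_id"].nunique()
    counts = tab.groupby("sample")["guide_id"].nunique() if len(tab) else \
        pd.Series(dtype=int)
    return counts.reindex(samples, fill_value=0) / n_guides


def guides_affected_in_k_samples(table: pd.DataFrame, k: int = 10,
                                 include_pam_n: bool = False) -> pd.Index:
    """Guides whose targeting sequence has a variant in >= k samples."""
    tab = affected_records(table, include_pam_n)
    if tab.empty:
        return pd.Index([], name="guide_id")
    counts = tab.groupby("guide_id")["sample"].nunique()
    return counts.index[counts >= k]


def per_gene_affected_guide_histogram(table: pd.DataFrame,
                                      library: pd.DataFrame,
                                      include_pam_n: bool = False,
                                      ) -> pd.Series:
    """Histogram over genes of the number of guides hit in >= 1 sample."""
    tab = affected_records(table, include_pam_n)
    guides_per_gene = int(library.groupby("gene")["guide_id"].nunique().max())
    hit_guides = set(tab["guide_id"]) if len(tab) else set()
    per_gene = library.assign(hit=library["guide_id"].isin(hit_guides)) \
        .groupby("gene")["hit"].sum()
    hist = per_gene.value_counts().reindex(range(guides_per_gene + 1),
                                           fill_value=0).sort_index()
    hist.name = "n_genes"
    return hist


def guide_variant_depletion_test(lfc: pd.Series, presence: pd.Series,
                                 min_per_class: int = 3,
                                 ) -> tuple[float, float, bool]:
    """Welch t-test of guide LFC between carriers and non-carriers.

    Returns (effect, p, protective); effect = mean(carriers) - mean(rest),
    protective when positive (carriers less depleted).  Degenerate classes
    give (nan, nan, False).
    """
    presence = presence.reindex(lfc.index).fillna(False).astype(bool)
    a = lfc[presence].dropna()
    b = lfc[~presence].dropna()
    if len(a) < min_per_class or len(b) < min_per_class:
        return float("nan"), float("nan"), False
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return float(a.mean() - b.mean()), float("nan"), False
    t = stats.ttest_ind(a, b, equal_var=False)
    effect = float(a.mean() - b.mean())
    return effect, float(t.pvalue), effect > 0


def snp_guide_enrichment(depletion_diff: pd.Series, snp_flag: pd.Series,
                         diff_threshold: float = 0.25,
                         ) -> tuple[float, float, pd.DataFrame]:
    """Fisher test: differential depletion between groups vs SNP-in-guide.

    ``depletion_diff`` holds per-guide group-mean LFC differences (e.g.
    EAS minus EUR); a guide is "differential" when |diff| exceeds the
    threshold.  Returns (odds_ratio, p, 2x2 table).
    """
    snp_flag = snp_flag.reindex(depletion_diff.index).fillna(False)
    differential = depletion_diff.abs() > diff_threshold
    table = pd.crosstab(differential, snp_flag) \
        .reindex(index=[True, False], columns=[True, False], fill_value=0)
    if (table.to_numpy().sum(axis=0) == 0).any() or \
            (table.to_numpy().sum(axis=1) == 0).any():
        return float("nan"), float("nan"), table
    odds, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return float(odds), float(p), table


def positional_effects(table: pd.DataFrame, guide_lfc: pd.DataFrame,
                       include_pam: bool = False,
                       include_pam_n: bool = False) -> pd.DataFrame:
    """Per-position mismatch effect on guide depletion.

    For each position, (guide, sample) pairs carrying a mismatch at that
    position are compared with pairs on the same guides carrying no
    mismatch at all; the effect is the mean LFC difference (positive =
    protective) with Welch-t and Wilcoxon rank-sum p-values.
    """
    tab = affected_records(table, include_pam_n)
    positions = sorted(p for p in tab["position_from_pam"].unique()
                       if include_pam or 1 <= p <= 20)
    clean = _clean_pairs(tab, guide_lfc)
    rows = []
    for p in positions:
        sub = tab[tab["position_from_pam"] == p]
        case = _pair_values(sub, guide_lfc)
        ctrl_guides = sub["guide_id"].unique()
        ctrl = np.concatenate([clean[g] for g in ctrl_guides
                               if g in clean and clean[g].size])
        if case.size == 0 or ctrl.size == 0:
            continue
        effect = float(case.mean() - ctrl.mean())
        if case.size < 2 or ctrl.size < 2:
            p_t = p_w = float("nan")
        else:
            p_t = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
            p_w = float(stats.mannwhitneyu(case, ctrl,
                                           alternative="two-sided").pvalue)
        rows.append((int(p), case.size, ctrl.size, effect, p_t, p_w))
    return pd.DataFrame(rows, columns=["position", "n_mismatch_pairs",
                                       "n_clean_pairs", "effect",
                                       "p_ttest", "p_wilcoxon"])


def _clean_pairs(table: pd.DataFrame,
                 guide_lfc: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per guide, LFC values of samples with no mismatch on that guide."""
    hit = table.groupby("guide_id")["sample"].agg(set) if len(table) else {}
    out = {}
    for g in (table["guide_id"].unique() if len(table) else []):
        if g not in guide_lfc.columns:
            continue
        col = guide_lfc[g]
        mask = ~col.index.isin(list(hit.get(g, set())))
        out[g] = col[mask].dropna().to_numpy()
    return out


def _pair_values(sub: pd.DataFrame, guide_lfc: pd.DataFrame) -> np.ndarray:
    vals = []
    for g, s in sub[["guide_id", "sample"]].drop_duplicates() \
            .itertuples(index=False):
        if g in guide_lfc.columns and s in guide_lfc.index:
            v = guide_lfc.at[s, g]
            if np.isfinite(v):
                vals.append(v)
    return np.asarray(vals, dtype=float)


def afr_burden_ratio(fractions: pd.Series, labels: pd.Series,
                     group: str = "AFR") -> float:
    """Ratio of median affected-guide fraction: ``group`` vs everyone else."""
    labels = labels.reindex(fractions.index)
    in_g = fractions[labels == group]
    out_g = fractions[labels != group]
    if in_g.empty or out_g.empty:
        raise InputError("both groups must be non-empty")
    denom = float(out_g.median())
    if denom == 0:
        return float("nan")
    return float(in_g.median()) / denom
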