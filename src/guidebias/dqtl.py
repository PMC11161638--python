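"""Dependency-QTL scanning and marker characterisation.

Each flagged gene dependency is regressed genome-wide on SNP dosage
(additive coding) with lineage fixed effects; per-gene families are
corrected with Benjamini-Yekutieli and the variant with the lowest q is the
marker d-QTL.  Markers are then classified by ancestry-differential allele
frequency, by distance to the gene TSS (proximal < 1 Mb, strict), and
tested for expression association under presence/absence coding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_qvalues, by_qvalues, lineage_design, ols_scan
from .config import InputError
from .types import VariantGenotypes

#: groups entering the differential-frequency rule (small groups excluded)
DIFFERENTIAL_GROUPS = ("AFR", "EAS", "EUR", "Admixed")


def filter_by_maf(genotypes: VariantGenotypes,
                  min_maf: float = 0.01) -> VariantGenotypes:
    """Keep variants with minor allele frequency strictly above ``min_maf``."""
    f = genotypes.allele_frequencies()
    maf = np.minimum(f, 1 - f)
    keep = maf[maf > min_maf].index
    if len(keep) == 0:
        import warnings
        warnings.warn("MAF filter removed every variant")
    return genotypes.subset_variants(keep)


def dqtl_scan(dependency: pd.Series, genotypes: VariantGenotypes,
              lineage: pd.Series, fdr_q: float = 0.05,
              min_samples: int = 10) -> pd.DataFrame:
    """Genome-wide per-variant OLS scan for one gene's dependency.

    Returns a table [variant_id, chrom, pos0, beta, p, q_bh, q_by,
    significant] over the tested variants; constant-dosage variants are
    skipped.  The BY family is all variants tested for this gene.
    """
    samples = dependency.dropna().index.intersection(genotypes.samples)
    if len(samples) < min_samples:
        raise InputError(
            f"need >= {min_samples} samples with dependency and genotypes")
    y = dependency.loc[samples].to_numpy()
    D = genotypes.dosages.loc[samples]
    C = lineage_design(lineage.loc[samples])

    dmat = D.to_numpy(dtype=float)
    full = ~np.isnan(dmat).any(axis=0)
    beta = np.full(dmat.shape[1], np.nan)
    pval = np.full(dmat.shape[1], np.nan)
    if full.any():
        b, _, p = ols_scan(y, dmat[:, full], C)
        beta[full] = b
        pval[full] = p
    for j in np.flatnonzero(~full):  # casewise deletion per variant
        d = dmat[:, j]
        ok = ~np.isnan(d)
        if ok.sum() < min_samples:
            continue
        b, _, p = ols_scan(y[ok], d[ok, None], C[ok])
        beta[j], pval[j] = b[0], p[0]

    res = pd.DataFrame({
        "variant_id": genotypes.variants.index,
        "chrom": genotypes.variants["chrom"].to_numpy(),
        "pos0": genotypes.variants["pos0"].to_numpy(),
        "beta": beta,
        "p": pval,
    })
    res = res[np.isfinite(res["p"])].reset_index(drop=True)
    res["q_bh"] = bh_qvalues(res["p"].to_numpy())
    res["q"] = by_qvalues(res["p"].to_numpy())
    res["significant"] = res["q"] < fdr_q
    return res


def select_marker(results: pd.DataFrame,
                  require_significant: bool = True) -> pd.Series | None:
    """The marker d-QTL: lowest q, ties by raw p then genomic order."""
    if results.empty:
        return None
    pool = results[results["significant"]] if require_significant else results
    if pool.empty:
        return None
    pool = pool.sort_values(["q", "p", "chrom", "pos0"], kind="mergesort")
    return pool.iloc[0]


def ancestry_maf(variant_id: str, genotypes: VariantGenotypes,
                 ancestry_labels: pd.Series, differential_maf: float = 0.2,
                 groups: tuple[str, ...] = DIFFERENTIAL_GROUPS,
                 ) -> tuple[pd.Series, float, bool]:
    """Per-group allele frequency of one variant and the differential rule.

    Returns (per-group frequencies incl. "ALL", max-min differential over
    the included groups with >= 1 sample, flag differential > threshold).
    """
    d = genotypes.dosages[variant_id]
    labels = ancestry_labels.reindex(d.index)
    freqs = {}
    for g in groups:
        sub = d[labels == g].dropna()
        freqs[g] = float(sub.mean() / 2.0) if len(sub) else np.nan
    freqs["ALL"] = float(d.dropna().mean() / 2.0)
    series = pd.Series(freqs)
    grp_vals = series.drop("ALL").dropna()
    if grp_vals.empty:
        return series, np.nan, False
    differential = float(grp_vals.max() - grp_vals.min())
    return series, differential, differential > differential_maf


def classify_proximal(marker_chrom: str, marker_pos0: int, tss_chrom: str,
                      tss0: int, proximal_bp: int = 1_000_000,
                      ) -> tuple[bool, float]:
    """Proximal iff same chromosome and |marker - TSS| < proximal_bp.

    Returns (proximal, distance); distance is +inf across chromosomes.
    """
    if marker_chrom != tss_chrom:
        return False, float("inf")
    dist = abs(int(marker_pos0) - int(tss0))
    return dist < proximal_bp, float(dist)


def eqtl_test(variant_id: str, genotypes: VariantGenotypes,
              expression: pd.Series, lineage: pd.Series,
              min_per_class: int = 2) -> dict | None:
    """Expression vs variant presence (het or hom alt) with lineage effects.

    Dosages 1 and 2 collapse into one carrier class.  Returns a dict with
    beta and p, or None when either class is too small.
    """
    d = genotypes.dosages[variant_id]
    common = expression.dropna().index.intersection(d.dropna().index)
    d = d.loc[common]
    presence = (d >= 1).astype(float)
    if (presence == 1).sum() < min_per_class or \
            (presence == 0).sum() < min_per_class:
        return None
    C = lineage_design(lineage.loc[common])
    beta, _, p = ols_scan(expression.loc[common].to_numpy(),
                          presence.to_numpy()[:, None], C)
    return {"variant_id": variant_id, "beta": float(beta[0]),
            "p": float(p[0]), "n_present": int((presence == 1).sum()),
            "n_absent": int((presence == 0).sum())}


def ld_r2(dosage_a: pd.Series | np.ndarray,
          dosage_b: pd.Series | np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of unphased dosages."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise InputError("need >= 2 paired non-missing samples")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def weak_expression_fraction(expression: pd.DataFrame,
                             threshold_rpm: float = 5.0,
                             ) -> tuple[pd.Series, float]:
    """Genes whose median expression (RPM) is strictly below the threshold.

    Returns (per-gene flag, fraction of genes flagged).
    """
    med = expression.median(axis=0, skipna=True)
    flags = med < threshold_rpm
    return flags, float(flags.mean()) if len(flags) else float("nan")


def scan_genes(dep_matrix: pd.DataFrame, genes: list[str],
               genotypes: VariantGenotypes, lineage: pd.Series,
               ancestry_labels: pd.Series, tss: pd.DataFrame,
               fdr_q: float = 0.05, differential_maf: float = 0.2,
               proximal_bp: int = 1_000_000) -> pd.DataFrame:
    """Marker d-QTL table for a list of genes (one row per gene).

    Emits both the significance-gated marker and the strongest association
    overall (``marker_significant`` distinguishes the two situations).
    """
    tss_ix = tss.set_index("gene")
    rows = []
    for gene in genes:
        res = dqtl_scan(dep_matrix[gene], genotypes, lineage, fdr_q)
        marker = select_marker(res, require_significant=True)
        strongest = select_marker(res, require_significant=False)
        chosen = marker if marker is not None else strongest
        if chosen is None:
            continue
        freqs, diff, anc_flag = ancestry_maf(
            chosen["variant_id"], genotypes, ancestry_labels,
            differential_maf)
        row = {"gene": gene, "variant_id": chosen["variant_id"],
               "chrom": chosen["chrom"], "pos0": int(chosen["pos0"]),
               "beta": chosen["beta"], "p": chosen["p"], "q": chosen["q"],
               "marker_significant": marker is not None,
               "n_significant": int(res["significant"].sum()),
               "differential_maf": diff, "ancestry_associated": anc_flag}
        for g, f in freqs.items():
            row[f"freq_{g}"] = f
        if gene in tss_ix.index:
            prox, dist = classify_proximal(
                chosen["chrom"], int(chosen["pos0"]),
                tss_ix.loc[gene, "chrom"], int(tss_ix.loc[gene, "tss0"]),
                proximal_bp)
            row["proximal"] = prox
            row["distance_to_tss"] = dist
        rows.append(row)
    return pd.DataFrame(rows)
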