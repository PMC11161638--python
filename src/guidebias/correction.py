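"""Per-cell-line guide exclusion and pre/post correction comparison.

Guides carrying a mismatch in a given sample are dropped from that sample's
gene-level aggregation only; samples without mismatches reproduce the
uncorrected score exactly.  Gene aggregation is an unweighted mean of guide
log-fold-changes (median available), a simple documented aggregator in
place of a full screen-modelling pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues
from .config import InputError
from .mismatch import affected_records
from .association import test_all_groups
from .types import ScreenData


def aggregate_gene_scores(guide_lfc: pd.DataFrame, library: pd.DataFrame,
                          aggregator: str = "mean") -> pd.DataFrame:
    """Uncorrected gene-level matrix: per-gene aggregate of guide LFCs."""
    gene_of = library.set_index("guide_id")["gene"]
    grouped = guide_lfc.T.groupby(gene_of.reindex(guide_lfc.columns))
    agg = grouped.median().T if aggregator == "median" else grouped.mean().T
    return agg


def correct_gene_scores(guide_lfc: pd.DataFrame, library: pd.DataFrame,
                        mismatch_table: pd.DataFrame,
                        aggregator: str = "mean",
                        include_pam_n: bool = False) -> pd.DataFrame:
    """Gene scores with per-sample exclusion of mismatched guides.

    A (sample, gene) cell where every guide is excluded becomes missing.
    """
    genes = library.groupby("gene")["guide_id"].nunique()
    if (genes == 0).any():
        raise InputError("gene with zero guides")
    masked = guide_lfc.copy()
    tab = affected_records(mismatch_table, include_pam_n)
    if len(tab):
        pairs = tab[["sample", "guide_id"]].drop_duplicates()
        pairs = pairs[pairs["guide_id"].isin(masked.columns) &
                      pairs["sample"].isin(masked.index)]
        s_idx = masked.index.get_indexer(pairs["sample"])
        g_idx = masked.columns.get_indexer(pairs["guide_id"])
        vals = masked.to_numpy(copy=True)
        vals[s_idx, g_idx] = np.nan
        masked = pd.DataFrame(vals, index=masked.index,
                              columns=masked.columns)
    return aggregate_gene_scores(masked, library, aggregator)


def pre_post_differential(dep_pre: pd.DataFrame, dep_post: pd.DataFrame,
                          fdr_q: float = 0.05,
                          min_pairs: int = 3) -> pd.DataFrame:
    """Paired t-test per gene on pre-minus-post differences, BH across genes.

    Genes identical pre/post (all differences zero) are reported with
    delta 0 and missing p and never count as discoveries.
    """
    genes = dep_pre.columns.intersection(dep_post.columns)
    samples = dep_pre.index.intersection(dep_post.index)
    rows = []
    for gene in genes:
        a = dep_pre.loc[samples, gene]
        b = dep_post.loc[samples, gene]
        ok = a.notna() & b.notna()
        if ok.sum() < min_pairs:
            rows.append((gene, np.nan, np.nan, int(ok.sum())))
            continue
        diff = (b[ok] - a[ok]).to_numpy()
        delta = float(diff.mean())
        if np.allclose(diff, diff[0]) and diff[0] == 0:
            rows.append((gene, 0.0, np.nan, int(ok.sum())))
            continue
        if np.std(diff, ddof=1) == 0:
            rows.append((gene, delta, np.nan, int(ok.sum())))
            continue
        p = float(stats.ttest_rel(b[ok], a[ok]).pvalue)
        rows.append((gene, delta, p, int(ok.sum())))
    res = pd.DataFrame(rows, columns=["gene", "delta", "p", "n_pairs"])
    res["q"] = bh_qvalues(res["p"].to_numpy()) if len(res) else []
    res["significant"] = res["q"] < fdr_q
    return res


def rerun_association_post_correction(screen: ScreenData,
                                      corrected: pd.DataFrame,
                                      labels: pd.DataFrame,
                                      groups: list[str],
                                      fdr_q: float = 0.05) -> pd.DataFrame:
    """Ancestry association pre vs post correction, paired per (gene, group).

    Returns the pre table joined with post columns (suffix ``_post``).
    """
    pre = test_all_groups(screen, labels, groups, fdr_q)
    post_screen = ScreenData(guide_lfc=screen.guide_lfc,
                             gene_dependency=corrected,
                             lineage=screen.lineage)
    post = test_all_groups(post_screen, labels, groups, fdr_q)
    merged = pre.merge(post, on=["gene", "group"], how="outer",
                       suffixes=("", "_post"))
    return merged
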