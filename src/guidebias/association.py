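"""Ancestry-dependency association and statistical power.

For each gene, samples are binned by their local ancestry at the gene's
transcription start site; dependency is regressed on a one-vs-rest group
indicator with cancer-lineage fixed effects, and Benjamini-Hochberg FDR is
applied per ancestry group across genes.  Power against a given group
imbalance is estimated by Monte-Carlo simulation of the same regression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, lineage_design, ols_scan, residualize
from .ancestry import WindowSet, _labels_at_window
from .config import InputError
from .types import GeneticMap, GlobalAncestry, LocalAncestryTrack, ScreenData

logger = logging.getLogger(__name__)


def bin_samples_by_locus_ancestry(tss: pd.DataFrame,
                                  track: LocalAncestryTrack,
                                  windows: WindowSet, gmap: GeneticMap,
                                  glob: GlobalAncestry) -> pd.DataFrame:
    """sample x gene matrix of single-label ancestry at each gene's TSS.

    Genes whose TSS is not covered by the genetic map are skipped with a
    warning and omitted from the returned columns.
    """
    cols = {}
    for gene, chrom, tss0 in tss[["gene", "chrom", "tss0"]] \
            .itertuples(index=False):
        try:
            w = windows.locate(gmap, chrom, int(tss0))
        except InputError as exc:
            logger.warning("gene %s skipped: %s", gene, exc)
            continue
        cols[gene] = _labels_at_window(track, glob, w)
    return pd.DataFrame(cols, index=track.samples)


def test_ancestry_dependency(screen: ScreenData, labels: pd.DataFrame,
                             group: str, fdr_q: float = 0.05,
                             min_group: int = 2) -> pd.DataFrame:
    """One-vs-rest OLS of dependency on locus-ancestry group membership.

    Returns a per-gene table [gene, group, beta, p, q, n_in, n_out,
    significant]; the BH family is the set of genes tested for this group.
    Genes where the indicator is confounded with lineage come back with
    missing p and are excluded from the family.
    """
    genes = [g for g in screen.gene_dependency.columns if g in labels.columns]
    rows = []
    for gene in genes:
        y = screen.gene_dependency[gene]
        lab = labels[gene]
        ok = y.notna() & lab.notna()
        n_in = int(((lab == group) & ok).sum())
        n_out = int(((lab != group) & ok).sum())
        if n_in < min_group or n_out < min_group:
            logger.warning("gene %s: group %s has too few samples "
                           "(%d vs %d)", gene, group, n_in, n_out)
            continue
        C = lineage_design(screen.lineage[ok])
        x = (lab[ok] == group).to_numpy(dtype=float)
        beta, _, p = ols_scan(y[ok].to_numpy(), x[:, None], C)
        rows.append((gene, group, float(beta[0]), float(p[0]), n_in, n_out))
    res = pd.DataFrame(rows, columns=["gene", "group", "beta", "p",
                                      "n_in", "n_out"])
    res["q"] = bh_qvalues(res["p"].to_numpy()) if len(res) else []
    res["significant"] = res["q"] < fdr_q
    return res


def test_all_groups(screen: ScreenData, labels: pd.DataFrame,
                    groups: list[str], fdr_q: float = 0.05) -> pd.DataFrame:
    """Run the one-vs-rest test for every ancestry group and concatenate."""
    parts = [test_ancestry_dependency(screen, labels, g, fdr_q)
             for g in groups]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=["gene", "group", "beta", "p", "n_in",
                                     "n_out", "q", "significant"])
    return pd.concat(parts, ignore_index=True)


def power_simulation(n_by_group: dict[str, int],
                     effect_grid: np.ndarray | None = None,
                     reps: int = 1000, alpha: float = 0.05,
                     lineage_freqs: dict[str, float] | None = None,
                     noise_sd: float = 1.0,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Monte-Carlo power of the lineage-adjusted one-vs-rest regression.

    For each group and effect size delta, group members draw scores
    Normal(delta, noise_sd^2) and everyone else Normal(0, noise_sd^2);
    lineage labels are drawn from ``lineage_freqs`` per replicate and enter
    the test (not the generating model) as fixed effects.  Power is the
    fraction of replicates with p < alpha.  Groups with fewer than 2
    members get missing power.
    """
    if reps < 100:
        raise InputError("need at least 100 replicates")
    if effect_grid is None:
        effect_grid = np.round(np.arange(0.0, 1.01, 0.01), 2)
    effect_grid = np.asarray(effect_grid, dtype=float)
    rng = rng or np.random.default_rng()
    n_total = int(sum(n_by_group.values()))
    lineages = list(lineage_freqs) if lineage_freqs else ["L0"]
    lin_p = np.array([lineage_freqs[l] for l in lineages]) \
        if lineage_freqs else np.array([1.0])
    lin_p = lin_p / lin_p.sum()

    rows = []
    for group, n_g in n_by_group.items():
        if n_g < 2:
            for delta in effect_grid:
                rows.append((group, n_g, float(delta), np.nan))
            continue
        x = np.zeros(n_total)
        x[:n_g] = 1.0
        hits = np.zeros(effect_grid.size)
        for _ in range(reps):
            lin = rng.choice(len(lineages), size=n_total, p=lin_p)
            C = np.ones((n_total, len(lineages)))
            for j in range(1, len(lineages)):
                C[:, j] = lin == j
            y0 = rng.normal(0.0, noise_sd, size=n_total)
            res, rank = residualize(np.column_stack([x, y0]), C)
            rx, ry0 = res[:, 0], res[:, 1]
            sxx = float(rx @ rx)
            df = n_total - rank - 1
            if sxx <= 1e-12 or df <= 0:
                continue  # group confounded with lineage this draw
            sxy0 = float(rx @ ry0)
            syy0 = float(ry0 @ ry0)
            # y(delta) = y0 + delta * x, so every delta shares one fit
            beta = (sxy0 + effect_grid * sxx) / sxx
            syy = syy0 + 2 * effect_grid * sxy0 + effect_grid ** 2 * sxx
            rss = np.maximum(syy - beta ** 2 * sxx, 0.0)
            tstat = beta / np.sqrt(rss / df / sxx)
            pvals = 2 * stats.t.sf(np.abs(tstat), df)
            hits += pvals < alpha
        for delta, h in zip(effect_grid, hits):
            rows.append((group, n_g, float(delta), h / reps))
    return pd.DataFrame(rows, columns=["group", "n", "effect", "power"])
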