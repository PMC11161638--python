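"""Local ancestry over genetic-map windows.

The genome is tiled left-to-right into windows of at least a minimum genetic
length (default 0.2 cM).  Within each window the diploid ancestry of a sample
is called as the unordered pair of reference populations (a, b) maximising
the naive-Bayes log-likelihood of the observed unphased dosages, with one
Bernoulli allele drawn from each population:

    P(g=0) = (1-f_a)(1-f_b)
    P(g=1) = f_a (1-f_b) + (1-f_a) f_b
    P(g=2) = f_a f_b

This is a deliberately simple, exactly testable classifier standing in for
conditional-random-field local-ancestry tools; downstream analyses only
consume the window labels.  Ties are broken toward homozygous pairs, then
lexicographic label order.  Windows with no informative variant inherit the
nearest assigned window on the same chromosome (left neighbour preferred).

Global ancestry averages haplotype-window fractions per chromosome, then
averages over chromosomes with equal weight; a sample is labelled with a
single predominant ancestry only when that fraction strictly exceeds the
threshold (default 80%), otherwise "Admixed".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .config import ADMIXED_LABEL, InputError
from .types import (AncestryPanel, GeneticMap, GlobalAncestry,
                    LocalAncestryTrack, VariantGenotypes)

_EPS_CM = 1e-9


@dataclass
class WindowSet:
    """Non-overlapping windows tiling each chromosome of a genetic map."""

    table: pd.DataFrame  # columns: chrom, start, end, cm_start, cm_end
    min_cm: float

    @property
    def n_windows(self) -> int:
        return len(self.table)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise InputError(f"no windows on chromosome {chrom}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def locate(self, gmap: GeneticMap, chrom: str, pos0: int) -> int:
        """Global index of the window containing ``pos0``."""
        sl = self.chrom_slice(chrom)
        cm = float(gmap.cm_at(chrom, pos0))
        sub = self.table.iloc[sl]
        cm0 = float(sub["cm_start"].iloc[0])
        k = int((cm - cm0 + _EPS_CM) // self.min_cm)
        k = min(k, len(sub) - 1)
        return sl.start + k

    def assign_variants(self, gmap: GeneticMap,
                        variants: pd.DataFrame) -> np.ndarray:
        """Window index per variant (variants sorted by chrom, pos0)."""
        out = np.empty(len(variants), dtype=np.int64)
        for chrom, grp in variants.groupby("chrom", sort=False):
            sl = self.chrom_slice(str(chrom))
            sub = self.table.iloc[sl]
            cm = gmap.cm_at(str(chrom), grp["pos0"].to_numpy())
            cm0 = float(sub["cm_start"].iloc[0])
            k = ((cm - cm0 + _EPS_CM) // self.min_cm).astype(np.int64)
            np.clip(k, 0, len(sub) - 1, out=k)
            out[variants.index.get_indexer(grp.index)] = sl.start + k
        return out


def build_windows(gmap: GeneticMap, min_cm: float = 0.2) -> WindowSet:
    """Tile every chromosome into windows of >= ``min_cm`` centimorgans.

    Windows are cut greedily left to right at multiples of ``min_cm`` on the
    cM scale; a terminal remainder shorter than ``min_cm`` forms its own
    window (so a chromosome shorter than ``min_cm`` is a single window).
    """
    if min_cm <= 0:
        raise InputError("min_cm must be positive")
    rows = []
    for chrom in gmap.chroms:
        tab = gmap.tables[chrom]
        cm_lo = float(tab["cm"].iloc[0])
        cm_hi = float(tab["cm"].iloc[-1])
        span = cm_hi - cm_lo
        n_full = int((span + _EPS_CM) // min_cm)
        bounds = [cm_lo + i * min_cm for i in range(n_full + 1)]
        if span - n_full * min_cm > _EPS_CM or n_full == 0:
            bounds.append(cm_hi)
        bounds[-1] = cm_hi
        for cm_start, cm_end in zip(bounds[:-1], bounds[1:]):
            start = int(round(float(gmap.pos_at_cm(chrom, cm_start))))
            end = int(round(float(gmap.pos_at_cm(chrom, cm_end))))
            rows.append((chrom, start, end, cm_start, cm_end))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                        "cm_start", "cm_end"])
    return WindowSet(table=table, min_cm=min_cm)


def _canonical_pairs(n_pops: int) -> list[tuple[int, int]]:
    # Homozygous pairs first, then heterozygous, each block lexicographic:
    # np.argmax then resolves ties toward homozygous / lexicographic pairs.
    hom = [(i, i) for i in range(n_pops)]
    het = [p for p in combinations_with_replacement(range(n_pops), 2)
           if p[0] != p[1]]
    return hom + het


def pair_genotype_logprobs(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """log P(g | f_a, f_b) for g in {0,1,2}; shape (3, n_variants)."""
    p0 = (1 - fa) * (1 - fb)
    p1 = fa * (1 - fb) + (1 - fa) * fb
    p2 = fa * fb
    return np.log(np.stack([p0, p1, p2]))


def infer_local_ancestry(genotypes: VariantGenotypes, panel: AncestryPanel,
                         windows: WindowSet, gmap: GeneticMap,
                         ) -> LocalAncestryTrack:
    """Call the diploid ancestry pair of every sample in every window."""
    common = genotypes.variants.index.intersection(panel.variants.index)
    if len(common) == 0:
        raise InputError("panel covers none of the genotyped variants")
    variants = genotypes.variants.loc[common]
    order = np.lexsort((variants["pos0"].to_numpy(),
                        variants["chrom"].to_numpy()))
    variants = variants.iloc[order]
    dos = genotypes.dosages.loc[:, variants.index].to_numpy(dtype=float)
    freqs = panel.freqs.loc[variants.index].to_numpy(dtype=float)

    widx = windows.assign_variants(gmap, variants)
    n_win = windows.n_windows
    n_samples = dos.shape[0]
    pops = panel.populations
    pairs = _canonical_pairs(len(pops))

    missing = np.isnan(dos)
    gcode = np.nan_to_num(dos).astype(np.int64)  # missing -> 0, masked below
    onehot = np.zeros((3,) + dos.shape, dtype=bool)
    for g in range(3):
        onehot[g] = (gcode == g) & ~missing

    # per-window sums via reduceat over the (chrom, pos)-sorted variant axis
    win_starts = np.searchsorted(widx, np.arange(n_win))
    informative = np.add.reduceat((~missing).astype(np.int64), win_starts,
                                  axis=1)
    empty_win = np.searchsorted(widx, np.arange(n_win), side="right") \
        == win_starts
    informative[:, empty_win] = 0

    loglik = np.empty((len(pairs), n_samples, n_win))
    for k, (a, b) in enumerate(pairs):
        lp = pair_genotype_logprobs(freqs[:, a], freqs[:, b])  # (3, V)
        per_site = (onehot * lp[:, None, :]).sum(axis=0)       # (S, V)
        loglik[k] = np.add.reduceat(per_site, win_starts, axis=1)
        loglik[k][:, empty_win] = 0.0

    best = np.argmax(loglik, axis=0)                    # (S, W)
    top2 = np.partition(loglik, -2, axis=0)[-2:, :, :]
    margin = top2[1] - top2[0]

    pair_arr = np.array([sorted(p) for p in pairs], dtype=np.int64)
    pair_out = pair_arr[best]                           # (S, W, 2)
    imputed = informative == 0
    margin = np.where(imputed, 0.0, margin)

    # uninformative windows inherit the nearest call on the same chromosome
    for chrom in gmap.chroms:
        sl = windows.chrom_slice(chrom)
        for s in range(n_samples):
            cols = np.arange(sl.start, sl.stop)
            bad = imputed[s, cols]
            if not bad.any() or bad.all():
                continue
            good = cols[~bad]
            for w in cols[bad]:
                left = good[good < w]
                src = left[-1] if left.size else good[good > w][0]
                pair_out[s, w] = pair_out[s, src]
                margin[s, w] = 0.0

    return LocalAncestryTrack(samples=genotypes.samples, populations=pops,
                              pair=pair_out, margin=margin, imputed=imputed)


def global_ancestry_fractions(track: LocalAncestryTrack, windows: WindowSet,
                              threshold: float = 0.8) -> GlobalAncestry:
    """Genome-wide ancestry fractions with equal chromosome weights."""
    n_pops = len(track.populations)
    chroms = windows.table["chrom"].unique()
    per_chrom = np.zeros((len(chroms), len(track.samples), n_pops))
    for ci, chrom in enumerate(chroms):
        sl = windows.chrom_slice(str(chrom))
        sub = track.pair[:, sl, :]           # (S, Wc, 2)
        counts = np.zeros((len(track.samples), n_pops))
        for p in range(n_pops):
            counts[:, p] = (sub == p).sum(axis=(1, 2))
        per_chrom[ci] = counts / (2 * (sl.stop - sl.start))
    fractions = per_chrom.mean(axis=0)
    frac_df = pd.DataFrame(fractions, index=track.samples,
                           columns=track.populations)
    predominant = frac_df.apply(
        lambda row: assign_predominant(row, threshold), axis=1)
    return GlobalAncestry(fractions=frac_df, predominant=predominant)


def assign_predominant(fractions: pd.Series, threshold: float = 0.8) -> str:
    """Predominant label if one fraction strictly exceeds the threshold."""
    top = fractions.idxmax()
    if fractions[top] > threshold:
        return str(top)
    return ADMIXED_LABEL


def ancestry_at_locus(track: LocalAncestryTrack, windows: WindowSet,
                      gmap: GeneticMap, glob: GlobalAncestry,
                      chrom: str, pos0: int) -> pd.Series:
    """Single-label locus ancestry for every sample at one position.

    Homozygous windows give their population; heterozygous windows resolve
    to the member with the higher global fraction for that sample (ties:
    lexicographic label order).
    """
    w = windows.locate(gmap, chrom, pos0)
    return _labels_at_window(track, glob, w)


def _labels_at_window(track: LocalAncestryTrack, glob: GlobalAncestry,
                      w: int) -> pd.Series:
    pops = track.populations
    a = track.pair[:, w, 0]
    b = track.pair[:, w, 1]
    frac = glob.fractions[pops].to_numpy()
    idx = np.arange(len(track.samples))
    fa = frac[idx, a]
    fb = frac[idx, b]
    # canonical pair order is lexicographic, so ties resolve to `a`
    chosen = np.where(fb > fa, b, a)
    labels = np.asarray(pops, dtype=object)[chosen]
    return pd.Series(labels, index=track.samples)
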