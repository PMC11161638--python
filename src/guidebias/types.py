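"""Shared in-memory containers.

Tabular data is held in pandas; dense matrices (dosages, scores) are
DataFrames with sample ids on the rows so that every association keeps
sample alignment explicit.  All genomic coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import InputError

#: columns of the variant table
VARIANT_COLUMNS = ["chrom", "pos0", "ref", "alt"]

#: columns of the guide table
GUIDE_COLUMNS = ["guide_id", "gene", "chrom", "start", "end", "strand",
                 "protospacer", "pam"]


@dataclass
class VariantGenotypes:
    """Biallelic SNVs with per-sample diploid dosages.

    Attributes
    ----------
    variants:
        DataFrame indexed by variant id with columns chrom, pos0 (0-based),
        ref, alt.
    dosages:
        sample x variant DataFrame with entries in {0, 1, 2} or NaN.
    """

    variants: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise InputError(f"variant table lacks columns: {missing}")
        if not self.variants.index.equals(self.dosages.columns):
            raise InputError("dosage columns must match variant index")
        bad = self.variants["ref"] == self.variants["alt"]
        if bad.any():
            raise InputError("ref must differ from alt for every variant")

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequencies(self) -> pd.Series:
        """Alternate-allele frequency per variant over non-missing samples."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def subset_variants(self, ids) -> "VariantGenotypes":
        return VariantGenotypes(self.variants.loc[ids],
                                self.dosages.loc[:, ids])


class GeneticMap:
    """Piecewise-linear position <-> centimorgan map per chromosome.

    Parameters
    ----------
    tables:
        mapping chrom -> DataFrame with columns ``pos0`` (0-based bp,
        strictly increasing) and ``cm`` (non-decreasing).
    """

    def __init__(self, tables: dict[str, pd.DataFrame]):
        if not tables:
            raise InputError("genetic map is empty")
        self.tables = {}
        for chrom, tab in tables.items():
            tab = tab.sort_values("pos0").reset_index(drop=True)
            if np.any(np.diff(tab["cm"].to_numpy()) < 0):
                raise InputError(f"cM not monotone on {chrom}")
            self.tables[chrom] = tab

    @classmethod
    def uniform(cls, chroms: list[str], length_bp: int,
                cm_total: float) -> "GeneticMap":
        """Constant recombination rate of ``cm_total`` over ``length_bp``."""
        tables = {
            c: pd.DataFrame({"pos0": [0, length_bp], "cm": [0.0, cm_total]})
            for c in chroms
        }
        return cls(tables)

    @property
    def chroms(self) -> list[str]:
        return list(self.tables)

    def cm_at(self, chrom: str, pos0) -> np.ndarray:
        tab = self._table(chrom)
        pos0 = np.asarray(pos0)
        lo, hi = tab["pos0"].iloc[0], tab["pos0"].iloc[-1]
        if np.any(pos0 < lo) or np.any(pos0 > hi):
            raise InputError(f"position outside map range on {chrom}")
        return np.interp(pos0, tab["pos0"], tab["cm"])

    def pos_at_cm(self, chrom: str, cm) -> np.ndarray:
        tab = self._table(chrom)
        return np.interp(cm, tab["cm"], tab["pos0"])

    def chrom_span_cm(self, chrom: str) -> float:
        tab = self._table(chrom)
        return float(tab["cm"].iloc[-1] - tab["cm"].iloc[0])

    def chrom_end(self, chrom: str) -> int:
        return int(self._table(chrom)["pos0"].iloc[-1])

    def _table(self, chrom: str) -> pd.DataFrame:
        if chrom not in self.tables:
            raise InputError(f"chromosome {chrom} not in genetic map")
        return self.tables[chrom]


@dataclass
class AncestryPanel:
    """Reference per-population alternate-allele frequencies.

    ``freqs`` is variant x population, clipped strictly inside (0, 1).
    """

    variants: pd.DataFrame
    freqs: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.variants.index.equals(self.freqs.index):
            raise InputError("panel variant index mismatch")
        vals = self.freqs.to_numpy()
        if np.any(vals <= 0) or np.any(vals >= 1):
            raise InputError("panel frequencies must lie strictly in (0,1)")

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)


@dataclass
class LocalAncestryTrack:
    """Diploid per-window ancestry assignments.

    ``pair`` has shape (n_samples, n_windows, 2) holding population indices
    into ``populations`` with pair[..., 0] <= pair[..., 1] (unordered pair in
    canonical order).  ``margin`` is the log-likelihood gap between the best
    and second-best pair; ``imputed`` marks windows whose call was copied
    from a neighbour for lack of informative variants.
    """

    samples: pd.Index
    populations: list[str]
    pair: np.ndarray
    margin: np.ndarray
    imputed: np.ndarray

    def __post_init__(self) -> None:
        ns, nw, two = self.pair.shape
        if two != 2 or self.margin.shape != (ns, nw):
            raise InputError("track arrays inconsistent")

    @property
    def n_windows(self) -> int:
        return self.pair.shape[1]


@dataclass
class GlobalAncestry:
    """Per-sample genome-wide ancestry fractions (rows sum to 1)."""

    fractions: pd.DataFrame  # sample x population
    predominant: pd.Series   # sample -> label or "Admixed"


@dataclass
class ScreenData:
    """Guide-level log-fold-changes and gene-level dependency scores.

    More negative means more depleted (stronger dependency).
    """

    guide_lfc: pd.DataFrame     # sample x guide
    gene_dependency: pd.DataFrame  # sample x gene
    lineage: pd.Series          # sample -> categorical label

    def __post_init__(self) -> None:
        if not self.guide_lfc.index.equals(self.gene_dependency.index):
            raise InputError("guide and gene matrices must share samples")
        if not self.guide_lfc.index.equals(self.lineage.index):
            raise InputError("lineage must cover the screened samples")

    @property
    def samples(self) -> pd.Index:
        return self.guide_lfc.index


@dataclass
class TruthSet:
    """Ground truth of a synthetic cohort, for parameter-recovery tests."""

    ancestry_painting: np.ndarray  # (n_samples, 2, n_windows) pop indices
    block_boundaries: dict = field(default_factory=dict)
    causal_artifact_table: pd.DataFrame | None = None
    true_effects: pd.DataFrame | None = None
    positional_weights_used: np.ndarray | None = None


def validate_guide_table(guides: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of a guide table and return it."""
    missing = [c for c in GUIDE_COLUMNS if c not in guides.columns]
    if missing:
        raise InputError(f"guide table lacks columns: {missing}")
    span = guides["end"] - guides["start"]
    if (span != 23).any():
        raise InputError("guide targeting intervals must have length 23")
    if (~guides["strand"].isin(["+", "-"])).any():
        raise InputError("strand must be '+' or '-'")
    if (guides["protospacer"].str.len() != 20).any():
        raise InputError("protospacers must be 20 nt")
    if (~guides["pam"].str.slice(1, 3).eq("GG")).any():
        raise InputError("PAM must match NGG on the guide strand")
    return guides
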