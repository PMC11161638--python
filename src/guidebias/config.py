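"""Configuration containers for the pipeline and the synthetic cohort.

Every threshold used anywhere in the analysis lives in :class:`PipelineConfig`
so that a run is a pure function of (config, inputs, seed).  Coordinates are
0-based half-open everywhere inside the package; conversion to/from 1-based
formats (VCF) happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from typing import Sequence

import numpy as np

#: Continental ancestry group labels used throughout (lexicographic order).
DEFAULT_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

ADMIXED_LABEL = "Admixed"


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of its documented range."""


class InputError(ValueError):
    """Raised when an input object violates a precondition."""


@dataclass
class PipelineConfig:
    """Thresholds of the full analysis.

    Attributes
    ----------
    window_cm:
        Minimum local-ancestry window size in centimorgans.
    predominance_threshold:
        Global-ancestry fraction above which (strictly) a sample is labelled
        with a single predominant ancestry; otherwise "Admixed".
    fdr_q:
        FDR significance level for every multiple-testing family.
    maf_min:
        Minor-allele-frequency floor (strict) for the d-QTL scan.
    differential_maf:
        Max-minus-min per-group allele frequency above which (strictly) a
        marker variant counts as ancestry-associated.
    proximal_bp:
        A marker closer (strictly) than this to the gene TSS, on the same
        chromosome, is "proximal".
    min_affected_lines:
        Minimum number of distinct samples carrying an in-guide variant for a
        guide to be flagged as recurrently affected.
    afr_ratio_max:
        Library design constraint: AFR per-individual mismatch carrier rate
        may not exceed this multiple of the non-AFR rate.
    afr_rate_floor:
        The AFR-ratio constraint only applies when the AFR carrier rate
        exceeds this floor (ratios of vanishing rates are noise).
    guides_per_gene:
        Library size per gene.
    power_reps:
        Monte-Carlo replicates per effect size in the power simulation.
    expression_rpm_threshold:
        Median reads-per-million below which (strictly) a gene counts as
        weakly expressed.
    ld_r2_threshold:
        r-squared above which two variants are treated as linked.
    differential_lfc:
        |group-mean LFC difference| above which a guide counts as
        differentially depleted in the SNP-enrichment contrast.
    include_pam_n:
        Whether variants at the degenerate PAM "N" base count as affecting a
        guide (they are always recorded, at position 0).
    seed:
        Global seed; expanded into independent per-stage streams.
    """

    window_cm: float = 0.2
    predominance_threshold: float = 0.8
    fdr_q: float = 0.05
    maf_min: float = 0.01
    differential_maf: float = 0.2
    proximal_bp: int = 1_000_000
    min_affected_lines: int = 10
    afr_ratio_max: float = 2.5
    afr_rate_floor: float = 1e-4
    guides_per_gene: int = 4
    power_reps: int = 1000
    expression_rpm_threshold: float = 5.0
    ld_r2_threshold: float = 0.8
    differential_lfc: float = 0.25
    include_pam_n: bool = False
    positional_test: str = "wilcoxon"  # or "ttest"; headline test for positions
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.predominance_threshold < 1):
            raise ConfigurationError("predominance_threshold must be in (0,1)")
        if not (0 < self.fdr_q < 1):
            raise ConfigurationError("fdr_q must be in (0,1)")
        for name in ("window_cm", "maf_min", "differential_maf", "proximal_bp",
                     "min_affected_lines", "afr_ratio_max", "guides_per_gene",
                     "power_reps", "expression_rpm_threshold",
                     "ld_r2_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.positional_test not in ("wilcoxon", "ttest"):
            raise ConfigurationError("positional_test must be wilcoxon or ttest")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _default_positional_weights() -> np.ndarray:
    # Linear decay from full attenuation at the PAM-proximal base to none at
    # the PAM-distal end, mirroring the seed-region tolerance gradient.
    return np.linspace(1.0, 0.0, 20)


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort generator.

    The defaults describe the study conditions the rest of the package is
    exercised under: a handful of ancestral populations differentiated at
    Fst 0.1, block-admixed diploid genomes on a uniform genetic map, a
    4-guides-per-gene library, and guide depletion scores whose attenuation
    depends on in-guide variants and their distance from the PAM.
    """

    n_populations: int = 3
    fst: float | Sequence[float] = 0.1
    n_samples: int = 100
    n_chromosomes: int = 2
    n_variants_per_chrom: int = 1000
    chrom_length_bp: int = 10_000_000
    cm_per_chrom: float = 10.0
    mean_block_cm: float = 5.0
    admixture_proportions: np.ndarray | None = None  # (n_samples, n_populations)
    n_genes: int = 50
    guides_per_gene: int = 4
    positional_weights: np.ndarray = field(
        default_factory=_default_positional_weights)
    het_attenuation_factor: float = 1.0
    noise_sd: float = 1.0
    gene_effect_mean: float = -1.0
    gene_effect_sd: float = 0.25
    n_lineages: int = 3
    lineage_effect_sd: float = 0.25
    injected_artifact_genes: list = field(default_factory=list)
    injected_true_dependency_effects: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        fst = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if fst.size == 1:
            fst = np.repeat(fst, self.n_populations)
        if fst.size != self.n_populations:
            raise ConfigurationError("fst must be scalar or per-population")
        if not np.all(np.isfinite(fst)) or np.any(fst < 0) or np.any(fst >= 1):
            raise ConfigurationError("fst values must be finite and in [0,1)")
        self.fst = fst
        if self.n_populations < 2:
            raise ConfigurationError("need at least 2 populations")
        for name in ("n_samples", "n_chromosomes", "n_variants_per_chrom",
                     "n_genes", "guides_per_gene", "n_lineages"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.lineage_effect_sd < 0:
            raise ConfigurationError("lineage_effect_sd must be >= 0")
        if not (0 <= self.het_attenuation_factor <= 1):
            raise ConfigurationError("het_attenuation_factor must be in [0,1]")
        w = np.asarray(self.positional_weights, dtype=float)
        if w.shape != (20,):
            raise ConfigurationError("positional_weights must have length 20")
        if np.any(w < 0) or np.any(w > 1):
            raise ConfigurationError("positional weights must be in [0,1]")
        self.positional_weights = w
        if self.admixture_proportions is not None:
            q = np.asarray(self.admixture_proportions, dtype=float)
            if q.shape != (self.n_samples, self.n_populations):
                raise ConfigurationError(
                    "admixture_proportions must be (n_samples, n_populations)")
            if np.any(q < 0) or not np.allclose(q.sum(axis=1), 1.0):
                raise ConfigurationError(
                    "admixture proportions must be non-negative and sum to 1")
            self.admixture_proportions = q

    @property
    def populations(self) -> tuple[str, ...]:
        return DEFAULT_POPULATIONS[: self.n_populations]
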