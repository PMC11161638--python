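# Methods

This note documents the models behind `guidebias`, the defaults that
matter, what the synthetic cohorts do and do not emulate, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort generator

**Population differentiation.** Reference allele frequencies follow a
Balding–Nichols construction: an ancestral frequency `p ~ Uniform(0.05,
0.95)` per variant, and per population `f ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`
with divergence `F` (default 0.1, scalar or per-population; `F = 0`
collapses to the ancestral frequency). Frequencies are clipped to
[0.001, 0.999]. This gives one-parameter control of differentiation where
the real analysis uses curated reference panels.

**Admixture.** Each haplotype is a sequence of ancestry blocks whose
breakpoints form a Poisson process on the centimorgan scale with mean
block length 5 cM (configurable), realised at the resolution of the
0.2 cM analysis windows: crossing a window boundary of genetic length `d`
switches ancestry with probability `1 − exp(−d / mean_block_cm)`,
redrawing from the sample's admixture proportions. Realising blocks at
window resolution makes the recorded painting exact — every allele is
drawn `Bernoulli(f_pop)` for precisely the population recorded in the
truth set. When proportions are not supplied they are drawn from a
symmetric Dirichlet(0.3), giving a mostly-homogeneous cohort with an
admixed tail; benchmark scenarios pass explicit one-hot proportions.

**Guide library.** Genes are placed at distinct TSS positions spread along
each chromosome; each gene receives 4 guides with random 20-nt
protospacers, NGG PAMs, random strands and disjoint 23-bp targeting
intervals near the TSS.

**Screen.** Guide-level log-fold-change is

    LFC(g, c) = effect(gene(g), c) · activity(g, c) + Normal(0, noise_sd²)

where `effect` is a per-gene base effect (default Normal(−1, 0.25²);
more negative = more depleted) plus a per-(gene, lineage) offset
(Normal(0, 0.25²)) plus any planted ancestry-linked effect, scaled by the
fraction of the sample's two haplotypes painted with that ancestry at the
gene's TSS. Activity multiplies `(1 − w_position · d)` over in-guide
variants the sample carries, `d = 1` for homozygous alternate and
`het_attenuation_factor` (default 1, i.e. presence is binary) for
heterozygous. The positional tolerance profile `w₁..w₂₀` defaults to a
linear decay from 1 at the PAM-proximal base to 0 at the distal end.
Variants in the two required PAM "GG" bases attenuate fully; the
degenerate "N" base does not attenuate. The uncorrected gene-level matrix
is the per-gene mean of guide LFCs.

`noise_sd` defaults to 1 (the screen-level score noise is not otherwise
pinned down); benchmark scenarios use smaller values chosen by power
analysis (below).

**What is not emulated.** Realistic linkage disequilibrium beyond block
structure, recombination hotspots, sequencing error, copy-number
alterations, indels, and guide-efficacy heterogeneity beyond the mismatch
mechanism. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signals under the stated noise
model — not performance on real screens.

## Local ancestry

Windows tile each chromosome greedily left to right at multiples of
0.2 cM (configurable); a terminal remainder shorter than the minimum forms
its own window. Per window and sample, the unordered population pair
(a, b) maximises `Σᵢ log P(gᵢ | f_a,i, f_b,i)` with `P(0) = (1−f_a)(1−f_b)`,
`P(1) = f_a(1−f_b) + (1−f_a)f_b`, `P(2) = f_a f_b`. This per-window
naive-Bayes classifier on unphased dosages deliberately replaces
conditional-random-field machinery: downstream analyses consume only the
window labels, and the simple classifier is exactly testable against the
simulated painting. Ties break toward homozygous pairs, then lexicographic
label order; the margin is the log-likelihood gap to the runner-up.
Windows with no informative variant inherit the nearest assigned window on
the same chromosome (left preferred) and are flagged.

Global fractions: within each chromosome, the fraction of haplotype-window
assignments per population (a diploid pair contributes ½ + ½); the global
fraction is the unweighted mean over chromosomes. A predominant label
requires a fraction strictly above 0.8, otherwise "Admixed".

Locus ancestry at a heterozygous window is resolved to the pair member
with the larger global fraction for that sample (ties: lexicographic).
The rule is isolated in one operation because any single-label reduction
of a heterozygous diploid block is a convention.

## Association and power

Per gene, dependency is regressed on `1{locus ancestry == group}` plus
lineage dummies (smallest lineage dropped, intercept kept). Families for
the BH correction are per ancestry group across genes — the one-vs-rest
scans are reported per group, so each group forms its own family.
Singular designs (group confounded with lineage) are reported with missing
p and excluded from the family. All scans share one vectorised OLS path
(Frisch–Waugh–Lovell residualisation; identical to per-column refits,
asserted against statsmodels).

The power simulation draws group scores `Normal(δ, noise_sd²)` against
`Normal(0, noise_sd²)` for δ on a grid, redraws lineage labels each
replicate from supplied frequencies (lineage enters the test, not the
generating model), and reuses one residualisation per replicate across
the whole δ grid, which makes 1000 replicates × 101 effects cheap.

## d-QTLs, eQTLs, LD

The scan uses additive dosage coding with lineage covariates; the
expression test collapses dosages 1 and 2 into a presence class —
the two codings intentionally differ. The multiple-testing family for
Benjamini–Yekutieli is all MAF-filtered variants tested for one gene;
families are not pooled across genes. Missing dosages are dropped
casewise per variant. Marker selection takes the lowest q, breaking ties
by raw p then genomic order, and both the significance-gated marker and
the strongest association overall are emitted. The
ancestry-differential rule (max − min group allele frequency > 0.2) uses
the AFR/EAS/EUR/Admixed groups only; very small groups are excluded
because their frequencies are noise. LD is composite r² of unphased
dosages; "tightly linked" defaults to r² ≥ 0.8 (configurable — no
canonical threshold exists for this use).

## Mismatch mapping

A guide's targeting interval is 23 bp: protospacer [s, s+20) + PAM
[s+20, s+23) on '+', and PAM [s, s+3) (reading CCN on the reference
strand) + protospacer [s+3, s+23) on '−'. Positions are counted from the
PAM: 1 = PAM-proximal protospacer base, 20 = distal; PAM N/G/G are
0/−1/−2. Variants at the degenerate N are recorded but excluded from
affected-guide counts by default — an N-site SNV cannot disrupt NGG
recognition — with a switch (`include_pam_n`) restoring the literal 23-bp
definition. Presence is zygosity-agnostic. Multi-allelic VCF records are
split into biallelic SNVs; non-SNV alleles are dropped with a counter.

Positional effects pool (guide, sample) pairs with a mismatch at one
position against pairs on the same guides with no mismatch at all, and
report the mean LFC difference (positive = protective) with both Welch-t
and Wilcoxon rank-sum p-values; the headline test is configurable because
the pair-level pooling admits either. The Fisher enrichment contrast
calls a guide "differentially depleted" at |Δ| > 0.25 LFC by default
(configurable; no canonical cutoff).

## Correction and design

Corrected gene scores exclude a gene's mismatched guides only for the
carrying sample; the aggregator is an unweighted mean of guide LFCs
(median by option) — a documented simple stand-in for model-based
gene-score pipelines, which are out of scope. Cells with every guide
excluded become missing. The pre/post comparison is a paired two-sided
t-test per gene on per-sample differences with BH across genes; genes
identical pre/post never count as discoveries.

Library design ranks candidates by a supplied on-target score and drops
candidates with any targeting-interval variant above 1% overall
frequency, or whose AFR carrier rate exceeds 2.5× the non-AFR rate.
Carrier rates are computed under Hardy–Weinberg independence across a
guide's variants (`1 − Π(1−f)²`) because individual genotypes are
unavailable at design time; the ratio constraint only applies when the
AFR rate exceeds 1e-4, since ratios of vanishing rates are unstable.
Genes with fewer than four surviving candidates are filled from the best
excluded candidates and flagged, keeping library size fixed.

## Benchmark operating points

The scenarios in `guidebias.scenarios` fix the study conditions measured
by the acceptance script; sizes were chosen by power analysis before the
benchmarks were frozen.

- *Window recovery*: 3 populations, Fst 0.1, 50 samples, one 10 cM
  chromosome, 200 variants per 0.2 cM window.
- *Power*: group sizes 26/6/203/373/4 (the screened collection's
  predominant-ancestry counts), 1000 replicates, lineage frequencies
  0.5/0.3/0.2, noise 1.
- *Marker recovery*: 100 samples in two groups, 800 variants, one fully
  attenuating SNP per replicate planted at frequency 0.5 vs 0.05 — an
  intermediate frequency in the carrier group, so carrier status varies
  within ancestry and the causal variant can outrank pure ancestry
  proxies; depletion noise 0.2 LFC so the ~0.16-LFC gene-level shift
  clears per-gene Benjamini–Yekutieli in most replicates.
- *Artifact correction*: 200 samples in two groups, 50 genes × 4 guides,
  10 genes with one fully attenuating PAM-proximal SNP (0.9 vs 0.02),
  noise 0.4 LFC: the planted quarter-guide shift of ≈0.22 LFC then has
  t ≈ 8 at the group sizes, while the post-correction scan reverts to
  its null. A companion cohort adds three genuine ancestry-linked
  effects of −1 LFC to check they survive correction.
- *Positional gradient*: one variant per guide cycling positions 1..20 at
  frequency 0.3 in both populations, tolerance profile linear from 1.0
  to 0.05 (kept strictly positive so every position has a nonzero
  expected protective shift), noise 0.3.

## Numerical choices

Coordinates are 0-based half-open internally; VCF and genetic-map files
are 1-based at the I/O boundary only. Strict inequalities follow the
stated thresholds everywhere: predominance > 0.8, MAF > 0.01,
differential > 0.2, proximal < 1 Mb, weakly expressed < 5 RPM. Window
assignment uses a 1e-9 cM guard against floating-point boundary error.
Degenerate regression inputs (constant predictors, zero residual degrees
of freedom) yield missing statistics, never exceptions. One global seed
expands into independent per-stage streams via `SeedSequence.spawn`, so
outputs are bit-reproducible for a fixed configuration and adding draws
to one stage never perturbs another.

## Known limitations

- The local-ancestry classifier ignores linkage between windows; its
  accuracy degrades quickly below ~50 informative variants per window or
  Fst ≈ 0.02, and it does not phase.
- Gene-level aggregation by mean is cruder than model-based scoring;
  absolute dependency scales are not comparable to production pipelines.
- The HWE carrier-rate model in library design ignores LD between a
  guide's variants (conservative for positively linked variants).
- Somatic variant input is handled as a generic per-sample variant table;
  no MAF-format-specific parsing beyond chrom/pos/ref/alt/sample.
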