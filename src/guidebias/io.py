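"""Readers and writers for the standard formats the pipeline consumes.

Internal coordinates are 0-based half-open; VCF and genetic-map files use
1-based positions, converted only here.  Every tabular output starts with a
header comment declaring its coordinate convention.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestry import WindowSet
from .config import InputError
from .types import (AncestryPanel, GeneticMap, LocalAncestryTrack,
                    VariantGenotypes, validate_guide_table)

logger = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=guidebias
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(genotypes: VariantGenotypes, path: str | Path) -> Path:
    """Write unphased diploid GT records (POS is 1-based)."""
    path = Path(path)
    samples = list(genotypes.samples)
    dos = genotypes.dosages.to_numpy()
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(genotypes.variants["chrom"]):
            end = int(genotypes.variants.loc[
                genotypes.variants["chrom"] == chrom, "pos0"].max()) + 2
            fh.write(f"##contig=<ID={chrom},length={end}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (vid, row) in enumerate(genotypes.variants.iterrows()):
            gts = [gt_map.get(int(d), "./.") if np.isfinite(d) else "./."
                   for d in dos[:, j]]
            fh.write(f"{row['chrom']}\t{row['pos0'] + 1}\t{vid}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


def read_vcf(path: str | Path) -> VariantGenotypes:
    """Read biallelic SNVs; multi-allelic records are split per alternate.

    Non-SNV alleles are dropped (logged with a counter).  GT "0/1" and
    "1/1" become dosages 1 and 2; "./." is missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = pd.Index(vcf.samples, name="sample_id")
    var_rows, dosage_cols, ids = [], [], []
    dropped = 0
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT, start=1):
            if len(rec.REF) != 1 or len(alt) != 1:
                dropped += 1
                continue
            gts = np.asarray([g[:2] for g in rec.genotypes], dtype=int)
            dos = np.where((gts < 0).any(axis=1), np.nan,
                           (gts == ai).sum(axis=1).astype(float))
            vid = rec.ID if rec.ID and len(rec.ALT) == 1 else \
                f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            var_rows.append((rec.CHROM, rec.POS - 1, rec.REF, alt))
            dosage_cols.append(dos)
            ids.append(vid)
    if dropped:
        logger.info("dropped %d non-SNV alleles", dropped)
    variants = pd.DataFrame(var_rows,
                            columns=["chrom", "pos0", "ref", "alt"],
                            index=pd.Index(ids, name="variant_id"))
    dosages = pd.DataFrame(np.column_stack(dosage_cols) if dosage_cols
                           else np.empty((len(samples), 0)),
                           index=samples, columns=variants.index)
    return VariantGenotypes(variants=variants, dosages=dosages)


def _write_tsv(df: pd.DataFrame, path: Path, comment: str,
               index: bool = False) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def write_guide_map(library: pd.DataFrame, path: str | Path) -> Path:
    cols = ["guide_id", "gene", "chrom", "start", "end", "strand",
            "protospacer", "pam"]
    return _write_tsv(library[cols].rename(
        columns={"start": "start_0based", "end": "end_open"}), Path(path),
        "guide map; coordinates 0-based half-open")


def read_guide_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.rename(columns={"start_0based": "start", "end_open": "end"})
    if ((df["end"] - df["start"]) != 23).any():
        raise InputError(f"{path}: guide intervals must span 23 bp")
    return validate_guide_table(df)


def write_matrix(matrix: pd.DataFrame, path: str | Path,
                 what: str = "matrix") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {what}; rows=samples, columns as labelled\n")
        matrix.to_csv(fh)
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def write_tss_bed(tss: pd.DataFrame, path: str | Path) -> Path:
    bed = pd.DataFrame({
        "chrom": tss["chrom"],
        "start": tss["tss0"],
        "end": tss["tss0"] + 1,
        "name": tss["gene"],
    })
    with open(path, "w") as fh:
        fh.write("# TSS; BED 0-based half-open\n")
        bed.to_csv(fh, sep="\t", index=False, header=False)
    return Path(path)


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["chrom", "start", "end", "name"])
    return pd.DataFrame({"gene": bed["name"], "chrom": bed["chrom"],
                         "tss0": bed["start"]})


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> Path:
    return _write_tsv(metadata.reset_index(), Path(path),
                      "per-sample metadata")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#").set_index("sample_id")


def write_panel(panel: AncestryPanel, path: str | Path) -> Path:
    df = panel.variants.copy()
    df["pos"] = df["pos0"] + 1
    df = df[["chrom", "pos", "ref", "alt"]]
    for pop in panel.populations:
        df[f"freq_{pop}"] = panel.freqs[pop]
    return _write_tsv(df.reset_index(), Path(path),
                      "reference panel allele frequencies; pos 1-based")


def read_panel(path: str | Path) -> AncestryPanel:
    df = pd.read_csv(path, sep="\t", comment="#").set_index("variant_id")
    pops = [c.removeprefix("freq_") for c in df.columns
            if c.startswith("freq_")]
    variants = pd.DataFrame({"chrom": df["chrom"], "pos0": df["pos"] - 1,
                             "ref": df["ref"], "alt": df["alt"]})
    freqs = df[[f"freq_{p}" for p in pops]]
    freqs.columns = pops
    return AncestryPanel(variants=variants, freqs=freqs)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> Path:
    rows = []
    for chrom, tab in gmap.tables.items():
        for pos0, cm in tab[["pos0", "cm"]].itertuples(index=False):
            rows.append((chrom, int(pos0) + 1, cm))
    return _write_tsv(pd.DataFrame(rows, columns=["chrom", "pos", "cM"]),
                      Path(path), "genetic map; pos 1-based")


def read_genetic_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    tables = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        tables[str(chrom)] = pd.DataFrame({"pos0": grp["pos"] - 1,
                                           "cm": grp["cM"]})
    return GeneticMap(tables)


def write_track(track: LocalAncestryTrack, windows: WindowSet,
                path: str | Path) -> Path:
    pops = np.asarray(track.populations, dtype=object)
    tab = windows.table
    rows = []
    for si, sample in enumerate(track.samples):
        for w in range(track.n_windows):
            a, b = track.pair[si, w]
            rows.append((sample, tab["chrom"].iat[w], tab["start"].iat[w],
                         tab["end"].iat[w], pops[a], pops[b],
                         round(float(track.margin[si, w]), 6)))
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                     "pop1", "pop2", "margin"])
    return _write_tsv(df, Path(path),
                      "local ancestry track; coords 0-based half-open")


def write_fixtures(genotypes: VariantGenotypes, library: pd.DataFrame,
                   guide_lfc: pd.DataFrame, gene_dependency: pd.DataFrame,
                   tss: pd.DataFrame, metadata: pd.DataFrame,
                   outdir: str | Path,
                   panel: AncestryPanel | None = None,
                   gmap: GeneticMap | None = None) -> dict[str, Path]:
    """Write a consistent fixture set; identifiers are cross-checked first."""
    if not genotypes.samples.equals(guide_lfc.index):
        raise InputError("sample ids differ between genotypes and screen")
    if set(metadata.index) != set(genotypes.samples):
        raise InputError("metadata samples do not match genotypes")
    if set(library["gene"]) - set(tss["gene"]):
        raise InputError("library genes missing from TSS table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(genotypes, outdir / "genotypes.vcf"),
        "guide_map": write_guide_map(library, outdir / "guide_map.tsv"),
        "guide_lfc": write_matrix(guide_lfc, outdir / "guide_lfc.csv",
                                  "guide-level log fold changes"),
        "gene_dependency": write_matrix(
            gene_dependency, outdir / "gene_dependency.csv",
            "gene-level dependency scores (more negative = more depleted)"),
        "tss": write_tss_bed(tss, outdir / "tss.bed"),
        "metadata": write_metadata(metadata, outdir / "metadata.tsv"),
    }
    if panel is not None:
        paths["panel"] = write_panel(panel, outdir / "panel.tsv")
    if gmap is not None:
        paths["genetic_map"] = write_genetic_map(
            gmap, outdir / "genetic_map.tsv")
    return paths


def read_inputs(outdir: str | Path) -> dict:
    """Read a fixture directory back into validated in-memory objects."""
    outdir = Path(outdir)
    genotypes = read_vcf(outdir / "genotypes.vcf")
    library = read_guide_map(outdir / "guide_map.tsv")
    guide_lfc = read_matrix(outdir / "guide_lfc.csv")
    gene_dep = read_matrix(outdir / "gene_dependency.csv")
    tss = read_tss_bed(outdir / "tss.bed")
    metadata = read_metadata(outdir / "metadata.tsv")
    if not genotypes.samples.equals(guide_lfc.index):
        raise InputError("genotypes.vcf and guide_lfc.csv disagree on "
                         "sample identifiers")
    out = {"genotypes": genotypes, "library": library,
           "guide_lfc": guide_lfc, "gene_dependency": gene_dep,
           "tss": tss, "metadata": metadata}
    if (outdir / "panel.tsv").exists():
        out["panel"] = read_panel(outdir / "panel.tsv")
    if (outdir / "genetic_map.tsv").exists():
        out["genetic_map"] = read_genetic_map(outdir / "genetic_map.tsv")
    return out
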