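"""Readers and writers for the interchange formats.

Formats: VCF 4.2 (genotypes), GFF3 (gene models, 1-based inclusive on disk),
FASTA (promoters), TSV (expression, metadata, traits, motifs, ground truth;
tab-separated, UTF-8, ``.`` for missing). Internal coordinates are 0-based
half-open; conversion happens here and only here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges
import pysam
from pyfaidx import Fasta

from .datatypes import GenotypeMatrix, MotifLibrary, PromoterSet, SampleMetadata

__all__ = [
    "write_vcf", "read_vcf",
    "write_gff3", "read_annotation",
    "write_fasta", "read_promoters",
    "write_motifs", "read_motifs",
    "write_expression", "read_expression",
    "write_metadata", "read_metadata",
    "write_traits", "read_traits",
    "write_tsv",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def write_vcf(genotypes: GenotypeMatrix, path, chrom_lengths: dict | None = None):
    """Write a VCF 4.2 text file (GID/SUBREG INFO fields carry annotation)."""
    sites = genotypes.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ecodiverge\n")
        if chrom_lengths:
            for c, L in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={L}>\n")
        else:
            for c in pd.unique(sites["chrom"]):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GID,Number=1,Type=String,'
                 'Description="Assigned gene ID (. = intergenic)">\n')
        fh.write('##INFO=<ID=SUBREG,Number=1,Type=String,'
                 'Description="Sub-gene compartment">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        codes = genotypes.codes
        for j, row in enumerate(sites.itertuples(index=False)):
            info = f"GID={row.gene_id};SUBREG={row.subregion}"
            gts = "\t".join(_GT[int(c)] for c in codes[j])
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t{info}\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF 4.x file.

    Multi-allelic records are skipped with a warning; het genotypes map to
    code 1 regardless of phasing separator; 1-based positions become
    internal 0-based.
    """
    import logging
    logger = logging.getLogger("ecodiverge")
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    has_gid = "GID" in vf.header.info
    has_sub = "SUBREG" in vf.header.info
    rows, code_rows = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            logger.warning("skipping non-biallelic record at %s:%d",
                           rec.chrom, rec.pos)
            continue
        gid = rec.info.get("GID", ".") if has_gid else "."
        sub = rec.info.get("SUBREG", ".") if has_sub else "."
        rows.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0], gid, sub))
        codes = []
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                codes.append(-1)
            else:
                codes.append(_CODE.get(tuple(gt), sum(1 for a in gt if a)))
        code_rows.append(codes)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                        "gene_id", "subregion"])
    codes = np.array(code_rows, dtype=np.int8) if code_rows else \
        np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(codes, sites, samples)


def write_gff3(annotation: pd.DataFrame, path):
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(f"{row.chrom}\tecodiverge\tgene\t{row.start + 1}\t"
                     f"{row.end}\t.\t{row.strand}\t.\tID={row.gene_id}\n")


def read_annotation(path) -> pd.DataFrame:
    """Read gene features from GFF3 into the internal annotation table.

    Returns gene_id / chrom / start / end / strand with 0-based half-open
    coordinates. Duplicate gene IDs are rejected.
    """
    gr = pyranges.read_gff3(str(path))
    df = gr.df
    df = df[df["Feature"] == "gene"]
    ann = pd.DataFrame({
        "gene_id": df["ID"].astype(str),
        "chrom": df["Chromosome"].astype(str),
        "start": df["Start"].astype(int),
        "end": df["End"].astype(int),
        "strand": df["Strand"].astype(str),
    }).reset_index(drop=True)
    if ann["gene_id"].duplicated().any():
        raise ValueError("duplicated gene IDs in annotation")
    return ann


def write_fasta(promoters: PromoterSet, path, width: int = 70):
    """Write promoter sequences; headers carry start/strand for round-trips."""
    with open(path, "w") as fh:
        for gid, seq in promoters.sequences.items():
            fh.write(f">{gid} start={promoters.starts[gid]} "
                     f"strand={promoters.strands[gid]}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_promoters(path) -> PromoterSet:
    """Read promoter FASTA written by :func:`write_fasta`."""
    fa = Fasta(str(path))
    seqs, starts, strands = {}, {}, {}
    for name in fa.keys():
        rec = fa[name]
        seqs[name] = str(rec[:])
        long_name = rec.long_name
        fields = dict(kv.split("=") for kv in long_name.split()[1:]
                      if "=" in kv)
        starts[name] = int(fields.get("start", 0))
        strands[name] = fields.get("strand", "+")
    return PromoterSet(seqs, starts, strands)


def write_motifs(motifs: MotifLibrary, path):
    pd.DataFrame({"name": list(motifs.motifs),
                  "iupac": list(motifs.motifs.values())}).to_csv(
        path, sep="\t", index=False)


def read_motifs(path) -> MotifLibrary:
    df = pd.read_csv(path, sep="\t")
    if not {"name", "iupac"} <= set(df.columns):
        raise ValueError("motif table needs 'name' and 'iupac' columns")
    return MotifLibrary(dict(zip(df["name"], df["iupac"])))


def write_expression(expr: pd.DataFrame, path):
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g",
                na_rep=".")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=".")
    if df.isna().all(axis=None):
        raise ValueError(f"expression table {path} is empty")
    return df


def write_metadata(meta: SampleMetadata, path):
    meta.table.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t")
    df["typical"] = df["typical"].astype(bool)
    return SampleMetadata(df)


def write_traits(traits: pd.DataFrame, path):
    traits.to_csv(path, sep="\t", index_label="sample", float_format="%.6g",
                  na_rep=".")


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample", na_values=".")


def write_tsv(df: pd.DataFrame, path, index: bool = False, **kw):
    """Uniform TSV writer for result tables ('.' for missing)."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", na_rep=".",
              **kw)
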