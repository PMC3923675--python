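"""Readers and writers for the external file dialects.

Methylation tables are tab-delimited with a header.  Per-strand call tables
carry (chrom, pos, strand, meth, total); combined CpG tables carry
(chrom, pos, meth, total, level) plus optional annotation columns; allele
tables add an ``allele`` column with values R/A.  Region sets are BED
(column 4 = class tag when present), SNPs are VCF (positions converted from
1-based on read), genomes are FASTA.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd
import pysam

from .regions import RegionSet

CALL_COLUMNS = ["chrom", "pos", "strand", "meth", "total"]


def read_meth_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("pos", "meth", "total"):
        if col in df.columns:
            df[col] = df[col].astype("int64")
    return df


def write_meth_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | os.PathLike, label: str) -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    tags = df[3].astype(str).tolist() if df.shape[1] >= 4 else None
    body = df.iloc[:, :3]
    body.columns = ["chrom", "start", "end"]
    return RegionSet(label, body, tags)


def write_bed(regions: RegionSet, path: str | os.PathLike) -> None:
    df = regions.to_frame()
    cols = ["chrom", "start", "end"] + (
        ["class_tag"] if regions.has_classes else []
    )
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_reads_bed(path: str | os.PathLike) -> pd.DataFrame:
    """6-column BED of single-base read 5' ends; strand in column 6."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype("int64"),
            "strand": df[5].astype(str),
        }
    )
    return out


def write_reads_bed(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"],
            "end": reads["start"] + 1,
            "name": ".",
            "score": 0,
            "strand": reads["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read SNPs from a VCF into a table with 0-based positions."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None:
                continue
            alt = rec.alts[0]
            if len(rec.ref) != 1 or len(alt) != 1:
                continue
            het = True
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is not None:
                    het = len(set(gt)) > 1
                break
            rows.append((rec.chrom, rec.pos - 1, rec.ref, alt, het))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref_base", "alt_base", "heterozygous"]
    )


def write_vcf(
    snps: pd.DataFrame,
    path: str | os.PathLike,
    contigs: Optional[dict] = None,
) -> None:
    """Write a SNP table (0-based positions) as a minimal VCF."""
    header = pysam.VariantHeader()
    header.add_meta("source", "pmdseq")
    if contigs:
        for name, length in contigs.items():
            header.contigs.add(name, length=int(length))
    else:
        for name in pd.unique(snps["chrom"]):
            header.contigs.add(str(name))
    header.add_sample("sample")
    header.formats.add("GT", 1, "String", "Genotype")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in snps.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos),
                stop=int(row.pos) + 1,
                alleles=(row.ref_base, row.alt_base),
            )
            het = bool(getattr(row, "heterozygous", True))
            rec.samples["sample"]["GT"] = (0, 1) if het else (1, 1)
            vcf.write(rec)
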