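"""Reading and writing of FASTA, VCF and TSV artefacts.

VCFs are written as minimal uncompressed VCF 4.2 with a single sample column
(GT) and read back through :mod:`pysam`.  Internal coordinates are 0-based
half-open; VCF text is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from pyfaidx import Fasta

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=gcsig
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


@dataclass(frozen=True)
class VcfRecord:
    """One biallelic VCF line (POS 1-based as in the file)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[str, str]
    qual: float | None = None
    filter: str = "PASS"
    info: str = "."


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into plain upper-case strings (faidx index built on demand)."""
    fa = Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_vcf(
    records: Iterable[VcfRecord],
    path: str | Path,
    sample: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    contigs = ""
    if contig_lengths:
        contigs = "".join(
            f"##contig=<ID={name},length={length}>\n"
            for name, length in contig_lengths.items()
        )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample))
        for r in records:
            qual = "." if r.qual is None else f"{r.qual:g}"
            gt = "/".join("1" if a == r.alt else "0" for a in r.genotype)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t{r.filter}\t"
                f"{r.info}\tGT\t{gt}\n"
            )


def read_vcf(path: str | Path) -> list[VcfRecord]:
    """Read a single-sample VCF; multi-allelic sites are decomposed."""
    out: list[VcfRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            gt_bases: tuple[str, ...] | None = None
            if sample_names:
                call = rec.samples[sample_names[0]]
                alleles = call.alleles
                if alleles and all(a is not None for a in alleles):
                    gt_bases = tuple(alleles)
            for alt in alts:
                if alt is None:
                    continue
                genotype = gt_bases if gt_bases is not None else (rec.ref, alt)
                if len(genotype) == 1:
                    genotype = (genotype[0], genotype[0])
                out.append(
                    VcfRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotype=tuple(genotype[:2]),
                        qual=rec.qual,
                        filter=";".join(rec.filter.keys()) or "PASS",
                    )
                )
    return out


SUPPORT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample",
    "depth",
    "alt_reads",
    "alt_fwd",
    "alt_rev",
]


def write_support_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=SUPPORT_COLUMNS)


def read_support_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SUPPORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"support table missing columns: {sorted(missing)}")
    return table


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
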