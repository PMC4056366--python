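"""Gene/exon annotation containers and interval helpers.

Coordinates are 0-based half-open everywhere in memory; GFF3 emission
converts to 1-based closed on write and back on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import ParameterError


@dataclass(frozen=True)
class Gene:
    """A gene with one or more exons on a single strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParameterError(f"gene strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ParameterError(f"malformed gene interval [{self.start}, {self.end})")
        for s, e in self.exons:
            if not self.start <= s < e <= self.end:
                raise ParameterError(f"exon [{s}, {e}) outside gene body of {self.gene_id}")


def exon_intervals(genes: Iterable[Gene]) -> list[tuple[str, int, int]]:
    """Flat (chrom, start, end) list of all exons."""
    return [(g.chrom, s, e) for g in genes for s, e in g.exons]


def interval_trees(intervals: Iterable[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over half-open (chrom, start, end) triples."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def gene_trees(genes: Iterable[Gene]) -> dict[str, IntervalTree]:
    """Per-chromosome trees whose interval payload is the :class:`Gene`."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    return trees


def position_in(trees: Mapping[str, IntervalTree], chrom: str, pos0: int) -> bool:
    """Half-open membership of a 0-based position in an interval set."""
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlaps_point(pos0))


def total_span(intervals: Sequence[tuple[str, int, int]]) -> int:
    return sum(e - s for _, s, e in intervals)


# ---------------------------------------------------------------------------
# GFF3 / BED round-trip


def write_gff3(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tgcsig\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tgcsig\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[Gene]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = fields["ID"]
                genes[gid] = {
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "exons": [],
                }
                order.append(gid)
            elif ftype == "exon":
                parent = fields["Parent"]
                genes[parent]["exons"].append((int(start) - 1, int(end)))
    return [
        Gene(
            gene_id=gid,
            chrom=rec["chrom"],
            start=rec["start"],
            end=rec["end"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        )
        for gid, rec in ((g, genes[g]) for g in order)
    ]


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str | None]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3].strip() if len(parts) > 3 else None
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out
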