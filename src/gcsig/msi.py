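"""Homopolymer scanning, MSI indel classification and the recurrence test.

Microsatellite-unstable (MSI) tumors with mismatch-repair deficiency
accumulate single-base deletions in mononucleotide repeats, dominated by
thymine tracts.  This module scans a reference for maximal homopolymer
tracts, classifies left-aligned somatic indels by repeat context, estimates
length-stratified per-tract background deletion rates across an MSI-positive
cohort, and tests individual tracts (genes) for recurrence with a one-sided
exact binomial test under Bonferroni correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ParameterError


@dataclass(frozen=True)
class HomopolymerTract:
    """A maximal single-base run on the reference (0-based half-open)."""

    chrom: str
    start: int
    end: int
    base: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IndelContextCall:
    """A left-aligned indel classified by its repeat context."""

    chrom: str
    pos0: int  # 0-based position of the first inserted/deleted base
    kind: str  # "ins" | "del"
    size: int
    bases: str  # inserted/deleted sequence
    repeat_context: str  # "mononucleotide" | "non-repeat"
    tract_base: str | None
    tract_length: int | None
    tract: HomopolymerTract | None
    sample: str | None = None

    @property
    def is_signature(self) -> bool:
        """True for the MSI signature class: a 1-bp T deletion in a T tract."""
        return (
            self.kind == "del"
            and self.size == 1
            and self.bases == "T"
            and self.repeat_context == "mononucleotide"
            and self.tract_base == "T"
        )


@dataclass(frozen=True)
class GeneRecurrence:
    """Recurrence-test result for one gene/tract across an MSI cohort."""

    gene: str
    tract: HomopolymerTract | None
    k: int
    n: int
    background_rate: float
    p_raw: float
    p_bonferroni: float
    family_size: int


def scan_homopolymers(
    sequences: Mapping[str, str],
    min_length: int = 5,
    base: str | None = None,
) -> list[HomopolymerTract]:
    """All maximal single-base runs of at least ``min_length``.

    ``N`` (or any non-ACGT symbol) breaks runs and never forms a tract.
    Runs touching sequence ends count as maximal.
    """
    if min_length < 2:
        raise ParameterError("minimum tract length must be >= 2")
    out: list[HomopolymerTract] = []
    for chrom in sequences:
        seq = sequences[chrom].upper()
        pos = 0
        for b, group in itertools.groupby(seq):
            run = sum(1 for _ in group)
            if run >= min_length and b in "ACGT" and (base is None or b == base):
                out.append(HomopolymerTract(chrom, pos, pos + run, b))
            pos += run
    return out


def tract_index(tracts: Iterable[HomopolymerTract]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees with tract payloads."""
    trees: dict[str, IntervalTree] = {}
    for t in tracts:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t)
    return trees


def classify_indel_context(
    chrom: str,
    pos0: int,
    kind: str,
    bases: str,
    tracts: Mapping[str, IntervalTree],
    sample: str | None = None,
) -> IndelContextCall:
    """Classify a left-aligned indel against a homopolymer tract index.

    A mononucleotide-tract assignment requires the inserted/deleted bases to
    be a run of the tract base and the left-aligned position to fall inside
    the tract (for insertions, immediately at or inside its span).
    """
    if kind not in ("ins", "del"):
        raise ParameterError(f"indel kind must be ins/del, got {kind!r}")
    if not bases or any(b not in "ACGT" for b in bases):
        raise ParameterError(f"indel bases must be non-empty ACGT, got {bases!r}")
    tract = None
    if len(set(bases)) == 1:
        tree = tracts.get(chrom)
        if tree is not None:
            for iv in sorted(tree.overlap(pos0, pos0 + 1)):
                if iv.data.base == bases[0]:
                    tract = iv.data
                    break
    if tract is not None:
        return IndelContextCall(
            chrom, pos0, kind, len(bases), bases, "mononucleotide",
            tract.base, tract.length, tract, sample,
        )
    return IndelContextCall(
        chrom, pos0, kind, len(bases), bases, "non-repeat", None, None, None, sample
    )


def msi_summary(calls: Sequence[IndelContextCall]) -> dict:
    """Cohort-level MSI signature summary.

    Reports the fraction of somatic indels in the signature class (1-bp T
    deletions in mononucleotide repeats), the indel size spectrum, the
    fraction of affected tracts stratified by tract length, and per-
    chromosome counts for assessing spatial dispersion.
    """
    if not calls:
        return {
            "n_indels": 0,
            "signature_fraction": None,
            "size_distribution": {},
            "affected_tracts_by_length": {},
            "per_chromosome": {},
            "warning": "empty indel set",
        }
    n = len(calls)
    sizes: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    by_len: dict[int, set] = {}
    n_sig = 0
    for c in calls:
        key = f"{c.kind}{c.size}"
        sizes[key] = sizes.get(key, 0) + 1
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
        if c.is_signature:
            n_sig += 1
        if c.tract is not None:
            by_len.setdefault(c.tract_length, set()).add(
                (c.tract.chrom, c.tract.start)
            )
    return {
        "n_indels": n,
        "signature_fraction": n_sig / n,
        "size_distribution": dict(sorted(sizes.items())),
        "affected_tracts_by_length": {
            length: len(tracts) for length, tracts in sorted(by_len.items())
        },
        "per_chromosome": dict(sorted(per_chrom.items())),
    }


def homopolymer_background_rate(
    per_sample_calls: Mapping[str, Sequence[IndelContextCall]],
    tracts: Sequence[HomopolymerTract],
    length: int,
    base: str = "T",
) -> tuple[float, int]:
    """Pooled per-(tract, sample) signature-deletion rate for one tract length.

    ``p = mutated (tract, sample) pairs / (n_tracts * n_samples)`` where a
    pair counts as mutated if at least one signature-class deletion maps to
    the tract in that sample (multiple deletions count once).  Returns
    ``(p, n_tracts)``.
    """
    eligible = [t for t in tracts if t.base == base and t.length == length]
    if not eligible:
        raise ParameterError(f"no tracts of base {base} and length {length}")
    if not per_sample_calls:
        raise ParameterError("at least one MSI-positive sample is required")
    keys = {(t.chrom, t.start) for t in eligible}
    mutated_pairs = set()
    for sample, calls in per_sample_calls.items():
        for c in calls:
            if (
                c.is_signature
                and c.tract is not None
                and c.tract_length == length
                and (c.tract.chrom, c.tract.start) in keys
            ):
                mutated_pairs.add((sample, c.tract.chrom, c.tract.start))
    n_tracts = len(eligible)
    rate = len(mutated_pairs) / (n_tracts * len(per_sample_calls))
    return rate, n_tracts


def recurrence_test(
    k: int,
    n: int,
    p: float,
    family_size: int = 1,
    gene: str = "",
    tract: HomopolymerTract | None = None,
) -> GeneRecurrence:
    """One-sided exact binomial recurrence test with Bonferroni correction.

    Tests whether ``k`` of ``n`` MSI-positive samples carrying a deletion in
    one tract exceeds the background per-tract rate ``p``:
    ``p_raw = P(X >= k), X ~ Binomial(n, p)``; ``p_bonferroni =
    min(1, family_size * p_raw)``.
    """
    if not 0 <= k <= n:
        raise ParameterError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p < 1:
        raise ParameterError(f"background rate must be in (0,1), got {p}")
    if family_size < 1:
        raise ParameterError("Bonferroni family size must be >= 1")
    p_raw = float(stats.binom.sf(k - 1, n, p))
    return GeneRecurrence(
        gene=gene,
        tract=tract,
        k=k,
        n=n,
        background_rate=p,
        p_raw=p_raw,
        p_bonferroni=min(1.0, family_size * p_raw),
        family_size=family_size,
    )


def gene_recurrence_table(
    per_sample_calls: Mapping[str, Sequence[IndelContextCall]],
    tracts: Sequence[HomopolymerTract],
    length: int,
    base: str = "T",
    background_rate: float | None = None,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Recurrence test for every gene-overlapping tract of one length class.

    Background rate defaults to the pooled cohort estimate for this tract
    length; the Bonferroni family defaults to the number of tracts of this
    length (each tested tract is one member of the family).
    """
    eligible = [t for t in tracts if t.base == base and t.length == length]
    if background_rate is None:
        background_rate, n_tracts = homopolymer_background_rate(
            per_sample_calls, tracts, length, base
        )
    else:
        n_tracts = len(eligible)
    if not 0 < background_rate < 1:
        raise ParameterError(
            f"degenerate background rate {background_rate} for length {length}"
        )
    m = family_size if family_size is not None else n_tracts
    n_samples = len(per_sample_calls)
    rows = []
    for t in eligible:
        carriers = set()
        for sample, calls in per_sample_calls.items():
            for c in calls:
                if (
                    c.is_signature
                    and c.tract is not None
                    and (c.tract.chrom, c.tract.start) == (t.chrom, t.start)
                ):
                    carriers.add(sample)
        k = len(carriers)
        gene = t.genes[0] if t.genes else f"{t.chrom}:{t.start}-{t.end}"
        res = recurrence_test(k, n_samples, background_rate, m, gene=gene, tract=t)
        rows.append(
            {
                "gene": gene,
                "chrom": t.chrom,
                "tract_start": t.start,
                "tract_end": t.end,
                "tract_length": t.length,
                "k": k,
                "n": n_samples,
                "p_bg": background_rate,
                "p_raw": res.p_raw,
                "p_bonferroni": res.p_bonferroni,
                "m": m,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "tract_start", "tract_end", "tract_length",
            "k", "n", "p_bg", "p_raw", "p_bonferroni", "m",
        ],
    )
    return frame.sort_values("p_raw", kind="mergesort").reset_index(drop=True)


def annotate_tract_genes(
    tracts: Sequence[HomopolymerTract],
    gene_trees: Mapping[str, IntervalTree],
) -> list[HomopolymerTract]:
    """Attach overlapping gene ids to each tract."""
    out = []
    for t in tracts:
        tree = gene_trees.get(t.chrom)
        genes: tuple[str, ...] = ()
        if tree is not None:
            genes = tuple(sorted(iv.data.gene_id for iv in tree.overlap(t.start, t.end)))
        out.append(
            HomopolymerTract(t.chrom, t.start, t.end, t.base, genes)
        )
    return out
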