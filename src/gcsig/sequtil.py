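"""Small sequence utilities: complements, pyrimidine-strand collapse, mutation classes.

Every single-nucleotide variant is reported on the strand carrying the
pyrimidine reference base (C or T); a G>T call is therefore the same event
as C>A read from the opposite strand.  This collapse yields the six
canonical substitution classes used throughout the package.
"""

from __future__ import annotations

from .errors import ParameterError

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine-collapsed substitution classes.
MUTATION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

PYRIMIDINES = frozenset("CT")
BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (ACGTN alphabet)."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ParameterError(f"non-ACGTN base in sequence: {exc}") from exc


def collapse_snv(ref: str, alt: str, context: str = "") -> tuple[str, str]:
    """Collapse an SNV onto the pyrimidine reference strand.

    Parameters
    ----------
    ref, alt
        Single reference and alternate bases, upper-case ACGT, ``ref != alt``.
    context
        Reference sequence window centred on the mutated base (odd length,
        e.g. the +/-2 bp pentamer).  May be empty.

    Returns
    -------
    (mutation_class, collapsed_context)
        ``mutation_class`` is one of :data:`MUTATION_CLASSES`; the context is
        reverse-complemented together with the alleles when the reference
        base is a purine.
    """
    ref = ref.upper()
    alt = alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise ParameterError(f"alleles must be single ACGT bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ParameterError("ref and alt alleles are identical")
    if context:
        context = context.upper()
        if len(context) % 2 != 1:
            raise ParameterError("context must have odd length (centred window)")
        centre = context[len(context) // 2]
        if centre != "N" and centre != ref:
            raise ParameterError(
                f"context centre {centre!r} does not match ref allele {ref!r}"
            )
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}", context
    return f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}", revcomp(context)


def max_kmer_count(seq: str, k: int = 5) -> int:
    """Highest occurrence count of any k-mer in ``seq``, counting overlaps."""
    if len(seq) < k:
        return 0
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return max(counts.values())
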