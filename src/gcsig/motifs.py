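"""Positional sequence-context motifs around a mutated base.

A motif fixes one or more flanking bases at offsets -2, -1, +1, +2 relative
to the (pyrimidine-collapsed) mutated base.  The conventional XpCpY notation
denotes the immediate 5' and 3' neighbours of a mutated C; ``Motif`` also
covers the two-position extensions used by the enrichment scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError

FLANK_OFFSETS = (-2, -1, 1, 2)


@dataclass(frozen=True)
class Motif:
    """Fixed bases at flank offsets around the mutated base.

    ``bases`` maps offsets in {-2, -1, +1, +2} to a required base.  The
    mutated base itself is not part of the motif; windows are matched after
    pyrimidine collapse, so the centre base is implied by the mutation class.
    """

    bases: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen = set()
        for off, base in self.bases:
            if off not in FLANK_OFFSETS:
                raise ParameterError(f"motif offset {off} outside +/-2 bp flanks")
            if base not in "ACGT":
                raise ParameterError(f"motif base {base!r} not in ACGT")
            if off in seen:
                raise ParameterError(f"duplicate motif offset {off}")
            seen.add(off)
        object.__setattr__(self, "bases", tuple(sorted(self.bases)))

    @classmethod
    def flanks(cls, five: str | None = None, three: str | None = None) -> "Motif":
        """Motif on the immediate neighbours, e.g. ``Motif.flanks('T', 'A')``."""
        pairs = []
        if five is not None:
            pairs.append((-1, five))
        if three is not None:
            pairs.append((1, three))
        return cls(tuple(pairs))

    def extended(self, offset: int, base: str) -> "Motif":
        """New motif with one extra fixed position."""
        return Motif(self.bases + ((offset, base),))

    @property
    def offsets(self) -> tuple[int, ...]:
        return tuple(off for off, _ in self.bases)

    def matches(self, window: str) -> bool:
        """Test a collapsed context window (odd length >= 5, centre = mutated base).

        Truncated windows (shorter flanks near contig ends) never match a
        motif position that falls outside them.
        """
        centre = len(window) // 2
        for off, base in self.bases:
            i = centre + off
            if i < 0 or i >= len(window):
                return False
            if window[i] != base:
                return False
        return True

    def label(self, mutation_class: str = "C>A") -> str:
        """Human-readable label, XpYpZ style for pure +/-1 motifs.

        >>> Motif.flanks('T', 'A').label('C>A')
        'TpCpA'
        """
        lookup = dict(self.bases)
        centre = mutation_class[0]
        if set(lookup) <= {-1, 1}:
            return f"{lookup.get(-1, 'N')}p{centre}p{lookup.get(1, 'N')}"
        parts = []
        for off in FLANK_OFFSETS:
            if off in lookup:
                parts.append(f"{off:+d}{lookup[off]}")
        return f"{centre}[" + ",".join(parts) + "]"
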