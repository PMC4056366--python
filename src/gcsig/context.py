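"""Sequence-context motif enrichment around somatic SNVs.

Somatic SNVs of one collapsed class are compared with germline SNVs of the
same class: for a candidate motif (fixed flanking bases within +/-2 bp of
the mutated base) the 2x2 table (somatic vs germline) x (motif vs no motif)
yields an odds ratio and a Pearson chi-square p-value.  The scan first
tests all single-flank motifs at the immediate neighbours and then extends
the significant ones by one additional fixed position, reporting motifs
that survive a Bonferroni correction over everything tested for the class.
Typical hits in gastric tumors are CpCpT / TpCpA for oxidative C>A damage
and CpG / GpC for deamination-driven C>T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import IntegrityError, ParameterError
from .motifs import FLANK_OFFSETS, Motif
from .sequtil import BASES, revcomp


@dataclass(frozen=True)
class ContextWindow:
    """Collapsed reference window centred on a mutated pyrimidine."""

    window: str  # up to 2 flanking bases each side + centre
    centre_offset: int  # index of the mutated base within ``window``
    truncated: bool  # True when the contig end clipped a flank

    @property
    def centre(self) -> str:
        return self.window[self.centre_offset]


def extract_context(
    chrom_seq: str,
    pos0: int,
    ref: str,
    alt: str,
    flank: int = 2,
) -> ContextWindow:
    """Collapsed +/-``flank`` bp window around an SNV.

    The stored window keeps up to ``flank`` bases each side (truncated and
    flagged at contig ends); purine-reference SNVs are reverse-complemented
    so the centre base is always the collapsed pyrimidine.
    """
    if not 0 <= pos0 < len(chrom_seq):
        raise ParameterError(f"position {pos0} outside contig of length {len(chrom_seq)}")
    if chrom_seq[pos0].upper() != ref.upper():
        raise IntegrityError(
            f"reference base {chrom_seq[pos0]!r} at {pos0} does not match "
            f"ref allele {ref!r}"
        )
    lo = max(0, pos0 - flank)
    hi = min(len(chrom_seq), pos0 + flank + 1)
    raw = chrom_seq[lo:hi].upper()
    centre = pos0 - lo
    truncated = (pos0 - lo) < flank or (hi - pos0 - 1) < flank
    if ref.upper() in "AG":
        raw = revcomp(raw)
        centre = len(raw) - 1 - centre
    return ContextWindow(window=raw, centre_offset=centre, truncated=truncated)


@dataclass(frozen=True)
class EnrichmentResult:
    motif: Motif
    label: str
    mutation_class: str
    somatic_with: int
    somatic_without: int
    germline_with: int
    germline_without: int
    odds_ratio: float
    chi2: float
    p_value: float
    p_adjusted: float | None = None
    haldane_corrected: bool = False


def _count_matches(windows: Sequence[ContextWindow], motif: Motif) -> int:
    return sum(
        1
        for w in windows
        if motif.matches(_pad(w))
    )


def _pad(w: ContextWindow) -> str:
    """Pad a truncated window with 'N' so offsets align on the centre."""
    left = 2 - w.centre_offset
    right = 2 - (len(w.window) - w.centre_offset - 1)
    return "N" * left + w.window + "N" * right


def motif_odds_ratio(
    somatic_windows: Sequence[ContextWindow],
    germline_windows: Sequence[ContextWindow],
    motif: Motif,
    mutation_class: str,
) -> EnrichmentResult:
    """Odds ratio and chi-square for one motif (somatic vs germline).

    Zero cells receive the Haldane-Anscombe +0.5 correction for the odds
    ratio (flagged in the result); the chi-square uses the raw table.
    """
    if not somatic_windows or not germline_windows:
        raise ParameterError("window sets must be non-empty")
    a = _count_matches(somatic_windows, motif)
    b = len(somatic_windows) - a
    c = _count_matches(germline_windows, motif)
    d = len(germline_windows) - c
    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa / bb) / (cc / dd)
    if min(a + b, c + d, a + c, b + d) == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return EnrichmentResult(
        motif=motif,
        label=motif.label(mutation_class),
        mutation_class=mutation_class,
        somatic_with=a,
        somatic_without=b,
        germline_with=c,
        germline_without=d,
        odds_ratio=float(odds_ratio),
        chi2=float(chi2),
        p_value=float(p),
        haldane_corrected=corrected,
    )


def scan_enriched_motifs(
    somatic_windows: Sequence[ContextWindow],
    germline_windows: Sequence[ContextWindow],
    mutation_class: str,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Bonferroni-controlled scan over single-flank motifs and extensions.

    Stage 1 tests the eight single-base motifs at offsets -1 and +1; motifs
    significant after correction are extended by one further fixed position
    (any remaining offset in {-2, -1, +1, +2}) in stage 2.  The returned
    list contains results passing the adjusted alpha, ranked by descending
    odds ratio; the Bonferroni family is everything tested for this class.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    tested: list[EnrichmentResult] = []
    stage1: list[EnrichmentResult] = []
    for off in (-1, 1):
        for base in BASES:
            res = motif_odds_ratio(
                somatic_windows, germline_windows, Motif(((off, base),)),
                mutation_class,
            )
            tested.append(res)
            stage1.append(res)
    m1 = len(tested)
    seeds = [r for r in stage1 if r.p_value * m1 <= alpha and r.odds_ratio > 1]
    seen = {r.motif for r in tested}
    for seed in seeds:
        used = set(seed.motif.offsets)
        for off in FLANK_OFFSETS:
            if off in used:
                continue
            for base in BASES:
                motif = seed.motif.extended(off, base)
                if motif in seen:
                    continue
                seen.add(motif)
                tested.append(
                    motif_odds_ratio(
                        somatic_windows, germline_windows, motif, mutation_class
                    )
                )
    m = len(tested)
    out = []
    for r in tested:
        p_adj = min(1.0, r.p_value * m)
        if p_adj <= alpha and r.odds_ratio > 1:
            out.append(
                EnrichmentResult(
                    **{
                        **r.__dict__,
                        "p_adjusted": p_adj,
                    }
                )
            )
    return sorted(out, key=lambda r: -r.odds_ratio)
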