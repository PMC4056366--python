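"""Six-class mutational spectra, somatic-vs-germline bias, and region tests.

The spectrum of a call set is the distribution of its SNVs over the six
pyrimidine-collapsed substitution classes.  The bias of class ``i`` is
``b_i = (s_i - g_i) / g_i`` where ``s_i`` and ``g_i`` are the somatic and
germline class frequencies: germline variation acts as the internal control
for sequencing/composition artefacts, so a positive bias flags a somatic
mutational process (e.g. oxidative C>A damage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ParameterError, UndefinedBiasError
from .regions import Gene, gene_trees
from .sequtil import MUTATION_CLASSES, collapse_snv


def classify_snv(ref: str, alt: str, context: str = "") -> tuple[str, str]:
    """Pyrimidine-collapsed mutation class and collapsed context window."""
    return collapse_snv(ref, alt, context)


@dataclass(frozen=True)
class SpectrumTable:
    """Per-class somatic and germline counts/frequencies for one stratum."""

    stratum: str
    somatic_counts: Mapping[str, int]
    germline_counts: Mapping[str, int]

    @property
    def n_somatic(self) -> int:
        return sum(self.somatic_counts.values())

    @property
    def n_germline(self) -> int:
        return sum(self.germline_counts.values())

    def frequencies(self, origin: str) -> dict[str, float]:
        counts = self.somatic_counts if origin == "somatic" else self.germline_counts
        total = sum(counts.values())
        if total == 0:
            raise ParameterError(f"no {origin} SNVs in stratum {self.stratum!r}")
        return {c: counts.get(c, 0) / total for c in MUTATION_CLASSES}

    def to_frame(self) -> pd.DataFrame:
        s = self.frequencies("somatic")
        g = self.frequencies("germline")
        return pd.DataFrame(
            {
                "class": list(MUTATION_CLASSES),
                "s_count": [self.somatic_counts.get(c, 0) for c in MUTATION_CLASSES],
                "s_freq": [s[c] for c in MUTATION_CLASSES],
                "g_count": [self.germline_counts.get(c, 0) for c in MUTATION_CLASSES],
                "g_freq": [g[c] for c in MUTATION_CLASSES],
            }
        )


def spectrum_from_classes(
    somatic: Iterable[str], germline: Iterable[str], stratum: str = "genome-wide"
) -> SpectrumTable:
    """Tally collapsed class labels into a :class:`SpectrumTable`."""
    som: dict[str, int] = {c: 0 for c in MUTATION_CLASSES}
    germ: dict[str, int] = {c: 0 for c in MUTATION_CLASSES}
    for c in somatic:
        som[c] += 1
    for c in germline:
        germ[c] += 1
    return SpectrumTable(stratum, som, germ)


@dataclass(frozen=True)
class BiasResult:
    stratum: str
    bias: Mapping[str, float]
    p_values: Mapping[str, float]
    chi2: Mapping[str, float]

    def stars(self, cls: str) -> str:
        p = self.p_values[cls]
        if p < 0.01:
            return "**"
        if p < 0.1:
            return "*"
        return ""


def compute_bias(
    spectrum: SpectrumTable, continuity_correction: bool = False
) -> BiasResult:
    """Per-class bias (s_i - g_i)/g_i with a 2x2 chi-square test per class.

    The test contrasts (class vs all other classes) x (somatic vs germline)
    counts.  A class with zero germline frequency but somatic events has an
    undefined bias and raises :class:`UndefinedBiasError`.
    """
    s = spectrum.frequencies("somatic")
    g = spectrum.frequencies("germline")
    bias: dict[str, float] = {}
    pvals: dict[str, float] = {}
    chi2s: dict[str, float] = {}
    for cls in MUTATION_CLASSES:
        if g[cls] == 0:
            if s[cls] > 0:
                raise UndefinedBiasError(
                    f"class {cls}: somatic frequency {s[cls]:.4g} but zero "
                    "germline frequency"
                )
            bias[cls] = 0.0
            pvals[cls] = 1.0
            chi2s[cls] = 0.0
            continue
        bias[cls] = (s[cls] - g[cls]) / g[cls]
        a = spectrum.somatic_counts.get(cls, 0)
        b = spectrum.n_somatic - a
        c = spectrum.germline_counts.get(cls, 0)
        d = spectrum.n_germline - c
        table = np.array([[a, b], [c, d]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            chi2s[cls], pvals[cls] = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(
                table, correction=continuity_correction
            )
            chi2s[cls], pvals[cls] = float(chi2), float(p)
    return BiasResult(spectrum.stratum, bias, pvals, chi2s)


def region_excess_test(
    somatic_positions: Sequence[tuple[str, int]],
    germline_positions: Sequence[tuple[str, int]],
    region_trees: Mapping[str, IntervalTree],
    continuity_correction: bool = False,
) -> dict:
    """Somatic-vs-germline excess of variants inside a region set.

    Builds the 2x2 table (somatic vs germline) x (in-region vs out) over
    0-based positions with half-open membership, and returns the odds ratio
    with a Pearson chi-square p-value.
    """
    if not region_trees:
        raise ParameterError("empty region set")

    def split(positions: Sequence[tuple[str, int]]) -> tuple[int, int]:
        inside = 0
        for chrom, pos0 in positions:
            tree = region_trees.get(chrom)
            if tree is not None and tree.overlaps_point(pos0):
                inside += 1
        return inside, len(positions) - inside

    a, b = split(somatic_positions)  # somatic in/out
    c, d = split(germline_positions)  # germline in/out
    corrected = False
    aa, bb, cc, dd = a, b, c, d
    if 0 in (a, b, c, d):
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        corrected = True
    odds_ratio = (aa / bb) / (cc / dd)
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return {
        "somatic_in": a,
        "somatic_out": b,
        "germline_in": c,
        "germline_out": d,
        "odds_ratio": float(odds_ratio),
        "chi2": float(chi2),
        "p_value": float(p),
        "haldane_corrected": corrected,
    }


def strand_bias_test(
    somatic_snvs: Sequence[tuple[str, int, str, str]],
    genes: Sequence[Gene],
) -> pd.DataFrame:
    """Transcribed- vs untranscribed-strand counts per class, chi-square vs 50/50.

    Each genic SNV is collapsed to its pyrimidine representation; the strand
    carrying the pyrimidine is compared with the gene's template (transcribed)
    strand.  SNVs outside genes are excluded, and SNVs overlapping genes on
    both strands are ambiguous: they are excluded and tallied in the
    ``ambiguous`` attribute of the returned frame.
    """
    trees = gene_trees(genes)
    counts: dict[str, list[int]] = {c: [0, 0] for c in MUTATION_CLASSES}
    ambiguous = 0
    genic = 0
    for chrom, pos0, ref, alt in somatic_snvs:
        tree = trees.get(chrom)
        if tree is None:
            continue
        strands = {iv.data.strand for iv in tree.overlap(pos0, pos0 + 1)}
        if not strands:
            continue
        if len(strands) > 1:
            ambiguous += 1
            continue
        genic += 1
        gene_strand = strands.pop()
        cls, _ = collapse_snv(ref, alt)
        pyr_strand = "+" if ref in "CT" else "-"
        transcribed_strand = "-" if gene_strand == "+" else "+"
        idx = 0 if pyr_strand == transcribed_strand else 1
        counts[cls][idx] += 1
    rows = []
    for cls in MUTATION_CLASSES:
        t, u = counts[cls]
        if t + u == 0:
            chi2, p = float("nan"), float("nan")
        else:
            chi2, p = stats.chisquare([t, u])
        rows.append(
            {
                "class": cls,
                "transcribed": t,
                "untranscribed": u,
                "chi2": float(chi2),
                "p_value": float(p),
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["ambiguous"] = ambiguous
    frame.attrs["genic"] = genic
    if genic == 0:
        frame.attrs["warning"] = "no genic SNVs"
    return frame
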