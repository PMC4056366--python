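"""Screening of non-human reads for a tumor-associated microbiome.

Reads failing to map to the human genome and aligning to microbial genomes
are filtered in three steps: a low-complexity filter (discard reads where
any 5-mer occurs more than three times, counting overlaps), a window-
evidence requirement (reads pooled over strains must hit more than four
distinct 1 kbp genome windows and include at least one uniquely mapping
read), and subtraction of species seen in the matched blood control
(likely reagent contamination).  Relative pathogen load is estimated from
sequencing coverage under the assumption of clonal populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import ParameterError
from .sequtil import max_kmer_count

KMER = 5
MAX_KMER_OCCURRENCES = 3
MIN_DISTINCT_WINDOWS = 4  # retained requires strictly more than this
WINDOW_BP = 1000


@dataclass(frozen=True)
class ComplexityDecision:
    keep: bool
    max_kmer_count: int
    short: bool = False


def low_complexity_filter(read: str) -> ComplexityDecision:
    """Keep a read unless some 5-mer occurs more than three times.

    Occurrences are counted with overlaps.  Reads shorter than 5 bp carry
    no 5-mer evidence; they are kept but flagged ``short``.
    """
    read = read.upper()
    if len(read) < KMER:
        return ComplexityDecision(keep=True, max_kmer_count=0, short=True)
    top = max_kmer_count(read, KMER)
    return ComplexityDecision(keep=top <= MAX_KMER_OCCURRENCES, max_kmer_count=top)


@dataclass(frozen=True)
class SpeciesEvidence:
    species: str
    reads: int
    distinct_windows: int
    has_unique_matches: bool
    in_control: bool

    @property
    def retained(self) -> bool:
        return (
            self.distinct_windows > MIN_DISTINCT_WINDOWS
            and self.has_unique_matches
            and not self.in_control
        )


def species_evidence(
    alignments: pd.DataFrame,
    control_alignments: pd.DataFrame | None,
    genome_sizes: Mapping[str, int],
    apply_complexity_filter: bool = True,
) -> pd.DataFrame:
    """Per-species evidence table and retention decision.

    ``alignments`` columns: read_id, sequence, species, strain, position,
    unique_flag.  Strains are pooled by species before counting; windows
    are fixed [i*1000, (i+1)*1000) tiles of the species genome.  A species
    is retained iff it hits more than four distinct windows, has at least
    one unique match, and is absent from the control.
    """
    required = {"read_id", "sequence", "species", "strain", "position", "unique_flag"}
    missing = required - set(alignments.columns)
    if missing:
        raise ParameterError(f"alignment table missing columns: {sorted(missing)}")
    table = alignments
    if apply_complexity_filter and len(table):
        keep = [low_complexity_filter(s).keep for s in table["sequence"]]
        table = table[pd.Series(keep, index=table.index)]
    control_species: set[str] = set()
    if control_alignments is not None and len(control_alignments):
        ctrl = control_alignments
        if apply_complexity_filter:
            ckeep = [low_complexity_filter(s).keep for s in ctrl["sequence"]]
            ctrl = ctrl[pd.Series(ckeep, index=ctrl.index)]
        control_species = set(ctrl["species"])
    rows = []
    for species, group in table.groupby("species", sort=True):
        if species not in genome_sizes:
            raise ParameterError(f"unknown genome size for species {species!r}")
        windows = set(int(p) // WINDOW_BP for p in group["position"])
        ev = SpeciesEvidence(
            species=str(species),
            reads=len(group),
            distinct_windows=len(windows),
            has_unique_matches=bool((group["unique_flag"] > 0).any()),
            in_control=species in control_species,
        )
        rows.append(
            {
                "species": ev.species,
                "reads": ev.reads,
                "windows": ev.distinct_windows,
                "unique": int(ev.has_unique_matches),
                "in_control": int(ev.in_control),
                "retained": int(ev.retained),
            }
        )
    return pd.DataFrame(
        rows, columns=["species", "reads", "windows", "unique", "in_control", "retained"]
    )


@dataclass(frozen=True)
class ConcentrationEstimate:
    species: str
    species_coverage: float
    species_genome_size: float
    host_coverage: float
    host_genome_size: float
    cell_ratio: float
    reading: str  # "genome_size_normalized" | "depth_ratio"


def estimate_concentration(
    species_coverage: float,
    species_genome_size: float,
    host_coverage: float,
    host_genome_size: float,
    species: str = "",
    depth_ratio: bool = False,
) -> ConcentrationEstimate:
    """Pathogen cells per host cell from relative sequencing coverage.

    Default reading: the total sequence yield attributable to a clonal
    population is proportional to cell count times genome size, so
    ``ratio = (cov_s / size_s) / (cov_h / size_h)`` — the genome-size
    normalisation makes the shared proportionality constant cancel.  The
    alternative ``depth_ratio`` reading treats per-base depth itself as
    proportional to cell count, giving ``ratio = cov_s / cov_h``; both are
    available because the coverage/cell-count relation can be read either
    way.  The reading used is recorded on the result.
    """
    for name, value in (
        ("species coverage", species_coverage),
        ("species genome size", species_genome_size),
        ("host coverage", host_coverage),
        ("host genome size", host_genome_size),
    ):
        if value <= 0:
            raise ParameterError(f"{name} must be > 0, got {value}")
    if depth_ratio:
        ratio = species_coverage / host_coverage
        reading = "depth_ratio"
    else:
        ratio = (species_coverage / species_genome_size) / (
            host_coverage / host_genome_size
        )
        reading = "genome_size_normalized"
    return ConcentrationEstimate(
        species=species,
        species_coverage=species_coverage,
        species_genome_size=species_genome_size,
        host_coverage=host_coverage,
        host_genome_size=host_genome_size,
        cell_ratio=float(ratio),
        reading=reading,
    )
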