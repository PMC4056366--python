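"""Synthetic genomes, variants, read support and auxiliary tables.

Every downstream stage of the toolkit is exercised against data produced
here, with complete ground truth.  The generator emulates the structure of
a paired tumor/normal whole-genome experiment in a gastric-cancer setting:

* a reference with planted homopolymer tracts (flank-protected, so the
  planted tract count equals the scannable count) and a gene/exon
  annotation covering a requested coding fraction;
* germline and somatic SNVs drawn from six-class signature mixtures, with
  per-class sequence-context multipliers (e.g. C>A inflated at TpCpA) and
  optionally exome-restricted classes (the deamination-style C>T signature
  that only appears in coding sequence);
* MSI-style single-base T deletions over poly-T tracts;
* per-site tumor/normal read support (depth, variant reads, strand split);
* DNA-PET style SV cluster tables and microbial alignment tables.

Internal coordinates are 0-based half-open; VCF emission is 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError, SizingError
from .io import VcfRecord
from .motifs import Motif
from .msi import HomopolymerTract
from .regions import Gene, exon_intervals, interval_trees, position_in
from .sequtil import COMPLEMENT, MUTATION_CLASSES

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class TractSpec:
    base: str
    length: int
    count: int


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic reference genome."""

    chrom_lengths: Mapping[str, int]
    base_composition: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    planted_tracts: tuple[TractSpec, ...] = ()
    exon_fraction: float = 0.03
    gene_count: int = 40
    seed: int = 0
    max_background_run: int | None = None

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ParameterError("at least one chromosome is required")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ParameterError(f"chromosome {name} has non-positive length")
        probs = [self.base_composition.get(b, 0.0) for b in "ACGT"]
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ParameterError("base composition must be probabilities summing to 1")
        for t in self.planted_tracts:
            if t.base not in "ACGT":
                raise ParameterError(f"tract base {t.base!r} not in ACGT")
            if t.length < 2:
                raise ParameterError("planted tract length must be >= 2")
            if t.count < 0:
                raise ParameterError("planted tract count must be >= 0")
        if not 0 < self.exon_fraction < 1:
            raise ParameterError("exon fraction must lie in (0, 1)")
        if self.gene_count < 1:
            raise ParameterError("gene count must be >= 1")

    @property
    def background_run_cap(self) -> int | None:
        """Longest background run permitted; below the shortest planted tract."""
        if self.max_background_run is not None:
            return self.max_background_run
        if self.planted_tracts:
            return min(t.length for t in self.planted_tracts) - 1
        return None


@dataclass(frozen=True)
class SignatureMixture:
    """Class mixture and context weighting for simulated SNVs and MSI indels."""

    somatic_class_probs: Mapping[str, float]
    germline_class_probs: Mapping[str, float]
    n_somatic: int = 0
    n_germline: int = 0
    context_multipliers: Mapping[str, tuple[tuple[Motif, float], ...]] = field(
        default_factory=dict
    )
    exome_only_classes: frozenset[str] = frozenset()
    msi_deletion_rate: float = 0.0
    msi_min_tract_length: int = 5
    msi_tract_base: str = "T"

    def validate(self) -> None:
        for name, probs in (
            ("somatic", self.somatic_class_probs),
            ("germline", self.germline_class_probs),
        ):
            unknown = set(probs) - set(MUTATION_CLASSES)
            if unknown:
                raise ParameterError(f"unknown {name} classes: {sorted(unknown)}")
            vals = list(probs.values())
            if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
                raise ParameterError(f"{name} class probabilities must sum to 1")
        for cls, pairs in self.context_multipliers.items():
            if cls not in MUTATION_CLASSES:
                raise ParameterError(f"context multiplier for unknown class {cls}")
            for _, mult in pairs:
                if mult <= 0:
                    raise ParameterError("context multipliers must be > 0")
        if not 0.0 <= self.msi_deletion_rate <= 1.0:
            raise ParameterError("MSI deletion rate must lie in [0, 1]")
        if self.n_somatic < 0 or self.n_germline < 0:
            raise ParameterError("variant counts must be >= 0")
        if not self.exome_only_classes <= set(MUTATION_CLASSES):
            raise ParameterError("exome-only classes must be mutation classes")


@dataclass(frozen=True)
class PlantedVariant:
    """Ground-truth record for one planted variant."""

    chrom: str
    pos0: int  # 0-based; for deletions, the first deleted base
    ref: str
    alt: str
    kind: str  # "snv" | "del"
    vclass: str  # mutation class for SNVs, e.g. "C>A"; "del1T" for MSI dels
    context: str  # collapsed +/-2 bp window (SNVs)
    region: str  # "exome" | "genome"
    origin: str  # "somatic" | "germline"
    tract_id: str | None = None

    def to_vcf(self, sequences: Mapping[str, str]) -> VcfRecord:
        """VCF-style record (1-based, anchored for deletions)."""
        if self.kind == "snv":
            return VcfRecord(
                self.chrom, self.pos0 + 1, self.ref, self.alt,
                genotype=(self.ref, self.alt),
            )
        anchor = sequences[self.chrom][self.pos0 - 1]
        ref = anchor + self.ref
        return VcfRecord(
            self.chrom, self.pos0, ref, anchor, genotype=(ref, anchor)
        )


@dataclass
class SimulatedReference:
    spec: GenomeSpec
    sequences: dict[str, str]
    genes: list[Gene]
    tracts: list[HomopolymerTract]

    @property
    def exons(self) -> list[tuple[str, int, int]]:
        return exon_intervals(self.genes)


@dataclass
class SimulatedVariants:
    germline: list[PlantedVariant]
    somatic: list[PlantedVariant]

    @property
    def all(self) -> list[PlantedVariant]:
        return self.germline + self.somatic

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(v) for v in self.all])

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(v) for v in self.all], fh, indent=1)


# ---------------------------------------------------------------------------
# Reference generation


def _break_long_runs(
    codes: np.ndarray, cap: int, bases: set[int], rng: np.random.Generator
) -> None:
    """Replace bases so no run of a base in ``bases`` exceeds ``cap`` (in place)."""
    n = len(codes)
    if n == 0:
        return
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for s, e in zip(starts, ends):
        base = codes[s]
        if e - s > cap and base in bases:
            for pos in range(s + cap, e, cap + 1):
                others = [c for c in range(4) if c != base]
                codes[pos] = others[rng.integers(0, 3)]


def _sample_flank(base_code: int, comp: np.ndarray, rng: np.random.Generator) -> int:
    """A base drawn from the composition, excluding ``base_code``."""
    weights = comp.copy()
    weights[base_code] = 0.0
    total = weights.sum()
    if total <= 0:
        weights = np.ones(4)
        weights[base_code] = 0.0
        total = 3.0
    return int(rng.choice(4, p=weights / total))


def generate_reference(spec: GenomeSpec) -> SimulatedReference:
    """Build a seeded synthetic reference with planted tracts and annotation.

    Planted homopolymer tracts are flank-protected (their neighbours are
    forced to differ from the tract base) and background runs are broken
    below the shortest planted length, so a homopolymer scan at the planted
    length recovers exactly the planted tracts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    comp = np.array([spec.base_composition.get(b, 0.0) for b in "ACGT"])

    sequences: dict[str, np.ndarray] = {}
    for chrom, length in spec.chrom_lengths.items():
        codes = rng.choice(4, size=length, p=comp).astype(np.uint8)
        cap = spec.background_run_cap
        if cap is not None and cap >= 1:
            if spec.max_background_run is not None:
                capped_bases = set(range(4))  # explicit cap applies to every base
            else:
                capped_bases = {_CODE[t.base] for t in spec.planted_tracts}
            _break_long_runs(codes, cap, capped_bases, rng)
        sequences[chrom] = codes

    # --- plant tracts (flank-protected, non-overlapping)
    tracts: list[HomopolymerTract] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_lengths}
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_probs = lengths / lengths.sum()
    for tspec in spec.planted_tracts:
        for _ in range(tspec.count):
            placed = False
            for _attempt in range(2000):
                chrom = chroms[int(rng.choice(len(chroms), p=chrom_probs))]
                clen = spec.chrom_lengths[chrom]
                if tspec.length + 2 > clen:
                    raise SizingError(
                        f"tract of length {tspec.length} does not fit on {chrom}"
                    )
                start = int(rng.integers(1, clen - tspec.length - 1))
                span = (start - 1, start + tspec.length + 1)
                if any(s < span[1] and span[0] < e for s, e in occupied[chrom]):
                    continue
                codes = sequences[chrom]
                bcode = _CODE[tspec.base]
                codes[start : start + tspec.length] = bcode
                codes[start - 1] = _sample_flank(bcode, comp, rng)
                codes[start + tspec.length] = _sample_flank(bcode, comp, rng)
                occupied[chrom].append(span)
                tracts.append(
                    HomopolymerTract(chrom, start, start + tspec.length, tspec.base)
                )
                placed = True
                break
            if not placed:
                raise SizingError(
                    f"could not place {tspec.count} tracts of length "
                    f"{tspec.length} on the requested genome"
                )

    seq_strings = {
        chrom: _BASES[codes].tobytes().decode("ascii")
        for chrom, codes in sequences.items()
    }

    genes = _place_genes(spec, rng)
    tracts = sorted(tracts, key=lambda t: (t.chrom, t.start))
    return SimulatedReference(spec, seq_strings, genes, tracts)


def _place_genes(spec: GenomeSpec, rng: np.random.Generator) -> list[Gene]:
    total = sum(spec.chrom_lengths.values())
    target_exon_bp = spec.exon_fraction * total
    exon_bp_per_gene = max(30, int(target_exon_bp / spec.gene_count))
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_probs = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[Gene] = []
    for i in range(spec.gene_count):
        n_exons = int(rng.integers(1, 4))
        exon_sizes = np.maximum(
            10, rng.multinomial(exon_bp_per_gene, np.ones(n_exons) / n_exons)
        )
        intron = max(20, exon_bp_per_gene // 4)
        span = int(exon_sizes.sum() + intron * (n_exons - 1))
        for _attempt in range(2000):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_probs))]
            clen = spec.chrom_lengths[chrom]
            if span + 2 >= clen:
                continue
            start = int(rng.integers(0, clen - span))
            if any(s < start + span and start < e for s, e in placed[chrom]):
                continue
            exons = []
            pos = start
            for size in exon_sizes:
                exons.append((pos, pos + int(size)))
                pos += int(size) + intron
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(
                    gene_id=f"gene{i + 1:04d}",
                    chrom=chrom,
                    start=start,
                    end=start + span,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            placed[chrom].append((start, start + span))
            break
        else:
            raise SizingError("could not place all genes; genome too small")
    return sorted(genes, key=lambda g: (g.chrom, g.start))


# ---------------------------------------------------------------------------
# Variant simulation


def _collapsed_window(seq: str, pos: int, flank: int = 2) -> str:
    lo = max(0, pos - flank)
    window = seq[lo : pos + flank + 1]
    if seq[pos] in "AG":
        window = "".join(COMPLEMENT[b] for b in reversed(window))
    return window


def _motif_match_mask(
    codes: np.ndarray, positions: np.ndarray, motif: Motif
) -> np.ndarray:
    """Vectorised motif match at collapsed windows around ``positions``."""
    is_pyr = (codes[positions] == 1) | (codes[positions] == 3)  # C or T
    match = np.ones(len(positions), dtype=bool)
    for off, base in motif.bases:
        bcode = _CODE[base]
        # pyrimidine site: reference neighbour at +off must equal base;
        # purine site: collapsed window is the reverse complement, so the
        # reference neighbour at -off must equal complement(base).
        fwd = codes[positions + off] == bcode
        rev = codes[positions - off] == _COMP_CODE[bcode]
        match &= np.where(is_pyr, fwd, rev)
    return match


def simulate_variants(
    reference: SimulatedReference,
    mixture: SignatureMixture,
    seed: int,
) -> SimulatedVariants:
    """Plant germline and somatic variants according to a signature mixture.

    Somatic SNVs are drawn class-by-class and placed on sites whose
    (pyrimidine-collapsed) reference base matches the class, weighted by the
    class's context multipliers; exome-restricted classes are confined to
    exons.  MSI indels are emitted as single-base deletions over eligible
    poly-T tracts, one Bernoulli trial per tract.  A class with no eligible
    site raises :class:`PlacementError` rather than silently undershooting.
    """
    mixture.validate()
    rng = np.random.default_rng(seed)

    chroms = list(reference.sequences)
    codes = {
        c: np.frombuffer(reference.sequences[c].encode("ascii"), dtype=np.uint8)
        for c in chroms
    }
    code_map = np.zeros(256, dtype=np.uint8)
    for b, i in _CODE.items():
        code_map[ord(b)] = i
    codes = {c: code_map[a] for c, a in codes.items()}

    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += len(codes[c])
    flat = np.concatenate([codes[c] for c in chroms])
    n_total = len(flat)

    # interior positions (full +/-2 flanks available on the same chromosome)
    interior = np.zeros(n_total, dtype=bool)
    for c in chroms:
        lo, hi = offsets[c], offsets[c] + len(codes[c])
        if hi - lo > 4:
            interior[lo + 2 : hi - 2] = True

    exon_trees = interval_trees(reference.exons)
    exome_mask = np.zeros(n_total, dtype=bool)
    for chrom, s, e in reference.exons:
        lo = offsets[chrom]
        exome_mask[lo + s : lo + e] = True

    collapsed_c = (flat == 1) | (flat == 2)  # C or G sites
    used = np.zeros(n_total, dtype=bool)

    def chrom_of(gpos: int) -> tuple[str, int]:
        for c in chroms:
            lo = offsets[c]
            if lo <= gpos < lo + len(codes[c]):
                return c, gpos - lo
        raise AssertionError("position outside genome")

    def place_class(
        cls: str, count: int, origin: str, weighted: bool
    ) -> list[PlantedVariant]:
        if count == 0:
            return []
        base_mask = collapsed_c if cls[0] == "C" else ~collapsed_c
        mask = base_mask & interior & ~used
        if origin == "somatic" and cls in mixture.exome_only_classes:
            mask = mask & exome_mask
        positions = np.flatnonzero(mask)
        weights = np.ones(len(positions))
        if weighted:
            # an infinite multiplier restricts the class to matching sites
            restrict: np.ndarray | None = None
            for motif, mult in mixture.context_multipliers.get(cls, ()):
                hit = _motif_match_mask(flat, positions, motif)
                if np.isinf(mult):
                    restrict = hit if restrict is None else (restrict | hit)
                else:
                    weights[hit] *= mult
            if restrict is not None:
                weights[~restrict] = 0.0
        eligible = weights > 0
        if eligible.sum() < count:
            raise PlacementError(
                f"only {int(eligible.sum())} eligible sites for class {cls} "
                f"({origin}), need {count}"
            )
        # Gumbel top-k = weighted sampling without replacement
        keys = np.full(len(positions), -np.inf)
        keys[eligible] = np.log(weights[eligible]) + rng.gumbel(
            size=int(eligible.sum())
        )
        chosen = positions[np.argpartition(-keys, count - 1)[:count]]
        used[chosen] = True
        out = []
        pyr = cls[0]
        alt_pyr = cls[2]
        for gpos in np.sort(chosen):
            chrom, pos = chrom_of(int(gpos))
            ref_base = "ACGT"[flat[gpos]]
            if ref_base == pyr:
                alt = alt_pyr
            else:
                alt = COMPLEMENT[alt_pyr]
            region = "exome" if position_in(exon_trees, chrom, pos) else "genome"
            out.append(
                PlantedVariant(
                    chrom=chrom,
                    pos0=pos,
                    ref=ref_base,
                    alt=alt,
                    kind="snv",
                    vclass=cls,
                    context=_collapsed_window(reference.sequences[chrom], pos),
                    region=region,
                    origin=origin,
                )
            )
        return out

    order = [c for c in MUTATION_CLASSES]
    somatic: list[PlantedVariant] = []
    germline: list[PlantedVariant] = []

    som_probs = np.array([mixture.somatic_class_probs.get(c, 0.0) for c in order])
    germ_probs = np.array([mixture.germline_class_probs.get(c, 0.0) for c in order])
    som_counts = (
        rng.multinomial(mixture.n_somatic, som_probs)
        if mixture.n_somatic
        else np.zeros(6, dtype=int)
    )
    germ_counts = (
        rng.multinomial(mixture.n_germline, germ_probs)
        if mixture.n_germline
        else np.zeros(6, dtype=int)
    )
    for cls, count in zip(order, som_counts):
        somatic.extend(place_class(cls, int(count), "somatic", weighted=True))
    for cls, count in zip(order, germ_counts):
        germline.extend(place_class(cls, int(count), "germline", weighted=False))

    # --- MSI single-base deletions over eligible poly-T tracts
    if mixture.msi_deletion_rate > 0:
        for i, tract in enumerate(reference.tracts):
            if tract.base != mixture.msi_tract_base:
                continue
            if tract.length < mixture.msi_min_tract_length or tract.start < 1:
                continue
            if rng.random() >= mixture.msi_deletion_rate:
                continue
            region = (
                "exome"
                if position_in(exon_trees, tract.chrom, tract.start)
                else "genome"
            )
            somatic.append(
                PlantedVariant(
                    chrom=tract.chrom,
                    pos0=tract.start,
                    ref=tract.base,
                    alt="",
                    kind="del",
                    vclass=f"del1{tract.base}",
                    context="",
                    region=region,
                    origin="somatic",
                    tract_id=f"tract{i:05d}",
                )
            )

    return SimulatedVariants(germline=germline, somatic=somatic)


# ---------------------------------------------------------------------------
# Read support


def simulate_read_support(
    variants: Sequence[PlantedVariant],
    mean_depth: float,
    dispersion: float,
    vaf: float,
    seed: int,
    normal_contamination_vaf: float = 0.0,
    sequences: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-site tumor and normal read support for planted variants.

    Depth is constant at ``mean_depth`` when ``dispersion`` is 0, otherwise
    gamma-Poisson with variance ``mean + dispersion * mean^2``.  Variant
    reads are Binomial(depth, VAF) and split 50/50 across strands; the
    normal sample sees germline variants at the same VAF and somatic
    variants at ``normal_contamination_vaf`` (default 0).
    """
    if mean_depth <= 0:
        raise ParameterError("mean depth must be > 0")
    if dispersion < 0:
        raise ParameterError("dispersion must be >= 0")
    if not 0.0 <= vaf <= 1.0:
        raise ParameterError("VAF must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for v in variants:
        if v.kind == "snv":
            pos, ref, alt = v.pos0 + 1, v.ref, v.alt
        else:
            if sequences is None:
                raise ParameterError(
                    "sequences are required to emit support for indels "
                    "(VCF-style anchored alleles)"
                )
            rec = v.to_vcf(sequences)
            pos, ref, alt = rec.pos, rec.ref, rec.alt
        for sample in ("tumor", "normal"):
            if sample == "tumor":
                site_vaf = vaf
            elif v.origin == "germline":
                site_vaf = vaf
            else:
                site_vaf = normal_contamination_vaf
            if dispersion == 0:
                depth = int(round(mean_depth))
            else:
                lam = rng.gamma(1.0 / dispersion, mean_depth * dispersion)
                depth = int(rng.poisson(lam))
            n_alt = int(rng.binomial(depth, site_vaf)) if depth > 0 else 0
            fwd = int(rng.binomial(n_alt, 0.5)) if n_alt > 0 else 0
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "sample": sample,
                    "depth": depth,
                    "alt_reads": n_alt,
                    "alt_fwd": fwd,
                    "alt_rev": n_alt - fwd,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Auxiliary fixtures: SV clusters and microbial alignments


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    genome_size: int
    n_reads: int
    n_windows: int
    strains: tuple[str, ...] = ("strain1",)
    low_complexity: bool = False
    unique_fraction: float = 1.0
    read_length: int = 76


@dataclass(frozen=True)
class AuxSpec:
    """Parameters for SV-cluster and microbial fixture tables."""

    chrom_lengths: Mapping[str, int]
    n_clusters: int = 50
    fraction_somatic: float = 0.2
    mean_cluster_size: float = 12.0
    anchor_size: tuple[int, int] = (1500, 4000)
    sv_types: tuple[str, ...] = ("deletion", "tandem duplication", "inversion")
    species: tuple[SpeciesSpec, ...] = ()
    control_species: tuple[str, ...] = ()


@dataclass
class AuxData:
    tumor_clusters: pd.DataFrame
    normal_clusters: pd.DataFrame
    microbial: pd.DataFrame
    control: pd.DataFrame
    genome_sizes: dict[str, int]


_CLUSTER_COLUMNS = [
    "cluster_id", "size", "chrom5", "start5", "end5",
    "chrom3", "start3", "end3", "sv_type", "similarity_score",
]


def _random_cluster(
    rng: np.random.Generator, spec: AuxSpec, idx: int, prefix: str
) -> dict:
    chroms = list(spec.chrom_lengths)
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    clen = spec.chrom_lengths[chrom]
    alen = int(rng.integers(*spec.anchor_size))
    start5 = int(rng.integers(0, max(1, clen - 4 * alen - 20000)))
    gap = int(rng.integers(15000, 50000))
    start3 = start5 + alen + gap
    return {
        "cluster_id": f"{prefix}{idx:05d}",
        "size": max(6, int(rng.poisson(spec.mean_cluster_size))),
        "chrom5": chrom,
        "start5": start5,
        "end5": start5 + alen,
        "chrom3": chrom,
        "start3": start3,
        "end3": start3 + alen,
        "sv_type": spec.sv_types[int(rng.integers(0, len(spec.sv_types)))],
        "similarity_score": float(rng.integers(0, 1500)),
    }


def _low_complexity_read(rng: np.random.Generator, length: int) -> str:
    unit = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5))
    return (unit * (length // 5 + 1))[:length]


def _random_read(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate_aux_data(spec: AuxSpec, seed: int) -> AuxData:
    """SV cluster tables (tumor = germline union somatic-only) and microbial tables."""
    rng = np.random.default_rng(seed)
    n_somatic = int(round(spec.n_clusters * spec.fraction_somatic))
    n_germline = spec.n_clusters - n_somatic

    germline = [_random_cluster(rng, spec, i, "gl") for i in range(n_germline)]
    somatic = [_random_cluster(rng, spec, i, "som") for i in range(n_somatic)]

    normal = pd.DataFrame(
        [{**c, "cluster_id": c["cluster_id"].replace("gl", "n")} for c in germline],
        columns=_CLUSTER_COLUMNS,
    )
    tumor = pd.DataFrame(
        [{**c, "cluster_id": c["cluster_id"].replace("gl", "t")} for c in germline]
        + somatic,
        columns=_CLUSTER_COLUMNS,
    )

    reads = []
    genome_sizes: dict[str, int] = {}
    read_no = 0
    for sp in spec.species:
        n_windows_avail = sp.genome_size // 1000
        if sp.n_windows > n_windows_avail:
            raise SizingError(
                f"{sp.name}: {sp.n_windows} windows requested but genome has "
                f"only {n_windows_avail}"
            )
        genome_sizes[sp.name] = sp.genome_size
        windows = rng.choice(n_windows_avail, size=sp.n_windows, replace=False)
        for i in range(sp.n_reads):
            window = int(windows[i % sp.n_windows])
            position = window * 1000 + int(
                rng.integers(0, max(1, 1000 - sp.read_length))
            )
            seq = (
                _low_complexity_read(rng, sp.read_length)
                if sp.low_complexity
                else _random_read(rng, sp.read_length)
            )
            reads.append(
                {
                    "read_id": f"read{read_no:06d}",
                    "sequence": seq,
                    "species": sp.name,
                    "strain": sp.strains[i % len(sp.strains)],
                    "position": position,
                    "unique_flag": int(rng.random() < sp.unique_fraction),
                }
            )
            read_no += 1
    microbial = pd.DataFrame(
        reads,
        columns=["read_id", "sequence", "species", "strain", "position", "unique_flag"],
    )

    control_rows = []
    for name in spec.control_species:
        size = genome_sizes.get(name, 1_000_000)
        genome_sizes.setdefault(name, size)
        for j in range(3):
            control_rows.append(
                {
                    "read_id": f"ctrl{name}_{j}",
                    "sequence": _random_read(rng, 76),
                    "species": name,
                    "strain": "strain1",
                    "position": int(rng.integers(0, size - 76)),
                    "unique_flag": 1,
                }
            )
    control = pd.DataFrame(
        control_rows,
        columns=["read_id", "sequence", "species", "strain", "position", "unique_flag"],
    )
    return AuxData(tumor, normal, microbial, control, genome_sizes)


# ---------------------------------------------------------------------------
# MSI cohort helper


def simulate_msi_cohort(
    reference: SimulatedReference,
    n_samples: int,
    background_rate: float,
    planted: Mapping[int, int] | None = None,
    seed: int = 0,
    min_tract_length: int = 5,
    base: str = "T",
) -> dict[str, list[PlantedVariant]]:
    """Per-sample MSI deletion sets over the reference's poly-T tracts.

    Each eligible (tract, sample) pair is mutated independently at
    ``background_rate``; ``planted`` maps tract indices (into
    ``reference.tracts``) to an exact number of carrier samples, overriding
    the background for those tracts.
    """
    if not 0 <= background_rate < 1:
        raise ParameterError("background rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    planted = dict(planted or {})
    samples = [f"msi{j + 1:02d}" for j in range(n_samples)]
    out: dict[str, list[PlantedVariant]] = {s: [] for s in samples}
    for i, tract in enumerate(reference.tracts):
        if tract.base != base or tract.length < min_tract_length or tract.start < 1:
            continue
        if i in planted:
            k = planted[i]
            if k > n_samples:
                raise ParameterError("planted carrier count exceeds cohort size")
            carriers = rng.choice(n_samples, size=k, replace=False)
        else:
            carriers = np.flatnonzero(rng.random(n_samples) < background_rate)
        region = "exome"  # cohort helper is used on exome-restricted tract sets
        for j in carriers:
            out[samples[int(j)]].append(
                PlantedVariant(
                    chrom=tract.chrom,
                    pos0=tract.start,
                    ref=tract.base,
                    alt="",
                    kind="del",
                    vclass=f"del1{tract.base}",
                    context="",
                    region=region,
                    origin="somatic",
                    tract_id=f"tract{i:05d}",
                )
            )
    return out
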