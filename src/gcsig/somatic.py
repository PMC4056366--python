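"""Tumor/normal somatic variant filtering.

Variants are called per sample by an external caller; this module compares
the tumor and matched-normal call sets and applies the study's somatic
rules:

* SNVs: somatic when the variant call is unique to the tumor, the normal
  called genotype differs from the tumor variant genotype, and fewer than
  two reads of the variant allele are seen in the normal sample.  Identical
  calls in tumor and normal are germline.
* Indels: somatic when supported by at least 20% of overlapping tumor
  reads, by reads on both strands, with a minimum of 10 reads overlapping
  the position, and no indel call in the normal sample at the (left-
  aligned) site.

Genotype comparison is allele-set based (phase is ignored) and indels are
left-aligned on both samples before comparison, so positional dialects do
not create false somatics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataCompletenessError, IntegrityError, ParameterError
from .io import VcfRecord

# rejection / status codes
SOMATIC = "somatic"
GERMLINE = "germline"
REJECTED = "rejected"

REASON_NORMAL_SUPPORT = "normal_alt_reads"
REASON_NORMAL_GENOTYPE = "normal_genotype_same"
REASON_VAF = "vaf_below_20pct"
REASON_STRAND = "single_strand"
REASON_DEPTH = "depth_below_10"
REASON_NORMAL_INDEL = "normal_indel_call"


@dataclass(frozen=True)
class GenotypeCall:
    """One per-sample variant call (position 1-based, as in VCF)."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[str, str]
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParameterError("VCF positions are 1-based (>= 1)")
        if self.ref == self.alt:
            raise ParameterError("ref and alt must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.genotype)

    @classmethod
    def from_vcf_record(cls, rec: VcfRecord, sample: str) -> "GenotypeCall":
        return cls(
            sample=sample,
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=rec.alt,
            genotype=rec.genotype,
            qual=rec.qual,
        )


@dataclass(frozen=True)
class AlleleSupport:
    """Read support for one variant allele at one site in one sample."""

    depth: int
    alt_reads: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.depth:
            raise ParameterError("need 0 <= alt reads <= depth")
        if self.alt_fwd + self.alt_rev != self.alt_reads:
            raise ParameterError("strand counts must sum to alt reads")


@dataclass(frozen=True)
class SomaticCall:
    call: GenotypeCall
    status: str
    reason: str | None = None


SupportIndex = Mapping[tuple[str, int, str, str], AlleleSupport]


def support_index(table: pd.DataFrame, sample: str) -> dict[tuple, AlleleSupport]:
    """Index a support TSV (schema from the simulator) by (chrom, pos, ref, alt)."""
    sub = table[table["sample"] == sample]
    out = {}
    for row in sub.itertuples(index=False):
        out[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = AlleleSupport(
            depth=int(row.depth),
            alt_reads=int(row.alt_reads),
            alt_fwd=int(row.alt_fwd),
            alt_rev=int(row.alt_rev),
        )
    return out


def call_somatic_snvs(
    tumor_calls: Sequence[GenotypeCall],
    normal_calls: Sequence[GenotypeCall],
    normal_support: SupportIndex,
) -> list[SomaticCall]:
    """Partition tumor SNV calls into somatic / germline / rejected.

    ``normal_support`` must contain a row for every tumor call that is not
    an identical germline call (the "< 2 variant reads in normal" check);
    a missing row raises :class:`DataCompletenessError` rather than guessing.
    A normal sample with no call at the site is treated as homozygous
    reference for the genotype comparison.
    """
    normal_by_site: dict[tuple[str, int], list[GenotypeCall]] = {}
    for c in normal_calls:
        normal_by_site.setdefault((c.chrom, c.pos), []).append(c)

    out: list[SomaticCall] = []
    for t in tumor_calls:
        if not t.is_snv:
            raise ParameterError(f"non-SNV call passed to SNV filter: {t}")
        site_calls = normal_by_site.get((t.chrom, t.pos), [])
        identical = [
            n
            for n in site_calls
            if n.ref == t.ref and n.alt == t.alt and n.allele_set == t.allele_set
        ]
        if identical:
            out.append(SomaticCall(t, GERMLINE))
            continue
        normal_gt = (
            site_calls[0].allele_set if site_calls else frozenset({t.ref})
        )
        if normal_gt == t.allele_set:
            out.append(SomaticCall(t, REJECTED, REASON_NORMAL_GENOTYPE))
            continue
        key = (t.chrom, t.pos, t.ref, t.alt)
        sup = normal_support.get(key)
        if sup is None:
            raise DataCompletenessError(
                f"no normal support row for tumor-unique site {key}"
            )
        if sup.alt_reads < 2:
            out.append(SomaticCall(t, SOMATIC))
        else:
            out.append(SomaticCall(t, REJECTED, REASON_NORMAL_SUPPORT))
    return out


def call_somatic_indels(
    tumor_calls: Sequence[GenotypeCall],
    tumor_support: SupportIndex,
    normal_calls: Sequence[GenotypeCall],
    reference: Mapping[str, str] | None = None,
) -> list[SomaticCall]:
    """Apply the four somatic indel predicates plus the normal-clean rule.

    When a reference is supplied, indels in both samples are left-aligned
    before the tumor/normal comparison.  Thresholds are taken literally:
    variant fraction uses ``>=`` on the exact rational, strand support needs
    at least one read on each strand, and depth needs at least 10 reads.
    """
    if reference is not None:
        tumor_calls = [left_align_indel(c, reference) for c in tumor_calls]
        normal_calls = [left_align_indel(c, reference) for c in normal_calls]
    normal_sites = {(c.chrom, c.pos, c.ref, c.alt) for c in normal_calls}
    normal_positions = {(c.chrom, c.pos) for c in normal_calls}

    out: list[SomaticCall] = []
    for t in tumor_calls:
        if t.is_snv:
            raise ParameterError(f"SNV call passed to indel filter: {t}")
        key = (t.chrom, t.pos, t.ref, t.alt)
        sup = tumor_support.get(key)
        if sup is None:
            raise DataCompletenessError(f"no tumor support row for indel {key}")
        if (t.chrom, t.pos, t.ref, t.alt) in normal_sites:
            out.append(SomaticCall(t, GERMLINE))
        elif (t.chrom, t.pos) in normal_positions:
            out.append(SomaticCall(t, REJECTED, REASON_NORMAL_INDEL))
        elif sup.depth < 10:
            out.append(SomaticCall(t, REJECTED, REASON_DEPTH))
        elif sup.depth == 0 or sup.alt_reads * 5 < sup.depth:  # alt/depth >= 0.20
            out.append(SomaticCall(t, REJECTED, REASON_VAF))
        elif sup.alt_fwd < 1 or sup.alt_rev < 1:
            out.append(SomaticCall(t, REJECTED, REASON_STRAND))
        else:
            out.append(SomaticCall(t, SOMATIC))
    return out


def left_align_indel(call: GenotypeCall, reference: Mapping[str, str]) -> GenotypeCall:
    """Shift an indel to its leftmost equivalent representation (idempotent).

    Uses the standard normalisation: while ref and alt alleles end in the
    same base, drop it and prepend the reference base to the left; then trim
    a shared leading base while both alleles keep length > 1.
    """
    if call.is_snv:
        return call
    seq = reference.get(call.chrom)
    if seq is None:
        raise IntegrityError(f"chromosome {call.chrom} absent from reference")
    pos0 = call.pos - 1
    ref, alt = call.ref, call.alt
    if seq[pos0 : pos0 + len(ref)].upper() != ref.upper():
        raise IntegrityError(
            f"ref allele {ref} does not match reference at {call.chrom}:{call.pos}"
        )
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref = ref[:-1]
            alt = alt[:-1]
            if len(ref) == 0 or len(alt) == 0:
                if pos0 == 0:
                    # cannot extend left of the contig; restore anchor
                    base = seq[pos0]
                    ref = base + ref
                    alt = base + alt
                    break
                pos0 -= 1
                base = seq[pos0]
                ref = base + ref
                alt = base + alt
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref = ref[1:]
            alt = alt[1:]
            pos0 += 1
        else:
            break
    new_gt = tuple(
        alt if a == call.alt else (ref if a == call.ref else a)
        for a in call.genotype
    )
    return replace(call, pos=pos0 + 1, ref=ref, alt=alt, genotype=new_gt)


def audit_frame(calls: Iterable[SomaticCall]) -> pd.DataFrame:
    """One row per input call: final status and rejection reason."""
    return pd.DataFrame(
        [
            {
                "chrom": c.call.chrom,
                "pos": c.call.pos,
                "ref": c.call.ref,
                "alt": c.call.alt,
                "sample": c.call.sample,
                "status": c.status,
                "reason": c.reason or "",
            }
            for c in calls
        ],
        columns=["chrom", "pos", "ref", "alt", "sample", "status", "reason"],
    )
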