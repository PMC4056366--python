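"""DNA-PET structural-variant cluster QC and tumor/normal comparison.

Long-insert paired-end-tag (DNA-PET) sequencing calls structural variants
from clusters of discordantly mapping tag pairs.  Four quality-control
criteria remove unreliable clusters:

i.   cluster size (supporting tag pairs) below 6;
ii.  either anchor region narrower than 1 kbp;
iii. membership in a supercluster (connected component of overlapping
     clusters) of size > 100, unless the cluster itself has size >= 10;
iv.  high sequence similarity between the fused regions (precomputed
     alignment score > 2000 over 20 kbp breakpoint windows).

Somatic status is then assigned by comparison with the matched normal:
a tumor cluster with a same-type normal cluster whose anchors lie within
a matching window is germline, otherwise somatic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import IntegrityError, ParameterError

REASON_SIZE = "i"
REASON_ANCHOR = "ii"
REASON_SUPERCLUSTER = "iii"
REASON_SIMILARITY = "iv"

MIN_CLUSTER_SIZE = 6
MIN_ANCHOR_BP = 1000
SUPERCLUSTER_LIMIT = 100
RESCUE_CLUSTER_SIZE = 10
SIMILARITY_LIMIT = 2000.0


@dataclass(frozen=True)
class PetCluster:
    """One DNA-PET cluster with its two anchor regions."""

    cluster_id: str
    size: int
    anchor5: tuple[str, int, int]
    anchor3: tuple[str, int, int]
    sv_type: str
    similarity_score: float | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ParameterError("cluster size must be >= 1")
        for chrom, start, end in (self.anchor5, self.anchor3):
            if start >= end:
                raise ParameterError(
                    f"malformed anchor [{start}, {end}) in {self.cluster_id}"
                )

    @property
    def anchors(self) -> tuple[tuple[str, int, int], ...]:
        return (self.anchor5, self.anchor3)


@dataclass(frozen=True)
class SuperCluster:
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


def clusters_from_frame(table: pd.DataFrame) -> list[PetCluster]:
    """Build clusters from the TSV schema (see package I/O docs)."""
    out = []
    for row in table.itertuples(index=False):
        score = getattr(row, "similarity_score", None)
        if score is not None and pd.isna(score):
            score = None
        out.append(
            PetCluster(
                cluster_id=str(row.cluster_id),
                size=int(row.size),
                anchor5=(str(row.chrom5), int(row.start5), int(row.end5)),
                anchor3=(str(row.chrom3), int(row.start3), int(row.end3)),
                sv_type=str(row.sv_type),
                similarity_score=None if score is None else float(score),
            )
        )
    return out


def build_superclusters(clusters: Sequence[PetCluster]) -> list[SuperCluster]:
    """Connected components under anchor overlap.

    Two clusters are adjacent when any anchor of one intersects any anchor
    of the other (same chromosome, half-open interval intersection).  The
    result is independent of input order; every cluster belongs to exactly
    one supercluster.
    """
    ids = sorted(c.cluster_id for c in clusters)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    trees: dict[str, IntervalTree] = {}
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        for chrom, start, end in c.anchors:
            tree = trees.setdefault(chrom, IntervalTree())
            for iv in tree.overlap(start, end):
                union(c.cluster_id, iv.data)
            tree.addi(start, end, c.cluster_id)

    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return [SuperCluster(frozenset(g)) for g in groups.values()]


def qc_filter_clusters(
    clusters: Sequence[PetCluster],
    superclusters: Sequence[SuperCluster] | None = None,
) -> tuple[list[PetCluster], dict[str, str]]:
    """Apply QC criteria i-iv; returns retained clusters and rejection reasons.

    A cluster is retained iff size >= 6, both anchors span >= 1 kbp, its
    supercluster has size <= 100 or its own size is >= 10, and its fused-
    region similarity score is absent or <= 2000.  Rejections are labelled
    with the first failing criterion in order i, ii, iii, iv.
    """
    if superclusters is None:
        superclusters = build_superclusters(clusters)
    sc_size: dict[str, int] = {}
    for sc in superclusters:
        for member in sc.members:
            sc_size[member] = sc.size
    retained: list[PetCluster] = []
    reasons: dict[str, str] = {}
    for c in clusters:
        if c.cluster_id not in sc_size:
            raise IntegrityError(
                f"cluster {c.cluster_id} not assigned to any supercluster"
            )
        if c.size < MIN_CLUSTER_SIZE:
            reasons[c.cluster_id] = REASON_SIZE
        elif any(end - start < MIN_ANCHOR_BP for _, start, end in c.anchors):
            reasons[c.cluster_id] = REASON_ANCHOR
        elif sc_size[c.cluster_id] > SUPERCLUSTER_LIMIT and c.size < RESCUE_CLUSTER_SIZE:
            reasons[c.cluster_id] = REASON_SUPERCLUSTER
        elif c.similarity_score is not None and c.similarity_score > SIMILARITY_LIMIT:
            reasons[c.cluster_id] = REASON_SIMILARITY
        else:
            retained.append(c)
    return retained, reasons


def _anchors_match(
    a: tuple[str, int, int], b: tuple[str, int, int], window: int
) -> bool:
    if a[0] != b[0]:
        return False
    mid_a = (a[1] + a[2]) / 2
    mid_b = (b[1] + b[2]) / 2
    return abs(mid_a - mid_b) <= window


def somatic_sv_calls(
    tumor_clusters: Sequence[PetCluster],
    normal_clusters: Sequence[PetCluster],
    matching_window: int = 10_000,
) -> tuple[list[PetCluster], list[PetCluster]]:
    """Split tumor clusters into (somatic, germline) by normal comparison.

    A tumor cluster is germline iff some normal cluster of the same SV type
    has both anchor midpoints within ``matching_window`` bp of the tumor
    cluster's corresponding anchors; otherwise it is somatic.
    """
    if matching_window < 0:
        raise ParameterError("matching window must be >= 0")
    by_type: dict[str, list[PetCluster]] = {}
    for n in normal_clusters:
        by_type.setdefault(n.sv_type, []).append(n)
    somatic: list[PetCluster] = []
    germline: list[PetCluster] = []
    for t in tumor_clusters:
        matched = any(
            _anchors_match(t.anchor5, n.anchor5, matching_window)
            and _anchors_match(t.anchor3, n.anchor3, matching_window)
            for n in by_type.get(t.sv_type, ())
        )
        (germline if matched else somatic).append(t)
    return somatic, germline


def sv_type_counts(clusters: Sequence[PetCluster]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in clusters:
        counts[c.sv_type] = counts.get(c.sv_type, 0) + 1
    return dict(sorted(counts.items()))


def annotate_frame(
    table: pd.DataFrame,
    retained_ids: set[str],
    reasons: Mapping[str, str],
    superclusters: Sequence[SuperCluster],
) -> pd.DataFrame:
    """Add status/reason/supercluster columns to a cluster TSV frame."""
    sc_id: dict[str, str] = {}
    sc_size: dict[str, int] = {}
    for idx, sc in enumerate(
        sorted(superclusters, key=lambda s: min(s.members))
    ):
        name = f"sc{idx:04d}"
        for member in sc.members:
            sc_id[member] = name
            sc_size[member] = sc.size
    out = table.copy()
    out["status"] = [
        "retained" if cid in retained_ids else "rejected" for cid in out["cluster_id"]
    ]
    out["reason"] = [reasons.get(cid, "") for cid in out["cluster_id"]]
    out["supercluster_id"] = [sc_id.get(cid, "") for cid in out["cluster_id"]]
    out["supercluster_size"] = [sc_size.get(cid, 0) for cid in out["cluster_id"]]
    return out
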