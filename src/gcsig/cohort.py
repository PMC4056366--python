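"""Published summary counts of the two-tumor gastric-cancer WGS study.

The methods in this package were developed around a whole-genome comparison
of two gastric adenocarcinomas: NGCII082 (microsatellite-unstable, active
H. pylori infection) and NGCII092 (chromosomally unstable, TP53-mutant).
This module carries the study's published per-tumor somatic variant summary
table and recomputes the dataset-level headline quantities from it — the
genome-wide mutation rate, the whole-genome vs exome yield advantage, the
share of gene-affecting structural variants carried by the CIN tumor, and
the recurrence bounds for the MSI target genes.  These are desk-scale
arithmetic checks; they do not require the deposited sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .msi import GeneRecurrence, recurrence_test

#: Per-tumor somatic variant summary (whole-genome calls).
SOMATIC_SUMMARY: dict[str, dict[str, int]] = {
    "NGCII082": {
        "snvs": 14_856,
        "snvs_coding": 119,
        "snvs_nonsynonymous": 86,
        "snvs_promoter": 101,
        "indels": 11_738,
        "indels_coding": 12,
        "cnvs": 836,
        "cnvs_affecting_genes": 3,
        "svs": 12,
        "svs_affecting_genes": 11,
    },
    "NGCII092": {
        "snvs": 17_473,
        "snvs_coding": 116,
        "snvs_nonsynonymous": 73,
        "snvs_promoter": 161,
        "indels": 2_486,
        "indels_coding": 2,
        "cnvs": 21_776,
        "cnvs_affecting_genes": 265,
        "svs": 146,
        "svs_affecting_genes": 96,
    },
}

#: Somatic SNVs recovered by the earlier exome-restricted studies (37 exomes).
EXOME_STUDY_SNVS = 5_588

#: Total length of the hg18 human reference assembly in bp.
HG18_GENOME_BP = 3_107_677_273

#: MSI recurrence inputs: carriers among the 14 MSI-positive tumors and the
#: exome background rates over thymine tracts of length 8 (n = 778) and 9
#: (n = 183).
MSI_COHORT_SIZE = 14
MSI_RECURRENCE_INPUTS: dict[str, dict] = {
    "ACVR2A": {"k": 12, "tract_length": 8, "background": 0.045, "family": 778},
    "RPL22": {"k": 9, "tract_length": 8, "background": 0.045, "family": 778},
    "LMAN1": {"k": 7, "tract_length": 9, "background": 0.048, "family": 183},
}


def mean_mutation_rate_per_mbp() -> float:
    """Average somatic SNV rate per megabase across the two genomes."""
    total_snvs = sum(t["snvs"] for t in SOMATIC_SUMMARY.values())
    per_tumor = total_snvs / len(SOMATIC_SUMMARY)
    return per_tumor / (HG18_GENOME_BP / 1e6)


def wgs_vs_exome_snv_yield() -> float:
    """Fold advantage of the two whole genomes over the 37-exome SNV yield."""
    total_snvs = sum(t["snvs"] for t in SOMATIC_SUMMARY.values())
    return total_snvs / EXOME_STUDY_SNVS


def gene_affecting_sv_share(tumor: str = "NGCII092") -> float:
    """Fraction of all gene-affecting SVs carried by one tumor (CIN burden)."""
    total = sum(t["svs_affecting_genes"] for t in SOMATIC_SUMMARY.values())
    return SOMATIC_SUMMARY[tumor]["svs_affecting_genes"] / total


def snv_share_of_mutated_genes(tumor: str = "NGCII082") -> float:
    """Share of a tumor's gene-level mutation events attributable to SNVs.

    Gene-level events are non-synonymous SNVs, coding indels, gene-affecting
    CNVs and gene-affecting SVs.
    """
    t = SOMATIC_SUMMARY[tumor]
    events = (
        t["snvs_nonsynonymous"]
        + t["indels_coding"]
        + t["cnvs_affecting_genes"]
        + t["svs_affecting_genes"]
    )
    return t["snvs_nonsynonymous"] / events


@dataclass(frozen=True)
class MsiRecurrenceBound:
    gene: str
    result: GeneRecurrence


def msi_recurrence_bounds() -> dict[str, GeneRecurrence]:
    """Bonferroni-corrected exact-binomial recurrence p for the MSI genes.

    Each gene's poly-T tract is tested with the published carrier count k
    out of the 14 MSI-positive tumors against the length-matched exome
    background rate, Bonferroni-corrected by the number of exome tracts of
    that length.
    """
    out = {}
    for gene, spec in MSI_RECURRENCE_INPUTS.items():
        out[gene] = recurrence_test(
            k=spec["k"],
            n=MSI_COHORT_SIZE,
            p=spec["background"],
            family_size=spec["family"],
            gene=gene,
        )
    return out
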