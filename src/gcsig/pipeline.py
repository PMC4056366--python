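"""End-to-end orchestration of the analysis stages.

The pipeline wires the stages in dependency order: simulation (or external
inputs) -> somatic filtering -> spectrum / context enrichment / MSI
analysis, with the SV-cluster QC and microbial screen running
independently, and finally a machine-readable JSON report whose counts
reconcile with the per-stage TSV outputs.  Everything is seeded and
deterministic apart from the report timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .context import extract_context, scan_enriched_motifs
from .errors import ParameterError
from .io import (
    read_fasta,
    read_support_table,
    read_tsv,
    read_vcf,
    write_fasta,
    write_support_table,
    write_tsv,
    write_vcf,
)
from .microbiome import species_evidence
from .motifs import Motif
from .msi import (
    annotate_tract_genes,
    classify_indel_context,
    gene_recurrence_table,
    msi_summary,
    scan_homopolymers,
    tract_index,
)
from .regions import gene_trees, interval_trees, read_gff3, write_bed, write_gff3
from .sequtil import MUTATION_CLASSES
from .simulate import (
    AuxSpec,
    GenomeSpec,
    SignatureMixture,
    SpeciesSpec,
    TractSpec,
    generate_reference,
    simulate_aux_data,
    simulate_msi_cohort,
    simulate_read_support,
    simulate_variants,
)
from .somatic import (
    GenotypeCall,
    audit_frame,
    call_somatic_indels,
    call_somatic_snvs,
    support_index,
)
from .spectrum import compute_bias, region_excess_test, spectrum_from_classes
from .svfilter import (
    annotate_frame,
    build_superclusters,
    clusters_from_frame,
    qc_filter_clusters,
    somatic_sv_calls,
    sv_type_counts,
)

ALL_STAGES = (
    "simulate",
    "somatic",
    "spectrum",
    "context",
    "msi",
    "svfilter",
    "microbe",
    "report",
)

#: Default six-class mixtures: the somatic side emulates the oxidative-
#: damage-dominated gastric tumor spectrum (C>A / T>A heavy, plus the
#: coding-restricted deamination C>T); the germline side is a typical
#: transition-heavy human polymorphism spectrum (a free parameter of the
#: generator, see the methods note).
DEFAULT_SOMATIC_PROBS = {
    "C>A": 0.30, "C>G": 0.08, "C>T": 0.25, "T>A": 0.15, "T>C": 0.14, "T>G": 0.08,
}
DEFAULT_GERMLINE_PROBS = {
    "C>A": 0.09, "C>G": 0.07, "C>T": 0.31, "T>A": 0.07, "T>C": 0.33, "T>G": 0.13,
}


@dataclass
class PipelineConfig:
    """Flat configuration for a full synthetic-data run."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    # --- synthetic genome
    chrom_length: int = 250_000
    n_chroms: int = 2
    exon_fraction: float = 0.05
    gene_count: int = 60
    tract_length: int = 8
    tract_count: int = 120

    # --- variants
    n_somatic_snvs: int = 4_000
    n_germline_snvs: int = 6_000
    msi_deletion_rate: float = 0.045
    ca_tpcpa_multiplier: float = 1.7
    ca_cpcpt_multiplier: float = 3.2
    ct_cpg_multiplier: float = 1.2
    ct_gpc_multiplier: float = 1.4
    ct_exome_only: bool = True

    # --- read support
    mean_depth: float = 60.0
    depth_dispersion: float = 0.05
    vaf: float = 0.5
    normal_contamination_vaf: float = 0.0

    # --- MSI cohort demonstration
    msi_cohort_size: int = 12
    msi_background_rate: float = 0.045
    planted_tract_carriers: int = 10

    # --- SV / microbial fixtures
    n_sv_clusters: int = 60
    sv_fraction_somatic: float = 0.25
    sv_matching_window: int = 10_000

    # --- analysis parameters
    alpha: float = 0.05

    # --- optional external inputs (default: files written by `simulate`)
    reference_fasta: Path | None = None
    annotation_gff: Path | None = None
    exome_bed: Path | None = None
    tumor_vcf: Path | None = None
    normal_vcf: Path | None = None
    support_table: Path | None = None
    tumor_clusters: Path | None = None
    normal_clusters: Path | None = None
    microbial_table: Path | None = None
    control_table: Path | None = None
    genome_sizes_table: Path | None = None

    def path(self, attr: str, default_name: str) -> Path:
        override = getattr(self, attr)
        p = Path(override) if override else Path(self.outdir) / default_name
        return p

    def require(self, attr: str, default_name: str) -> Path:
        p = self.path(attr, default_name)
        if not p.exists():
            raise ParameterError(f"required input missing: {p} ({attr})")
        return p

    def config_hash(self) -> str:
        # hash the analysis parameters only; file locations do not change results
        payload = {
            k: str(v)
            for k, v in dataclasses.asdict(self).items()
            if not (k == "outdir" or k.endswith(("_fasta", "_gff", "_bed", "_vcf",
                                                "_table", "_clusters")))
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


_CONFIG_TYPES = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; keyword overrides win."""
    values: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"malformed config line: {line!r}")
            key, raw = (s.strip() for s in line.split("=", 1))
            values[key] = raw
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "outdir" not in values:
        raise ParameterError("config must set outdir")
    kwargs = {}
    for key, raw in values.items():
        if key not in _CONFIG_TYPES:
            raise ParameterError(f"unknown config key: {key}")
        if not isinstance(raw, str):
            kwargs[key] = raw
            continue
        default = getattr(PipelineConfig, key, None)
        fld = _CONFIG_TYPES[key]
        if key == "stages":
            kwargs[key] = tuple(s.strip() for s in raw.split(",") if s.strip())
        elif fld.type in ("Path", "Path | None") or key == "outdir":
            kwargs[key] = Path(raw)
        elif isinstance(default, bool):
            kwargs[key] = raw.lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            kwargs[key] = int(raw)
        elif isinstance(default, float):
            kwargs[key] = float(raw)
        else:
            kwargs[key] = raw
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = GenomeSpec(
        chrom_lengths={
            f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)
        },
        planted_tracts=(TractSpec("T", cfg.tract_length, cfg.tract_count),),
        exon_fraction=cfg.exon_fraction,
        gene_count=cfg.gene_count,
        seed=cfg.seed,
    )
    reference = generate_reference(spec)
    mults: dict[str, tuple] = {
        "C>A": (
            (Motif.flanks("T", "A"), cfg.ca_tpcpa_multiplier),
            (Motif.flanks("C", "T"), cfg.ca_cpcpt_multiplier),
        ),
        "C>T": (
            (Motif.flanks(three="G"), cfg.ct_cpg_multiplier),
            (Motif.flanks(five="G"), cfg.ct_gpc_multiplier),
        ),
    }
    mixture = SignatureMixture(
        somatic_class_probs=DEFAULT_SOMATIC_PROBS,
        germline_class_probs=DEFAULT_GERMLINE_PROBS,
        n_somatic=cfg.n_somatic_snvs,
        n_germline=cfg.n_germline_snvs,
        context_multipliers=mults,
        exome_only_classes=frozenset({"C>T"}) if cfg.ct_exome_only else frozenset(),
        msi_deletion_rate=cfg.msi_deletion_rate,
    )
    variants = simulate_variants(reference, mixture, seed=cfg.seed + 1)
    support = simulate_read_support(
        variants.all,
        mean_depth=cfg.mean_depth,
        dispersion=cfg.depth_dispersion,
        vaf=cfg.vaf,
        seed=cfg.seed + 2,
        normal_contamination_vaf=cfg.normal_contamination_vaf,
        sequences=reference.sequences,
    )
    aux = simulate_aux_data(
        AuxSpec(
            chrom_lengths={"chr1": 50_000_000},
            n_clusters=cfg.n_sv_clusters,
            fraction_somatic=cfg.sv_fraction_somatic,
            species=(
                SpeciesSpec("Helicobacter pylori", 1_600_000, 120, 25),
                SpeciesSpec("Sparse species", 2_000_000, 4, 3),
                SpeciesSpec("Contaminant species", 4_000_000, 40, 12),
            ),
            control_species=("Contaminant species",),
        ),
        seed=cfg.seed + 3,
    )

    write_fasta(reference.sequences, out / "reference.fa")
    write_gff3(reference.genes, out / "genes.gff3")
    write_bed(
        [(c, s, e) for c, s, e in reference.exons], out / "exome.bed"
    )
    write_bed(
        [(t.chrom, t.start, t.end, t.base) for t in reference.tracts],
        out / "tracts.bed",
    )
    contigs = dict(spec.chrom_lengths)
    tumor_records = [v.to_vcf(reference.sequences) for v in variants.all]
    normal_records = [v.to_vcf(reference.sequences) for v in variants.germline]
    write_vcf(tumor_records, out / "tumor.vcf", "tumor", contigs)
    write_vcf(normal_records, out / "normal.vcf", "normal", contigs)
    write_support_table(support, out / "support.tsv")
    variants.write_truth(out / "truth.json")
    write_tsv(aux.tumor_clusters, out / "tumor_clusters.tsv")
    write_tsv(aux.normal_clusters, out / "normal_clusters.tsv")
    write_tsv(aux.microbial, out / "microbial.tsv")
    write_tsv(aux.control, out / "control.tsv")
    write_tsv(
        pd.DataFrame(
            sorted(aux.genome_sizes.items()), columns=["species", "genome_size"]
        ),
        out / "genome_sizes.tsv",
    )


def stage_somatic(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    reference = read_fasta(cfg.require("reference_fasta", "reference.fa"))
    tumor = read_vcf(cfg.require("tumor_vcf", "tumor.vcf"))
    normal = read_vcf(cfg.require("normal_vcf", "normal.vcf"))
    support = read_support_table(cfg.require("support_table", "support.tsv"))

    tumor_calls = [GenotypeCall.from_vcf_record(r, "tumor") for r in tumor]
    normal_calls = [GenotypeCall.from_vcf_record(r, "normal") for r in normal]
    tumor_snvs = [c for c in tumor_calls if c.is_snv]
    tumor_indels = [c for c in tumor_calls if not c.is_snv]
    normal_snvs = [c for c in normal_calls if c.is_snv]
    normal_indels = [c for c in normal_calls if not c.is_snv]

    snv_result = call_somatic_snvs(
        tumor_snvs, normal_snvs, support_index(support, "normal")
    )
    indel_result = call_somatic_indels(
        tumor_indels, support_index(support, "tumor"), normal_indels, reference
    )
    audit = audit_frame(snv_result + indel_result)
    write_tsv(audit, out / "somatic_audit.tsv")

    from .io import VcfRecord

    somatic_records = []
    for res in snv_result + indel_result:
        if res.status == "somatic":
            c = res.call
            somatic_records.append(
                VcfRecord(
                    chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                    genotype=c.genotype,
                )
            )
    write_vcf(somatic_records, out / "somatic.vcf", "tumor")


def _classified_sets(cfg: PipelineConfig):
    """Somatic/germline SNVs with collapsed classes and windows, from the audit."""
    out = Path(cfg.outdir)
    reference = read_fasta(cfg.require("reference_fasta", "reference.fa"))
    audit = read_tsv(out / "somatic_audit.tsv")
    snvs = audit[(audit["ref"].str.len() == 1) & (audit["alt"].str.len() == 1)]
    sets: dict[str, list] = {"somatic": [], "germline": []}
    for row in snvs.itertuples(index=False):
        if row.status not in sets:
            continue
        window = extract_context(
            reference[str(row.chrom)], int(row.pos) - 1, str(row.ref), str(row.alt)
        )
        from .sequtil import collapse_snv

        cls, _ = collapse_snv(str(row.ref), str(row.alt))
        sets[row.status].append(
            {
                "chrom": str(row.chrom),
                "pos0": int(row.pos) - 1,
                "ref": str(row.ref),
                "alt": str(row.alt),
                "class": cls,
                "window": window,
            }
        )
    return reference, sets


def stage_spectrum(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    _, sets = _classified_sets(cfg)
    exome = interval_trees(
        [(c, s, e) for c, s, e, *_ in _read_bed_rows(cfg.require("exome_bed", "exome.bed"))]
    )
    genes = read_gff3(cfg.require("annotation_gff", "genes.gff3"))

    results = {}
    for stratum, selector in (
        ("genome-wide", lambda v: True),
        ("exome", lambda v: _in_trees(exome, v)),
    ):
        som = [v["class"] for v in sets["somatic"] if selector(v)]
        germ = [v["class"] for v in sets["germline"] if selector(v)]
        if not som or not germ:
            continue
        table = spectrum_from_classes(som, germ, stratum)
        bias = compute_bias(table)
        frame = table.to_frame()
        frame["bias"] = [bias.bias[c] for c in MUTATION_CLASSES]
        frame["p_value"] = [bias.p_values[c] for c in MUTATION_CLASSES]
        write_tsv(frame, out / f"spectrum_{stratum.replace('-', '_')}.tsv")
        results[stratum] = {
            "bias": bias.bias,
            "p_values": bias.p_values,
            "n_somatic": table.n_somatic,
            "n_germline": table.n_germline,
        }

    excess = region_excess_test(
        [(v["chrom"], v["pos0"]) for v in sets["somatic"]],
        [(v["chrom"], v["pos0"]) for v in sets["germline"]],
        exome,
    )
    from .spectrum import strand_bias_test

    strand = strand_bias_test(
        [(v["chrom"], v["pos0"], v["ref"], v["alt"]) for v in sets["somatic"]],
        genes,
    )
    write_tsv(strand, out / "strand_bias.tsv")
    with open(out / "spectrum_summary.json", "w") as fh:
        json.dump(
            {"strata": results, "coding_excess": excess,
             "strand_ambiguous": int(strand.attrs["ambiguous"])},
            fh, indent=1,
        )


def _read_bed_rows(path: Path):
    from .regions import read_bed

    return read_bed(path)


def _in_trees(trees, v) -> bool:
    tree = trees.get(v["chrom"])
    return bool(tree is not None and tree.overlaps_point(v["pos0"]))


def stage_context(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    _, sets = _classified_sets(cfg)
    rows = []
    for cls in ("C>A", "C>T"):
        som = [v["window"] for v in sets["somatic"] if v["class"] == cls]
        germ = [v["window"] for v in sets["germline"] if v["class"] == cls]
        if not som or not germ:
            continue
        for res in scan_enriched_motifs(som, germ, cls, alpha=cfg.alpha):
            rows.append(
                {
                    "motif": res.label,
                    "class": res.mutation_class,
                    "a": res.somatic_with,
                    "b": res.somatic_without,
                    "c": res.germline_with,
                    "d": res.germline_without,
                    "odds_ratio": res.odds_ratio,
                    "p": res.p_value,
                    "p_adjusted": res.p_adjusted,
                    "corrected_flag": int(res.haldane_corrected),
                }
            )
    write_tsv(
        pd.DataFrame(
            rows,
            columns=["motif", "class", "a", "b", "c", "d", "odds_ratio", "p",
                     "p_adjusted", "corrected_flag"],
        ),
        out / "enriched_motifs.tsv",
    )


def stage_msi(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    reference = read_fasta(cfg.require("reference_fasta", "reference.fa"))
    genes = read_gff3(cfg.require("annotation_gff", "genes.gff3"))
    tracts = scan_homopolymers(reference, min_length=5)
    tracts = annotate_tract_genes(tracts, gene_trees(genes))
    index = tract_index(tracts)
    write_bed(
        [(t.chrom, t.start, t.end, f"{t.base}{t.length}") for t in tracts],
        out / "homopolymers.bed",
    )

    audit = read_tsv(out / "somatic_audit.tsv")
    indels = audit[
        (audit["status"] == "somatic")
        & ((audit["ref"].str.len() > 1) | (audit["alt"].str.len() > 1))
    ]
    calls = []
    for row in indels.itertuples(index=False):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) > len(alt):
            kind, bases = "del", ref[len(alt):]
        else:
            kind, bases = "ins", alt[len(ref):]
        pos0 = int(row.pos) - 1 + len(min(ref, alt, key=len))
        calls.append(
            classify_indel_context(str(row.chrom), pos0, kind, bases, index, "tumor")
        )
    summary = msi_summary(calls)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "chrom": c.chrom,
                    "pos0": c.pos0,
                    "kind": c.kind,
                    "size": c.size,
                    "bases": c.bases,
                    "repeat_context": c.repeat_context,
                    "tract_base": c.tract_base or "",
                    "tract_length": c.tract_length or 0,
                }
                for c in calls
            ],
            columns=["chrom", "pos0", "kind", "size", "bases", "repeat_context",
                     "tract_base", "tract_length"],
        ),
        out / "msi_indels.tsv",
    )

    # cohort demonstration: recurrence over simulated MSI-positive samples
    recurrence = None
    if cfg.msi_cohort_size > 0:
        from .simulate import SimulatedReference

        ref_obj = SimulatedReference(
            spec=None, sequences=reference, genes=genes,
            tracts=[t for t in tracts if t.base == "T" and t.length >= cfg.tract_length],
        )
        planted_idx = 0 if ref_obj.tracts else None
        cohort = simulate_msi_cohort(
            ref_obj,
            n_samples=cfg.msi_cohort_size,
            background_rate=cfg.msi_background_rate,
            planted={planted_idx: cfg.planted_tract_carriers}
            if planted_idx is not None
            else {},
            seed=cfg.seed + 4,
            min_tract_length=cfg.tract_length,
        )
        per_sample = {
            s: [
                classify_indel_context(v.chrom, v.pos0, "del", v.ref, index, s)
                for v in vs
            ]
            for s, vs in cohort.items()
        }
        recurrence = gene_recurrence_table(
            per_sample, ref_obj.tracts, length=cfg.tract_length,
            background_rate=cfg.msi_background_rate,
        )
        write_tsv(recurrence, out / "gene_recurrence.tsv")

    with open(out / "msi_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)


def stage_svfilter(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    tumor_frame = read_tsv(cfg.require("tumor_clusters", "tumor_clusters.tsv"))
    normal_frame = read_tsv(cfg.require("normal_clusters", "normal_clusters.tsv"))
    tumor = clusters_from_frame(tumor_frame)
    normal = clusters_from_frame(normal_frame)
    supers = build_superclusters(tumor)
    retained, reasons = qc_filter_clusters(tumor, supers)
    annotated = annotate_frame(
        tumor_frame, {c.cluster_id for c in retained}, reasons, supers
    )
    somatic, germline = somatic_sv_calls(
        retained, normal, matching_window=cfg.sv_matching_window
    )
    somatic_ids = {c.cluster_id for c in somatic}
    annotated["somatic"] = [
        int(cid in somatic_ids) for cid in annotated["cluster_id"]
    ]
    write_tsv(annotated, out / "sv_clusters.tsv")
    with open(out / "sv_summary.json", "w") as fh:
        json.dump(
            {
                "retained": len(retained),
                "rejected": len(reasons),
                "somatic": len(somatic),
                "germline": len(germline),
                "somatic_by_type": sv_type_counts(somatic),
            },
            fh, indent=1,
        )


def stage_microbe(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    microbial = read_tsv(cfg.require("microbial_table", "microbial.tsv"))
    control = read_tsv(cfg.require("control_table", "control.tsv"))
    sizes_frame = read_tsv(cfg.require("genome_sizes_table", "genome_sizes.tsv"))
    sizes = dict(zip(sizes_frame["species"], sizes_frame["genome_size"]))
    evidence = species_evidence(microbial, control, sizes)
    write_tsv(evidence, out / "microbiome.tsv")


def stage_report(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
        }
    }
    audit_path = out / "somatic_audit.tsv"
    if audit_path.exists():
        audit = read_tsv(audit_path)
        is_snv = (audit["ref"].str.len() == 1) & (audit["alt"].str.len() == 1)
        report["somatic_counts"] = {
            "snvs_somatic": int(((audit["status"] == "somatic") & is_snv).sum()),
            "indels_somatic": int(((audit["status"] == "somatic") & ~is_snv).sum()),
            "germline": int((audit["status"] == "germline").sum()),
            "rejected": int((audit["status"] == "rejected").sum()),
        }
    spectrum_path = out / "spectrum_summary.json"
    if spectrum_path.exists():
        report["spectrum"] = json.loads(spectrum_path.read_text())
    motifs_path = out / "enriched_motifs.tsv"
    if motifs_path.exists():
        motifs = read_tsv(motifs_path)
        report["enriched_motifs"] = motifs.to_dict(orient="records")
    msi_path = out / "msi_summary.json"
    if msi_path.exists():
        report["msi"] = json.loads(msi_path.read_text())
    recurrence_path = out / "gene_recurrence.tsv"
    if recurrence_path.exists():
        rec = read_tsv(recurrence_path)
        report["gene_recurrence"] = rec.head(10).to_dict(orient="records")
    sv_path = out / "sv_summary.json"
    if sv_path.exists():
        report["sv"] = json.loads(sv_path.read_text())
    microbe_path = out / "microbiome.tsv"
    if microbe_path.exists():
        mic = read_tsv(microbe_path)
        report["microbiome"] = {
            "retained_species": sorted(mic[mic["retained"] == 1]["species"]),
            "screened_species": int(len(mic)),
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "somatic": stage_somatic,
    "spectrum": stage_spectrum,
    "context": stage_context,
    "msi": stage_msi,
    "svfilter": stage_svfilter,
    "microbe": stage_microbe,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns the report."""
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        raise ParameterError(f"unknown stages: {sorted(unknown)}")
    report: dict = {}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        result = _STAGE_FUNCS[stage](cfg)
        if stage == "report":
            report = result
    return report
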