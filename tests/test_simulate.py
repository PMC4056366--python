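"""Generator contracts: planting, determinism, placement and read support."""

from __future__ import annotations

import math

import pytest

from gcsig.errors import ParameterError, PlacementError, SizingError
from gcsig.io import write_fasta
from gcsig.motifs import Motif
from gcsig.msi import scan_homopolymers
from gcsig.sequtil import revcomp
from gcsig.simulate import (
    AuxSpec,
    GenomeSpec,
    SignatureMixture,
    SpeciesSpec,
    TractSpec,
    generate_reference,
    simulate_aux_data,
    simulate_read_support,
    simulate_variants,
)

from conftest import tpcpa_mixture


class TestGenerateReference:
    def test_planted_tracts_are_exactly_scannable(self, tract_reference):
        tracts = scan_homopolymers(tract_reference.sequences, min_length=8, base="T")
        assert len(tracts) == 10
        assert all(t.length == 8 for t in tracts)
        planted = {(t.chrom, t.start) for t in tract_reference.tracts}
        assert {(t.chrom, t.start) for t in tracts} == planted

    def test_seeded_determinism_byte_identical_fasta(self, tmp_path):
        spec = GenomeSpec(
            chrom_lengths={"chrA": 20_000},
            planted_tracts=(TractSpec("T", 8, 5),),
            seed=3,
        )
        paths = []
        for i in range(2):
            ref = generate_reference(spec)
            p = tmp_path / f"ref{i}.fa"
            write_fasta(ref.sequences, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_degenerate_composition_only_tract_is_non_background(self):
        spec = GenomeSpec(
            chrom_lengths={"chr1": 5_000},
            base_composition={"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0},
            planted_tracts=(TractSpec("T", 8, 1),),
            gene_count=2,
            seed=5,
        )
        ref = generate_reference(spec)
        seq = ref.sequences["chr1"]
        tract = ref.tracts[0]
        non_a = {i for i, b in enumerate(seq) if b != "A"}
        assert non_a == set(range(tract.start, tract.end))
        assert seq[tract.start : tract.end] == "T" * 8

    def test_oversized_tract_raises_sizing_error(self):
        spec = GenomeSpec(
            chrom_lengths={"chr1": 100},
            planted_tracts=(TractSpec("T", 200, 1),),
            seed=0,
        )
        with pytest.raises(SizingError):
            generate_reference(spec)

    def test_exon_fraction_approximately_honoured(self, signature_reference):
        total = sum(len(s) for s in signature_reference.sequences.values())
        exon_bp = sum(e - s for _, s, e in signature_reference.exons)
        assert 0.5 * 0.05 <= exon_bp / total <= 1.5 * 0.05

    def test_invalid_composition_rejected(self):
        spec = GenomeSpec(
            chrom_lengths={"chr1": 1000},
            base_composition={"A": 0.7, "C": 0.2, "G": 0.2, "T": 0.2},
        )
        with pytest.raises(ParameterError):
            spec.validate()


class TestSimulateVariants:
    def test_truth_matches_emitted_reference(self, sixty_forty_variants, signature_reference):
        seqs = signature_reference.sequences
        for v in sixty_forty_variants.all:
            assert seqs[v.chrom][v.pos0] == v.ref
            window = seqs[v.chrom][v.pos0 - 2 : v.pos0 + 3]
            if v.ref in "AG":
                window = revcomp(window)
            assert window == v.context

    def test_seeded_determinism(self, signature_reference):
        mixture = tpcpa_mixture(500, 500)
        a = simulate_variants(signature_reference, mixture, seed=9)
        b = simulate_variants(signature_reference, mixture, seed=9)
        assert a.all == b.all

    def test_exclusive_context_forces_motif(self, signature_reference):
        mixture = SignatureMixture(
            somatic_class_probs={"C>A": 1.0},
            germline_class_probs={"C>A": 1.0},
            n_somatic=300,
            context_multipliers={
                "C>A": ((Motif.flanks("T", "A"), math.inf),)
            },
        )
        sim = simulate_variants(signature_reference, mixture, seed=4)
        assert len(sim.somatic) == 300
        for v in sim.somatic:
            assert v.vclass == "C>A"
            assert v.context[1] == "T" and v.context[3] == "A"

    def test_exome_restricted_class_stays_in_exons(self, signature_reference):
        mixture = SignatureMixture(
            somatic_class_probs={"C>T": 1.0},
            germline_class_probs={"C>T": 1.0},
            n_somatic=400,
            exome_only_classes=frozenset({"C>T"}),
        )
        sim = simulate_variants(signature_reference, mixture, seed=6)
        assert all(v.region == "exome" for v in sim.somatic)

    def test_missing_context_raises_placement_error(self):
        spec = GenomeSpec(
            chrom_lengths={"chr1": 2_000},
            base_composition={"A": 0.5, "C": 0.0, "G": 0.0, "T": 0.5},
            gene_count=2,
            seed=1,
        )
        ref = generate_reference(spec)
        mixture = SignatureMixture(
            somatic_class_probs={"C>A": 1.0},
            germline_class_probs={"T>C": 1.0},
            n_somatic=10,
        )
        with pytest.raises(PlacementError):
            simulate_variants(ref, mixture, seed=2)

    def test_msi_rate_zero_emits_no_indels(self, tract_reference):
        mixture = SignatureMixture(
            somatic_class_probs={"C>A": 1.0},
            germline_class_probs={"C>A": 1.0},
            n_somatic=50,
            msi_deletion_rate=0.0,
        )
        sim = simulate_variants(tract_reference, mixture, seed=3)
        assert all(v.kind == "snv" for v in sim.somatic)

    def test_mixture_recovery_within_two_points(self, sixty_forty_variants):
        classes = [v.vclass for v in sixty_forty_variants.somatic if v.kind == "snv"]
        frac_ca = classes.count("C>A") / len(classes)
        assert abs(frac_ca - 0.60) < 0.02


class TestReadSupport:
    def test_mean_alt_reads_near_binomial_mean(self, signature_reference):
        mixture = tpcpa_mixture(1_000, 0, multiplier=1.0)
        sim = simulate_variants(signature_reference, mixture, seed=12)
        table = simulate_read_support(
            sim.somatic, mean_depth=100, dispersion=0.0, vaf=0.5, seed=13
        )
        tumor = table[table["sample"] == "tumor"]
        assert len(tumor) == 1_000
        assert (tumor["depth"] == 100).all()
        assert 48 <= tumor["alt_reads"].mean() <= 52

    def test_vaf_zero_gives_no_variant_reads(self, signature_reference):
        mixture = tpcpa_mixture(100, 0, multiplier=1.0)
        sim = simulate_variants(signature_reference, mixture, seed=12)
        table = simulate_read_support(
            sim.somatic, mean_depth=50, dispersion=0.1, vaf=0.0, seed=14
        )
        assert (table["alt_reads"] == 0).all()

    def test_same_seed_identical_tables(self, signature_reference):
        mixture = tpcpa_mixture(200, 0, multiplier=1.0)
        sim = simulate_variants(signature_reference, mixture, seed=12)
        t1 = simulate_read_support(sim.somatic, 60, 0.05, 0.5, seed=7)
        t2 = simulate_read_support(sim.somatic, 60, 0.05, 0.5, seed=7)
        assert t1.equals(t2)

    def test_strand_counts_sum_to_alt_reads(self, signature_reference):
        mixture = tpcpa_mixture(300, 0, multiplier=1.0)
        sim = simulate_variants(signature_reference, mixture, seed=12)
        table = simulate_read_support(sim.somatic, 60, 0.05, 0.5, seed=8)
        assert (table["alt_fwd"] + table["alt_rev"] == table["alt_reads"]).all()
        assert (table["alt_reads"] <= table["depth"]).all()

    def test_bad_parameters_rejected(self):
        with pytest.raises(ParameterError):
            simulate_read_support([], mean_depth=-1, dispersion=0, vaf=0.5, seed=0)
        with pytest.raises(ParameterError):
            simulate_read_support([], mean_depth=10, dispersion=-0.5, vaf=0.5, seed=0)


class TestAuxData:
    def test_zero_somatic_fraction_tumor_equals_normal(self):
        spec = AuxSpec(chrom_lengths={"chr1": 10_000_000}, n_clusters=30,
                       fraction_somatic=0.0)
        aux = simulate_aux_data(spec, seed=5)
        cols = ["size", "chrom5", "start5", "end5", "chrom3", "start3", "end3",
                "sv_type"]
        assert aux.tumor_clusters[cols].equals(aux.normal_clusters[cols])

    def test_species_window_request_is_honoured(self):
        spec = AuxSpec(
            chrom_lengths={"chr1": 1_000_000},
            species=(SpeciesSpec("bug", 100_000, 20, 5),),
        )
        aux = simulate_aux_data(spec, seed=6)
        windows = {int(p) // 1000 for p in aux.microbial["position"]}
        assert len(windows) == 5

    def test_window_request_exceeding_genome_raises(self):
        spec = AuxSpec(
            chrom_lengths={"chr1": 1_000_000},
            species=(SpeciesSpec("bug", 3_000, 10, 10),),
        )
        with pytest.raises(SizingError):
            simulate_aux_data(spec, seed=0)

    def test_low_complexity_species_reads_are_repetitive(self):
        from gcsig.microbiome import low_complexity_filter

        spec = AuxSpec(
            chrom_lengths={"chr1": 1_000_000},
            species=(SpeciesSpec("junk", 50_000, 10, 3, low_complexity=True),),
        )
        aux = simulate_aux_data(spec, seed=7)
        assert all(
            not low_complexity_filter(s).keep for s in aux.microbial["sequence"]
        )
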