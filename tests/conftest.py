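"""Shared synthetic fixtures; everything is generated at test time."""

from __future__ import annotations

import pytest

from gcsig.motifs import Motif
from gcsig.simulate import (
    GenomeSpec,
    SignatureMixture,
    TractSpec,
    generate_reference,
    simulate_variants,
)


@pytest.fixture(scope="session")
def tract_reference():
    """100 kbp single-chromosome reference with ten planted 8-T tracts."""
    spec = GenomeSpec(
        chrom_lengths={"chr1": 100_000},
        planted_tracts=(TractSpec("T", 8, 10),),
        exon_fraction=0.05,
        gene_count=20,
        seed=11,
    )
    return generate_reference(spec)


@pytest.fixture(scope="session")
def signature_reference():
    """Larger two-chromosome reference for signature-recovery runs."""
    spec = GenomeSpec(
        chrom_lengths={"chr1": 200_000, "chr2": 200_000},
        planted_tracts=(TractSpec("T", 8, 60),),
        exon_fraction=0.05,
        gene_count=50,
        seed=23,
    )
    return generate_reference(spec)


@pytest.fixture(scope="session")
def sixty_forty_variants(signature_reference):
    """20,000 somatic SNVs planted as a 60/40 C>A / C>T mixture."""
    mixture = SignatureMixture(
        somatic_class_probs={"C>A": 0.6, "C>T": 0.4},
        germline_class_probs={"C>A": 0.5, "C>T": 0.5},
        n_somatic=20_000,
        n_germline=2_000,
    )
    return simulate_variants(signature_reference, mixture, seed=101)


def tpcpa_mixture(n_somatic: int, n_germline: int, multiplier: float = 5.0):
    """C>A-only mixture with a planted TpCpA context multiplier."""
    return SignatureMixture(
        somatic_class_probs={"C>A": 1.0},
        germline_class_probs={"C>A": 1.0},
        n_somatic=n_somatic,
        n_germline=n_germline,
        context_multipliers={"C>A": ((Motif.flanks("T", "A"), multiplier),)},
    )
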