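"""Tumor/normal filter rules, boundaries, left-alignment and the partition."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcsig.errors import DataCompletenessError, IntegrityError
from gcsig.somatic import (
    GERMLINE,
    REASON_DEPTH,
    REASON_NORMAL_SUPPORT,
    REASON_STRAND,
    REASON_VAF,
    REJECTED,
    SOMATIC,
    AlleleSupport,
    GenotypeCall,
    call_somatic_indels,
    call_somatic_snvs,
    left_align_indel,
)


def snv(sample, pos, ref="C", alt="A", gt=None):
    return GenotypeCall(
        sample=sample, chrom="chr1", pos=pos, ref=ref, alt=alt,
        genotype=gt or (ref, alt),
    )


def indel(sample, pos, ref, alt):
    return GenotypeCall(
        sample=sample, chrom="chr1", pos=pos, ref=ref, alt=alt,
        genotype=(ref, alt),
    )


def support(depth, alt_reads, fwd=None):
    fwd = alt_reads // 2 if fwd is None else fwd
    return AlleleSupport(depth, alt_reads, fwd, alt_reads - fwd)


class TestSomaticSnvRule:
    @pytest.mark.parametrize(
        "normal_alt_reads,expected_status,expected_reason",
        [
            (0, SOMATIC, None),
            (1, SOMATIC, None),  # boundary: "< 2 variant reads" passes at 1
            (2, REJECTED, REASON_NORMAL_SUPPORT),
        ],
    )
    def test_normal_read_threshold(self, normal_alt_reads, expected_status,
                                   expected_reason):
        result = call_somatic_snvs(
            [snv("tumor", 100)],
            [],
            {("chr1", 100, "C", "A"): support(40, normal_alt_reads)},
        )
        assert result[0].status == expected_status
        assert result[0].reason == expected_reason

    def test_identical_calls_are_germline(self):
        result = call_somatic_snvs([snv("tumor", 50)], [snv("normal", 50)], {})
        assert result[0].status == GERMLINE

    def test_same_allele_set_in_normal_rejected(self):
        # normal carries the same alleles under a different record: not somatic
        tumor = snv("tumor", 60, gt=("A", "A"))
        normal = GenotypeCall("normal", "chr1", 60, "C", "T", ("A", "A"))
        result = call_somatic_snvs([tumor], [normal], {})
        assert result[0].status == REJECTED

    def test_missing_support_row_is_an_error(self):
        with pytest.raises(DataCompletenessError):
            call_somatic_snvs([snv("tumor", 100)], [], {})

    def test_partition_every_call_has_one_status(self):
        rng = np.random.default_rng(42)
        tumor, normal, sup = [], [], {}
        for pos in range(1, 501):
            t = snv("tumor", pos)
            tumor.append(t)
            kind = rng.integers(0, 3)
            if kind == 0:
                normal.append(snv("normal", pos))
            else:
                sup[("chr1", pos, "C", "A")] = support(30, int(rng.integers(0, 4)))
        result = call_somatic_snvs(tumor, normal, sup)
        assert len(result) == len(tumor)
        assert all(r.status in (SOMATIC, GERMLINE, REJECTED) for r in result)


class TestSomaticIndelRule:
    REF = {"chr1": "A" * 2000}

    def test_all_thresholds_at_boundary_pass(self):
        sup = {("chr1", 100, "AT", "A"): AlleleSupport(10, 2, 1, 1)}
        result = call_somatic_indels(
            [indel("tumor", 100, "AT", "A")], sup, [], reference=None
        )
        assert result[0].status == SOMATIC

    def test_single_strand_support_rejected(self):
        sup = {("chr1", 100, "AT", "A"): AlleleSupport(10, 2, 2, 0)}
        result = call_somatic_indels([indel("tumor", 100, "AT", "A")], sup, [])
        assert result[0].status == REJECTED
        assert result[0].reason == REASON_STRAND

    def test_depth_below_ten_rejected(self):
        sup = {("chr1", 100, "AT", "A"): AlleleSupport(9, 9, 5, 4)}
        result = call_somatic_indels([indel("tumor", 100, "AT", "A")], sup, [])
        assert result[0].status == REJECTED
        assert result[0].reason == REASON_DEPTH

    def test_vaf_below_twenty_percent_rejected(self):
        sup = {("chr1", 100, "AT", "A"): AlleleSupport(100, 19, 10, 9)}
        result = call_somatic_indels([indel("tumor", 100, "AT", "A")], sup, [])
        assert result[0].status == REJECTED
        assert result[0].reason == REASON_VAF

    def test_normal_indel_call_blocks_somatic(self):
        sup = {("chr1", 100, "AT", "A"): AlleleSupport(50, 25, 12, 13)}
        result = call_somatic_indels(
            [indel("tumor", 100, "AT", "A")],
            sup,
            [indel("normal", 100, "AT", "A")],
        )
        assert result[0].status == GERMLINE

    def test_positional_dialects_compare_equal_after_left_alignment(self):
        # same deletion reported at different positions in tumor and normal
        ref = {"chr1": "AGCTTTTTTGCA"}
        tumor_call = indel("tumor", 5, "TT", "T")  # delete one T mid-tract
        normal_call = indel("normal", 8, "TT", "T")  # same event, right-shifted
        sup = {("chr1", 3, "CT", "C"): AlleleSupport(50, 25, 12, 13)}
        result = call_somatic_indels([tumor_call], sup, [normal_call], ref)
        assert result[0].status == GERMLINE


class TestLeftAlign:
    def test_homopolymer_deletion_shifts_to_first_repeat_base(self):
        # reference A TTTT G: deleting the 4th T equals deleting the 1st
        ref = {"chr1": "ATTTTG"}
        call = indel("t", 4, "TT", "T")
        aligned = left_align_indel(call, ref)
        assert (aligned.pos, aligned.ref, aligned.alt) == (1, "AT", "A")

    def test_non_repeat_deletion_unchanged(self):
        ref = {"chr1": "AGCTA"}
        call = indel("t", 2, "GC", "G")
        aligned = left_align_indel(call, ref)
        assert (aligned.pos, aligned.ref, aligned.alt) == (2, "GC", "G")

    def test_idempotence_on_examples(self):
        ref = {"chr1": "ATTTTG"}
        once = left_align_indel(indel("t", 4, "TT", "T"), ref)
        twice = left_align_indel(once, ref)
        assert once == twice

    def test_reference_mismatch_raises(self):
        ref = {"chr1": "AGCTA"}
        with pytest.raises(IntegrityError):
            left_align_indel(indel("t", 2, "TT", "T"), ref)

    @settings(max_examples=200, derandomize=True)
    @given(
        run_length=st.integers(2, 12),
        del_offset=st.integers(0, 11),
        del_size=st.integers(1, 3),
    )
    def test_left_alignment_idempotent_in_homopolymers(
        self, run_length, del_offset, del_size
    ):
        """Deleting any slice of a homopolymer normalises to the run start."""
        seq = "G" + "T" * run_length + "C"
        ref = {"chr1": seq}
        start = min(del_offset, run_length - 1)
        size = min(del_size, run_length - start)
        # anchored representation of deleting `size` T's at offset `start`
        pos = 1 + start  # 1-based anchor at the base before the deleted T's
        anchor = seq[pos - 1]
        call = indel("t", pos, anchor + "T" * size, anchor)
        once = left_align_indel(call, ref)
        assert once.pos == 1
        assert once.ref == "G" + "T" * size
        assert once.alt == "G"
        assert left_align_indel(once, ref) == once


def brute_force_indel_status(depth, alt_reads, fwd, rev, normal_has_indel):
    """Independent re-statement of the four indel predicates."""
    if normal_has_indel:
        return "not-somatic"
    ok = (
        depth >= 10
        and alt_reads / depth >= 0.20
        and fwd >= 1
        and rev >= 1
    )
    return SOMATIC if ok else "not-somatic"


def test_indel_filter_matches_brute_force_on_simulated_sites():
    """Exact agreement with predicate re-application on 10,000 random sites."""
    rng = np.random.default_rng(2024)
    calls, sup, normal = [], {}, []
    expected = []
    for i in range(10_000):
        pos = i + 1
        depth = int(rng.integers(1, 40))
        alt_reads = int(rng.integers(0, depth + 1))
        fwd = int(rng.integers(0, alt_reads + 1))
        rev = alt_reads - fwd
        normal_has = bool(rng.random() < 0.1)
        calls.append(indel("tumor", pos, "AT", "A"))
        sup[("chr1", pos, "AT", "A")] = AlleleSupport(depth, alt_reads, fwd, rev)
        if normal_has:
            normal.append(indel("normal", pos, "AT", "A"))
        expected.append(
            brute_force_indel_status(depth, alt_reads, fwd, rev, normal_has)
        )
    result = call_somatic_indels(calls, sup, normal)
    got = [r.status if r.status == SOMATIC else "not-somatic" for r in result]
    assert got == expected
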