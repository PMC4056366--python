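"""Homopolymer scan, indel context classification and the recurrence test."""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from gcsig.errors import ParameterError
from gcsig.msi import (
    HomopolymerTract,
    classify_indel_context,
    gene_recurrence_table,
    homopolymer_background_rate,
    msi_summary,
    recurrence_test,
    scan_homopolymers,
    tract_index,
)
from gcsig.simulate import (
    GenomeSpec,
    TractSpec,
    generate_reference,
    simulate_msi_cohort,
)


def regex_scan_oracle(seq, min_length, base=None):
    """Maximal-run oracle via regular expressions."""
    out = []
    for b in "ACGT":
        if base is not None and b != base:
            continue
        for m in re.finditer(f"{b}{{{min_length},}}", seq):
            out.append((m.start(), m.end(), b))
    return sorted(out)


class TestScanHomopolymers:
    def test_single_tract_with_coordinates(self):
        tracts = scan_homopolymers({"c": "AATTTTTTTTGC"}, min_length=6)
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.start, t.end, t.base, t.length) == (2, 10, "T", 8)

    def test_no_tracts_in_alternating_sequence(self):
        assert scan_homopolymers({"c": "ACGTACGTACGT"}, min_length=5) == []

    def test_run_spanning_whole_contig(self):
        tracts = scan_homopolymers({"c": "TTTTTT"}, min_length=6)
        assert len(tracts) == 1
        assert (tracts[0].start, tracts[0].end) == (0, 6)

    def test_n_bases_break_runs(self):
        tracts = scan_homopolymers({"c": "TTTNTTT"}, min_length=3)
        assert [(t.start, t.end) for t in tracts] == [(0, 3), (4, 7)]

    def test_min_length_below_two_rejected(self):
        with pytest.raises(ParameterError):
            scan_homopolymers({"c": "AAAA"}, min_length=1)

    def test_matches_regex_oracle_on_random_references(self):
        rng = np.random.default_rng(314)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=100_000))
            got = sorted(
                (t.start, t.end, t.base)
                for t in scan_homopolymers({"c": seq}, min_length=5)
            )
            assert got == regex_scan_oracle(seq, 5)


class TestClassifyIndelContext:
    TRACTS = tract_index([HomopolymerTract("c", 10, 18, "T")])

    def test_one_bp_t_deletion_in_tract_is_signature(self):
        call = classify_indel_context("c", 10, "del", "T", self.TRACTS)
        assert call.is_signature
        assert call.repeat_context == "mononucleotide"
        assert call.tract_length == 8

    def test_two_bp_deletion_not_signature_class(self):
        call = classify_indel_context("c", 10, "del", "TT", self.TRACTS)
        assert call.repeat_context == "mononucleotide"
        assert not call.is_signature

    def test_non_repeat_deletion(self):
        call = classify_indel_context("c", 50, "del", "C", self.TRACTS)
        assert call.repeat_context == "non-repeat"
        assert call.tract_base is None


class TestMsiSummary:
    def test_planted_signature_fraction_recovered(self):
        rng = np.random.default_rng(7)
        tracts = tract_index([HomopolymerTract("c", 10, 18, "T")])
        calls = []
        for i in range(2_000):
            if rng.random() < 0.8:
                calls.append(classify_indel_context("c", 10, "del", "T", tracts))
            else:
                calls.append(classify_indel_context("c", 500, "ins", "AAA", tracts))
        summary = msi_summary(calls)
        assert abs(summary["signature_fraction"] - 0.80) < 0.03

    def test_insertions_only_give_zero_signature(self):
        tracts = tract_index([])
        calls = [
            classify_indel_context("c", i, "ins", "AAA", tracts) for i in range(50)
        ]
        assert msi_summary(calls)["signature_fraction"] == 0.0

    def test_empty_input_warns(self):
        summary = msi_summary([])
        assert summary["n_indels"] == 0
        assert "warning" in summary

    def test_uniform_deletions_affect_tracts_in_proportion(self):
        """Uniform per-tract deletions: affected counts match tract counts."""
        from scipy import stats

        tract_list = [
            HomopolymerTract("c", 100 * i, 100 * i + 8, "T") for i in range(60)
        ] + [HomopolymerTract("c", 50_000 + 100 * i, 50_000 + 100 * i + 9, "T")
             for i in range(30)]
        index = tract_index(tract_list)
        rng = np.random.default_rng(12)
        calls = []
        for t in tract_list:
            if rng.random() < 0.5:
                calls.append(classify_indel_context(t.chrom, t.start, "del", "T", index))
        summary = msi_summary(calls)
        by_len = summary["affected_tracts_by_length"]
        observed = [by_len.get(8, 0), by_len.get(9, 0)]
        expected = np.array([60, 30]) / 90 * sum(observed)
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.01


class TestBackgroundRate:
    def _cohort(self, n_tracts, n_samples, mutated_pairs):
        tracts = [HomopolymerTract("c", 100 * i, 100 * i + 8, "T") for i in range(n_tracts)]
        index = tract_index(tracts)
        per_sample = {f"s{j}": [] for j in range(n_samples)}
        for sample_idx, tract_idx in mutated_pairs:
            t = tracts[tract_idx]
            per_sample[f"s{sample_idx}"].append(
                classify_indel_context(t.chrom, t.start, "del", "T", index)
            )
        return per_sample, tracts

    def test_pooled_rate_direct_arithmetic(self):
        pairs = [(j % 4, j) for j in range(18)]  # 18 distinct (sample, tract) pairs
        per_sample, tracts = self._cohort(100, 4, pairs)
        rate, n = homopolymer_background_rate(per_sample, tracts, length=8)
        assert n == 100
        assert rate == pytest.approx(18 / 400)

    def test_no_mutations_rate_zero(self):
        per_sample, tracts = self._cohort(10, 3, [])
        rate, _ = homopolymer_background_rate(per_sample, tracts, length=8)
        assert rate == 0.0

    def test_everything_mutated_rate_one(self):
        pairs = [(s, t) for s in range(2) for t in range(5)]
        per_sample, tracts = self._cohort(5, 2, pairs)
        rate, _ = homopolymer_background_rate(per_sample, tracts, length=8)
        assert rate == 1.0

    def test_duplicate_deletions_count_once(self):
        per_sample, tracts = self._cohort(10, 1, [(0, 0), (0, 0), (0, 0)])
        rate, _ = homopolymer_background_rate(per_sample, tracts, length=8)
        assert rate == pytest.approx(1 / 10)

    def test_missing_length_class_rejected(self):
        per_sample, tracts = self._cohort(10, 1, [])
        with pytest.raises(ParameterError):
            homopolymer_background_rate(per_sample, tracts, length=9)


def exact_binomial_tail(k, n, p):
    """Extended-precision one-sided tail via rational arithmetic."""
    pf = Fraction(p).limit_denominator(10**9)
    total = Fraction(0)
    for j in range(k, n + 1):
        total += comb(n, j) * pf**j * (1 - pf) ** (n - j)
    return total


class TestRecurrenceTest:
    def test_zero_carriers_gives_p_one(self):
        assert recurrence_test(0, 14, 0.05).p_raw == pytest.approx(1.0)

    def test_matches_rational_arithmetic_oracle(self):
        rng = np.random.default_rng(99)
        cases = [(7, 14, 0.048), (12, 14, 0.045)] + [
            (
                int(rng.integers(0, n + 1)),
                int(n),
                float(rng.uniform(0.01, 0.5)),
            )
            for n in rng.integers(2, 101, size=30)
        ]
        for k, n, p in cases:
            oracle = float(exact_binomial_tail(k, n, p))
            got = recurrence_test(k, n, p).p_raw
            assert got == pytest.approx(oracle, rel=1e-12)

    def test_monotone_in_k_and_p(self):
        ps = [recurrence_test(k, 14, 0.05).p_raw for k in range(15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        qs = [recurrence_test(7, 14, p).p_raw for p in (0.01, 0.05, 0.1, 0.3)]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_bonferroni_never_below_raw_and_capped(self):
        res = recurrence_test(2, 14, 0.3, family_size=1000)
        assert res.p_bonferroni >= res.p_raw
        assert res.p_bonferroni <= 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            recurrence_test(5, 4, 0.1)
        with pytest.raises(ParameterError):
            recurrence_test(1, 4, 0.0)


@pytest.fixture(scope="module")
def cohort_reference():
    spec = GenomeSpec(
        chrom_lengths={"chr1": 120_000},
        planted_tracts=(TractSpec("T", 8, 50),),
        exon_fraction=0.4,
        gene_count=30,
        seed=41,
    )
    return generate_reference(spec)


class TestEndToEndRecurrence:
    def test_planted_recurrent_tract_flagged(self, cohort_reference):
        cohort = simulate_msi_cohort(
            cohort_reference, n_samples=12, background_rate=0.05,
            planted={0: 10}, seed=42, min_tract_length=8,
        )
        index = tract_index(cohort_reference.tracts)
        per_sample = {
            s: [
                classify_indel_context(v.chrom, v.pos0, "del", v.ref, index, s)
                for v in vs
            ]
            for s, vs in cohort.items()
        }
        table = gene_recurrence_table(
            per_sample, cohort_reference.tracts, length=8,
            background_rate=0.05,
        )
        planted = cohort_reference.tracts[0]
        top = table.iloc[0]
        assert (top["chrom"], top["tract_start"]) == (planted.chrom, planted.start)
        assert top["k"] == 10
        assert top["p_bonferroni"] < 0.05

    def test_unplanted_false_positive_rate_at_most_alpha(self):
        """200-replicate null simulation: Bonferroni keeps FWER <= alpha."""
        from scipy import stats as ss

        rng = np.random.default_rng(77)
        alpha = 0.05
        n_tracts, n_samples, p_bg = 100, 12, 0.05
        reps = 200
        false_flags = 0
        for _ in range(reps):
            ks = rng.binomial(n_samples, p_bg, size=n_tracts)
            p_raw = ss.binom.sf(ks - 1, n_samples, p_bg)
            if (np.minimum(1.0, p_raw * n_tracts) <= alpha).any():
                false_flags += 1
        assert false_flags / reps <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)
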