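"""Alignment, change counting, codon classification and group statistics."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partcurator.curation import StandardFeature
from partcurator.variant_analysis import (
    DEFAULT_SCORING,
    align,
    classify_coding_changes,
    compare_group,
    compare_variant,
    derived_variant_columns,
    group_stats,
    group_variants,
    percent_no_aa_change,
    pooled_change_percentages,
    round_half_up,
    select_consensus,
)
from conftest import curated_synthetic

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


def _enumerate_best(a, b, sc=DEFAULT_SCORING):
    """Exhaustive oracle: evaluate every alignment path of two short strings.

    Border gap runs (before the first / after the last aligned pair) are free
    and uncounted; returns the best (score, changes, gap_columns) under the
    lexicographic objective (max score, min changes, min gap columns).
    """
    n, m = len(a), len(b)
    best = (0, 0, 0)

    def evaluate(cols):
        idx = [k for k, (x, y) in enumerate(cols) if x != "-" and y != "-"]
        if not idx:
            return (0, 0, 0)
        score = changes = gapcols = 0
        prev = None
        for k in range(idx[0], idx[-1] + 1):
            x, y = cols[k]
            if x != "-" and y != "-":
                score += sc.match if x == y else sc.mismatch
                changes += x != y
                prev = "M"
            elif y == "-":
                score += sc.gap_extend if prev == "X" else sc.gap_open
                changes += 1
                gapcols += 1
                prev = "X"
            else:
                score += sc.gap_extend if prev == "Y" else sc.gap_open
                changes += 1
                gapcols += 1
                prev = "Y"
        return (score, changes, gapcols)

    def rec(i, j, cols):
        nonlocal best
        if i == n and j == m:
            t = evaluate(cols)
            if (t[0], -t[1], -t[2]) > (best[0], -best[1], -best[2]):
                best = t
            return
        if i < n:
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < m:
            rec(i, j + 1, cols + [("-", b[j])])
        if i < n and j < m:
            rec(i + 1, j + 1, cols + [(a[i], b[j])])

    rec(0, 0, [])
    return best


class TestAlign:
    @settings(max_examples=60, deadline=None)
    @given(DNA)
    def test_self_alignment_is_zero_comparison(self, seq):
        aln = align(seq, seq)
        assert aln.n_bp_changes == 0
        assert aln.score == len(seq) * DEFAULT_SCORING.match
        comp = compare_variant(seq, seq)
        assert not comp.border_only

    def test_border_trim_counts_nothing(self):
        rng = random.Random(0)
        consensus = "".join(rng.choice("ACGT") for _ in range(60))
        aln = align(consensus[5:], consensus)
        assert aln.n_bp_changes == 0
        assert aln.b_span == (5, 60)
        comp = compare_variant(consensus[5:], consensus)
        assert comp.border_only and comp.n_bp_changes == 0

    def test_single_internal_substitution(self):
        rng = random.Random(1)
        consensus = "".join(rng.choice("ACGT") for _ in range(100))
        variant = list(consensus)
        variant[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[variant[50]]
        aln = align("".join(variant), consensus)
        assert aln.n_bp_changes == 1 and aln.n_mismatches == 1

    def test_internal_deletion_counts_gap_columns(self):
        rng = random.Random(2)
        consensus = "".join(rng.choice("ACGT") for _ in range(80))
        variant = consensus[:40] + consensus[43:]
        aln = align(variant, consensus)
        assert aln.n_indel_columns == 3 and aln.n_mismatches == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align("", "ACGT")

    @settings(max_examples=80, deadline=None)
    @given(DNA, DNA)
    def test_change_count_symmetric_under_swap(self, a, b):
        fwd, rev = align(a, b), align(b, a)
        assert fwd.n_bp_changes == rev.n_bp_changes
        assert fwd.n_mismatches == rev.n_mismatches
        assert fwd.score == rev.score

    def test_matches_exhaustive_enumeration_on_tiny_alphabet(self):
        strings = [
            "".join(p)
            for L in (1, 2, 3)
            for p in itertools.product("AC", repeat=L)
        ]
        for a in strings:
            for b in strings:
                aln = align(a, b)
                assert (aln.score, aln.n_bp_changes, aln.n_indel_columns) == _enumerate_best(a, b)

    def test_matches_exhaustive_enumeration_on_random_pairs(self):
        rng = random.Random(99)
        for _ in range(150):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            aln = align(a, b)
            assert (aln.score, aln.n_bp_changes, aln.n_indel_columns) == _enumerate_best(a, b)


class TestClassifyCodingChanges:
    def test_synonymous_third_base(self):
        # codon 1: GCT -> GCC, both alanine
        result = classify_coding_changes("GATGCCAAAGATGGG", "GATGCTAAAGATGGG")
        assert (result.n_synonymous, result.n_conservative, result.n_nonconservative) == (1, 0, 0)
        assert result.identical_protein

    def test_conservative_substitution(self):
        # codon 1: CTT (Leu) -> ATT (Ile): BLOSUM62(L, I) = 2 > 0
        result = classify_coding_changes("GATATTAAAGATGGG", "GATCTTAAAGATGGG")
        assert (result.n_synonymous, result.n_conservative, result.n_nonconservative) == (0, 1, 0)
        assert not result.identical_protein

    def test_nonconservative_substitution(self):
        # codon 1: GGT (Gly) -> TGT (Cys): BLOSUM62(G, C) = -3
        result = classify_coding_changes("GATTGTAAAGATGGG", "GATGGTAAAGATGGG")
        assert (result.n_synonymous, result.n_conservative, result.n_nonconservative) == (0, 0, 1)

    def test_identical_dna_identical_protein(self):
        result = classify_coding_changes("ATGAAATAA", "ATGAAATAA")
        assert result.identical_protein
        assert (result.n_synonymous, result.n_conservative, result.n_nonconservative) == (0, 0, 0)

    def test_inframe_indel_counts_nonconservative(self):
        consensus = "ATGGCTGCAGATTTAGGGTGA"
        variant = consensus[:9] + consensus[12:]  # clean 3 bp deletion
        result = classify_coding_changes(variant, consensus)
        assert result.n_nonconservative == 3
        assert not result.identical_protein and not result.frameshift

    def test_frameshift_flagged_not_classified(self):
        consensus = "ATGGCTGCAGATTTAGGGTGA"
        variant = consensus[:9] + consensus[10:]  # 1 bp deletion
        result = classify_coding_changes(variant, consensus)
        assert result.frameshift
        assert (result.n_synonymous, result.n_conservative, result.n_nonconservative) == (0, 0, 0)

    def test_ambiguous_base_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 4"):
            classify_coding_changes("ATGNAA", "ATGAAA")


class TestConsensusAndGroups:
    def _feat(self, name, seq, n_instances, key="promoter"):
        return StandardFeature(
            base_name=name,
            sequence=seq,
            feature_key=key,
            display_name=name,
            instances=[(f"P{i}", "1..10", "forward") for i in range(n_instances)],
        )

    def test_most_used_variant_is_consensus(self):
        variants = [
            self._feat("x", "AAAA", 10),
            self._feat("x", "CCCC", 3),
            self._feat("x", "GGGG", 1),
        ]
        assert select_consensus(variants).sequence == "AAAA"

    def test_tie_goes_to_longer_sequence(self):
        variants = [self._feat("x", "A" * 180, 5), self._feat("x", "C" * 200, 5)]
        assert select_consensus(variants).sequence == "C" * 200

    def test_singleton_group_is_its_own_consensus(self):
        only = self._feat("x", "ACGT", 1)
        assert select_consensus([only]) is only

    def test_group_variants_partitions_by_base_name(self):
        feats = [
            self._feat("MCS", "AAAA", 1),
            self._feat("MCS", "CCCC", 1),
            self._feat("other", "GGGG", 1),
        ]
        feats[0].display_name, feats[1].display_name = "MCS-001", "MCS-002"
        groups = {g.base_name: g for g in group_variants(feats)}
        assert groups["MCS"].n_variants == 2
        assert groups["other"].n_variants == 1

    def test_singleton_group_stats_are_zero(self):
        group = group_variants([self._feat("x", "ACGTACGT", 3)])[0]
        stats = group_stats(group, compare_group(group))
        assert stats.n_bp_changes == 0
        assert stats.changes_per_variant == 0.0
        assert stats.changes_per_1000bp == 0.0

    @pytest.mark.parametrize("seed", [0, 11, 42])
    def test_planted_family_edits_recovered_exactly(self, seed):
        synthetic, library, _ = curated_synthetic(seed=seed)
        truth = synthetic.ground_truth
        groups = {g.base_name: g for g in group_variants(library)}
        for family, expected_variants in truth.families.items():
            group = groups[family]
            expected_by_seq = {v.sequence: v for v in expected_variants}
            consensus_expected = next(v for v in expected_variants if v.is_consensus)
            assert group.consensus.sequence == consensus_expected.sequence
            for variant in group.variants:
                if variant is group.consensus:
                    continue
                expected = expected_by_seq[variant.sequence]
                comp = compare_variant(variant, group.consensus, coding=group.is_coding)
                assert comp.n_mismatches == expected.n_mismatches
                assert comp.n_indel_columns == expected.n_indel_columns
                assert comp.border_only == expected.border_only
                if group.is_coding:
                    assert comp.n_synonymous == expected.n_synonymous
                    assert comp.n_conservative == expected.n_conservative
                    assert comp.n_nonconservative == expected.n_nonconservative
                    assert comp.identical_protein == expected.identical_protein


class TestTableArithmetic:
    def test_rounding_convention_is_half_up(self):
        assert round_half_up(2.5) == 3
        assert round_half_up(1.25, 1) == 1.3
        assert round_half_up(0.15, 1) == 0.2

    @pytest.mark.parametrize(
        "n_var,n_changes,total_len,n_len_only,cpv,cp1000",
        [
            (12, 12, 1154, 3, 1.0, 10.4),    # a highly conserved promoter family
            (14, 282, 14376, 3, 20.1, 19.6),  # a highly variable resistance gene
            (120, 238, 43989, 27, 2.0, 5.4),  # pooled non-coding totals
        ],
    )
    def test_derived_columns_from_integer_inputs(
        self, n_var, n_changes, total_len, n_len_only, cpv, cp1000
    ):
        derived = derived_variant_columns(n_var, n_changes, total_len, n_len_only)
        assert derived["changes_per_variant"] == cpv
        assert derived["changes_per_1000bp"] == cp1000

    def test_pooled_change_percentages_sum_preserving(self):
        assert pooled_change_percentages(641, 54, 156) == (75, 7, 18)
        assert pooled_change_percentages(10, 0, 0) == (100, 0, 0)
        assert pooled_change_percentages(0, 0, 0) == (0, 0, 0)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 5000), st.integers(0, 5000), st.integers(0, 5000))
    def test_pooled_percentages_always_sum_to_100(self, a, b, c):
        pct = pooled_change_percentages(a, b, c)
        assert sum(pct) == (100 if a + b + c else 0)
        for share, count in zip(pct, (a, b, c)):
            if a + b + c:
                assert abs(share - 100 * count / (a + b + c)) < 1

    def test_percent_no_aa_change(self):
        assert percent_no_aa_change(134, 190) == 71
        assert percent_no_aa_change(0, 10) == 0
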