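"""Variant families, consensus comparison and variation statistics.

Standard features sharing a base name form a variant group.  Each variant is
compared against the group consensus (the most-used variant) by pairwise
global alignment with free end gaps: leading and trailing gap runs are
border differences and are not counted, each internal mismatch and each
internal gap column counts as one bp change.  For coding features, each
mismatch is assigned to its consensus codon and classified as synonymous
(identical translation), conservative (positive BLOSUM62 score) or
non-conservative; internal indel columns count as non-conservative.

The alignment objective is lexicographic — maximize score (match +1,
mismatch -2, gap open -5, gap extend -1), then minimize counted bp changes,
then minimize internal gap columns — which makes the reported change counts
well-defined even when several alignments reach the optimal score.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .curation import FeatureLibrary, StandardFeature

_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for printed tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    result = Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(result) if ndigits > 0 else int(result) if ndigits == 0 else float(result)


@dataclass(frozen=True)
class AlignmentScoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5  # score of the first column of a gap run
    gap_extend: int = -1


DEFAULT_SCORING = AlignmentScoring()


@dataclass
class Alignment:
    """An ends-free pairwise alignment with border-aware change counts."""

    aligned_a: str
    aligned_b: str
    score: int
    n_mismatches: int
    n_indel_columns: int
    a_span: tuple[int, int]  # internal (aligned) region within sequence a
    b_span: tuple[int, int]
    internal_a: str
    internal_b: str

    @property
    def n_bp_changes(self) -> int:
        return self.n_mismatches + self.n_indel_columns


_M, _X, _Y, _START = 0, 1, 2, 3
_NEG = float("-inf")


def align(a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING) -> Alignment:
    """Ends-free global alignment of ``a`` against ``b`` (Gotoh, affine gaps).

    End gaps are free and uncounted; the internal region is flanked by
    aligned pairs.  Raises ``ValueError`` on empty input.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    K = n + m + 3
    K2 = K * K
    # packed = score*K^2 - changes*K - gapcols; linear in per-column deltas
    d_match = scoring.match * K2
    d_mismatch = scoring.mismatch * K2 - K
    d_open = scoring.gap_open * K2 - K - 1
    d_ext = scoring.gap_extend * K2 - K - 1

    width = m + 1
    M = [[_NEG] * width for _ in range(n + 1)]
    X = [[_NEG] * width for _ in range(n + 1)]
    Y = [[_NEG] * width for _ in range(n + 1)]
    pM = [bytearray(width) for _ in range(n + 1)]
    pX = [bytearray(width) for _ in range(n + 1)]
    pY = [bytearray(width) for _ in range(n + 1)]

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        pMi, pXi, pYi = pM[i], pX[i], pY[i]
        for j in range(1, m + 1):
            # M: consume a[i-1] and b[j-1]
            best, ptr = Mp[j - 1], _M
            if Xp[j - 1] > best:
                best, ptr = Xp[j - 1], _X
            if Yp[j - 1] > best:
                best, ptr = Yp[j - 1], _Y
            if 0 > best:
                # start the internal region here; the skipped prefixes of both
                # sequences are leading border runs and are free
                best, ptr = 0, _START
            if best > _NEG:
                Mi[j] = best + (d_match if ai == b[j - 1] else d_mismatch)
                pMi[j] = ptr
            # X: gap in b, consume a[i-1]
            best, ptr = _NEG, _M
            if Mp[j] > _NEG:
                best, ptr = Mp[j] + d_open, _M
            if Yp[j] > _NEG and Yp[j] + d_open > best:
                best, ptr = Yp[j] + d_open, _Y
            if Xp[j] > _NEG and Xp[j] + d_ext > best:
                best, ptr = Xp[j] + d_ext, _X
            if best > _NEG:
                Xi[j] = best
                pXi[j] = ptr
            # Y: gap in a, consume b[j-1]
            best, ptr = _NEG, _M
            if Mi[j - 1] > _NEG:
                best, ptr = Mi[j - 1] + d_open, _M
            if Xi[j - 1] > _NEG and Xi[j - 1] + d_open > best:
                best, ptr = Xi[j - 1] + d_open, _X
            if Yi[j - 1] > _NEG and Yi[j - 1] + d_ext > best:
                best, ptr = Yi[j - 1] + d_ext, _Y
            if best > _NEG:
                Yi[j] = best
                pYi[j] = ptr

    # Endpoint: the last aligned pair may fall anywhere — the remaining
    # suffixes of both sequences are trailing border runs and are free; the
    # empty alignment (pure border) scores 0.
    best_val, best_pos = 0, None
    for i in range(1, n + 1):
        Mi = M[i]
        for j in range(1, m + 1):
            if Mi[j] > best_val:
                best_val, best_pos = Mi[j], (i, j)

    if best_pos is None:
        aligned_a = a + "-" * m
        aligned_b = "-" * n + b
        return Alignment(aligned_a, aligned_b, 0, 0, 0, (0, 0), (0, 0), "", "")

    i, j = best_pos
    i1, j1 = i, j
    cols_a: list[str] = []
    cols_b: list[str] = []
    state = _M
    score = 0
    n_mismatch = 0
    n_gapcols = 0
    while True:
        if state == _M:
            ca, cb = a[i - 1], b[j - 1]
            cols_a.append(ca)
            cols_b.append(cb)
            if ca == cb:
                score += scoring.match
            else:
                score += scoring.mismatch
                n_mismatch += 1
            ptr = pM[i][j]
            i, j = i - 1, j - 1
            if ptr == _START:
                break
            state = ptr
        elif state == _X:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            n_gapcols += 1
            ptr = pX[i][j]
            score += scoring.gap_extend if ptr == _X else scoring.gap_open
            i -= 1
            state = ptr
        else:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            n_gapcols += 1
            ptr = pY[i][j]
            score += scoring.gap_extend if ptr == _Y else scoring.gap_open
            j -= 1
            state = ptr
    i0, j0 = i, j
    internal_a = "".join(reversed(cols_a))
    internal_b = "".join(reversed(cols_b))
    aligned_a = a[:i0] + "-" * j0 + internal_a + a[i1:] + "-" * (m - j1)
    aligned_b = "-" * i0 + b[:j0] + internal_b + "-" * (n - i1) + b[j1:]
    return Alignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        n_mismatches=n_mismatch,
        n_indel_columns=n_gapcols,
        a_span=(i0, i1),
        b_span=(j0, j1),
        internal_a=internal_a,
        internal_b=internal_b,
    )


# ---------------------------------------------------------------------------
# Variant comparison
# ---------------------------------------------------------------------------

@dataclass
class VariantComparison:
    variant_name: str
    border_only: bool
    n_bp_changes: int
    n_mismatches: int
    n_indel_columns: int
    n_synonymous: int = 0
    n_conservative: int = 0
    n_nonconservative: int = 0
    identical_protein: bool = False
    frameshift: bool = False


@dataclass
class CodingChanges:
    n_synonymous: int
    n_conservative: int
    n_nonconservative: int
    identical_protein: bool
    frameshift: bool = False


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def _indel_runs(internal_a: str, internal_b: str) -> list[int]:
    runs: list[int] = []
    current = 0
    for ca, cb in zip(internal_a, internal_b):
        if ca == "-" or cb == "-":
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def classify_coding_changes(
    variant: str,
    consensus: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> CodingChanges:
    """Classify internal bp changes of a coding variant against its consensus.

    Codons are read in the consensus frame (frame 0 of the full consensus
    sequence).  Variants whose internal indels break the frame are not
    classified at the codon level and are flagged ``frameshift``.
    """
    for seq, label in ((variant, "variant"), (consensus, "consensus")):
        bad = next((k for k, c in enumerate(seq.upper()) if c not in "ACGT"), None)
        if bad is not None:
            raise ValueError(f"untranslatable {label} sequence at position {bad + 1}")
    aln = align(variant, consensus, scoring)
    frameshift = any(run % 3 for run in _indel_runs(aln.internal_a, aln.internal_b))
    if frameshift:
        return CodingChanges(0, 0, 0, False, frameshift=True)

    consensus = consensus.upper()
    # consensus position -> aligned variant character, and mismatch positions
    var_at: dict[int, str] = {}
    mismatches: list[int] = []
    b_pos = aln.b_span[0]
    for ca, cb in zip(aln.internal_a, aln.internal_b):
        if cb == "-":
            continue
        if ca != "-":
            var_at[b_pos] = ca
            if ca != cb:
                mismatches.append(b_pos)
        b_pos += 1

    by_codon: dict[int, list[int]] = {}
    for pos in mismatches:
        by_codon.setdefault(pos // 3, []).append(pos)

    n_syn = n_cons = n_non = 0
    blosum = _blosum62()
    for codon_idx, positions in sorted(by_codon.items()):
        start = codon_idx * 3
        c_codon = consensus[start : start + 3]
        if len(c_codon) < 3:
            n_non += len(positions)  # partial trailing codon
            continue
        v_codon = "".join(var_at.get(start + off, "-") for off in range(3))
        if "-" in v_codon:
            n_non += len(positions)  # codon disrupted by an indel or border
            continue
        aa_c, aa_v = _translate_codon(c_codon), _translate_codon(v_codon)
        if aa_c == aa_v:
            n_syn += len(positions)
        elif "*" in (aa_c, aa_v):
            n_non += len(positions)
        elif blosum[aa_c, aa_v] > 0:
            n_cons += len(positions)
        else:
            n_non += len(positions)
    n_non += aln.n_indel_columns  # in-frame indels still change the protein
    identical = aln.n_indel_columns == 0 and n_cons == 0 and n_non == 0
    return CodingChanges(n_syn, n_cons, n_non, identical, frameshift=False)


def compare_variant(
    variant: StandardFeature | str,
    consensus: StandardFeature | str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    coding: bool | None = None,
) -> VariantComparison:
    """Compare one variant against the consensus sequence of its group."""
    v_seq = variant.sequence if isinstance(variant, StandardFeature) else variant
    c_seq = consensus.sequence if isinstance(consensus, StandardFeature) else consensus
    v_name = variant.display_name if isinstance(variant, StandardFeature) else "variant"
    if coding is None:
        coding = (
            isinstance(variant, StandardFeature)
            and variant.feature_key.upper() == "CDS"
        )
    aln = align(v_seq, c_seq, scoring)
    comparison = VariantComparison(
        variant_name=v_name,
        border_only=aln.n_bp_changes == 0 and v_seq.upper() != c_seq.upper(),
        n_bp_changes=aln.n_bp_changes,
        n_mismatches=aln.n_mismatches,
        n_indel_columns=aln.n_indel_columns,
    )
    if coding:
        changes = classify_coding_changes(v_seq, c_seq, scoring)
        comparison.n_synonymous = changes.n_synonymous
        comparison.n_conservative = changes.n_conservative
        comparison.n_nonconservative = changes.n_nonconservative
        comparison.identical_protein = changes.identical_protein
        comparison.frameshift = changes.frameshift
    return comparison


# ---------------------------------------------------------------------------
# Variant groups and table statistics
# ---------------------------------------------------------------------------

@dataclass
class VariantGroup:
    base_name: str
    variants: list[StandardFeature]
    consensus: StandardFeature

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def is_coding(self) -> bool:
        return self.consensus.feature_key.upper() == "CDS"


def select_consensus(variants: Sequence[StandardFeature]) -> StandardFeature:
    """Most-used variant; ties broken by longer sequence, then lexicographic."""
    if not variants:
        raise ValueError("empty variant group")
    return sorted(variants, key=lambda f: (-f.occurrence_count, -f.length, f.sequence))[0]


def group_variants(library: FeatureLibrary | Iterable[StandardFeature]) -> list[VariantGroup]:
    """One group per base name (singletons included), consensus selected."""
    features = list(library)
    by_name: dict[str, list[StandardFeature]] = {}
    for feat in features:
        by_name.setdefault(feat.base_name, []).append(feat)
    groups = []
    for name in sorted(by_name):
        variants = sorted(by_name[name], key=lambda f: f.display_name)
        groups.append(VariantGroup(name, variants, select_consensus(variants)))
    return groups


@dataclass
class VariantGroupStats:
    base_name: str
    n_variants: int
    n_occurrences: int
    n_bp_changes: int
    total_length_bp: int
    changes_per_variant: float
    changes_per_1000bp: float
    n_length_only: int
    pct_length_only: float


def derived_variant_columns(
    n_variants: int, n_bp_changes: int, total_length_bp: int, n_length_only: int
) -> dict[str, float]:
    """The derived columns of the variant-statistics table, as printed
    (ratios to one decimal, half-up)."""
    return {
        "changes_per_variant": round_half_up(n_bp_changes / n_variants, 1) if n_variants else 0.0,
        "changes_per_1000bp": round_half_up(1000 * n_bp_changes / total_length_bp, 1)
        if total_length_bp
        else 0.0,
        "pct_length_only": round_half_up(100 * n_length_only / n_variants, 1) if n_variants else 0.0,
    }


def compare_group(
    group: VariantGroup, scoring: AlignmentScoring = DEFAULT_SCORING
) -> list[VariantComparison]:
    """Compare every non-consensus variant against the group consensus."""
    return [
        compare_variant(v, group.consensus, scoring, coding=group.is_coding)
        for v in group.variants
        if v is not group.consensus
    ]


def group_stats(group: VariantGroup, comparisons: Sequence[VariantComparison]) -> VariantGroupStats:
    n_variants = group.n_variants
    n_changes = sum(c.n_bp_changes for c in comparisons)
    total_length = sum(v.length for v in group.variants)
    n_length_only = sum(1 for c in comparisons if c.border_only)
    derived = derived_variant_columns(n_variants, n_changes, total_length, n_length_only)
    return VariantGroupStats(
        base_name=group.base_name,
        n_variants=n_variants,
        n_occurrences=sum(v.occurrence_count for v in group.variants),
        n_bp_changes=n_changes,
        total_length_bp=total_length,
        changes_per_variant=derived["changes_per_variant"],
        changes_per_1000bp=derived["changes_per_1000bp"],
        n_length_only=n_length_only,
        pct_length_only=derived["pct_length_only"],
    )


@dataclass
class CodingChangeStats:
    pct_synonymous: int
    pct_conservative: int
    pct_nonconservative: int
    pct_variants_no_aa_change: int
    n_synonymous: int = 0
    n_conservative: int = 0
    n_nonconservative: int = 0
    n_variants_no_aa_change: int = 0


def pooled_change_percentages(n_syn: int, n_cons: int, n_non: int) -> tuple[int, int, int]:
    """Integer percentages of the three change types, summing to exactly 100.

    Uses largest-remainder rounding so the printed triple is a true
    composition (the three classes partition all counted bp changes).
    """
    total = n_syn + n_cons + n_non
    if total == 0:
        return (0, 0, 0)
    exact = [100 * n_syn / total, 100 * n_cons / total, 100 * n_non / total]
    floors = [int(x) for x in exact]
    short = 100 - sum(floors)
    order = sorted(range(3), key=lambda k: (exact[k] - floors[k], exact[k]), reverse=True)
    for k in order[:short]:
        floors[k] += 1
    return tuple(floors)  # type: ignore[return-value]


def percent_no_aa_change(n_no_change: int, n_variants: int) -> int:
    return round_half_up(100 * n_no_change / n_variants) if n_variants else 0


def coding_summary(
    analyzed: Sequence[tuple[VariantGroup, Sequence[VariantComparison]]],
) -> tuple[CodingChangeStats, pd.DataFrame]:
    """Pool change-type counts over coding groups; also emit per-group rows.

    A group's consensus counts as a variant with no amino-acid changes.
    """
    rows = []
    tot_syn = tot_cons = tot_non = tot_no_aa = tot_variants = 0
    for group, comparisons in analyzed:
        syn = sum(c.n_synonymous for c in comparisons)
        cons = sum(c.n_conservative for c in comparisons)
        non = sum(c.n_nonconservative for c in comparisons)
        no_aa = 1 + sum(1 for c in comparisons if c.identical_protein)
        pct = pooled_change_percentages(syn, cons, non)
        rows.append(
            {
                "feature": group.base_name,
                "pct_synonymous": pct[0],
                "pct_conservative": pct[1],
                "pct_nonconservative": pct[2],
                "pct_variants_no_aa_change": percent_no_aa_change(no_aa, group.n_variants),
            }
        )
        tot_syn += syn
        tot_cons += cons
        tot_non += non
        tot_no_aa += no_aa
        tot_variants += group.n_variants
    pct = pooled_change_percentages(tot_syn, tot_cons, tot_non)
    stats = CodingChangeStats(
        pct_synonymous=pct[0],
        pct_conservative=pct[1],
        pct_nonconservative=pct[2],
        pct_variants_no_aa_change=percent_no_aa_change(tot_no_aa, tot_variants),
        n_synonymous=tot_syn,
        n_conservative=tot_cons,
        n_nonconservative=tot_non,
        n_variants_no_aa_change=tot_no_aa,
    )
    return stats, pd.DataFrame(rows)


def variant_table(
    library: FeatureLibrary,
    min_variants: int = 2,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Variant-group statistics tables over the whole library.

    Returns (group statistics with totals, per-variant comparisons, coding
    change-type summary with a pooled total row).
    """
    groups = [g for g in group_variants(library) if g.n_variants >= min_variants]
    stat_rows, comp_rows, coding_pairs = [], [], []
    for group in groups:
        comparisons = compare_group(group, scoring)
        stats = group_stats(group, comparisons)
        stat_rows.append(
            {
                "feature": stats.base_name,
                "coding": group.is_coding,
                "n_variants": stats.n_variants,
                "n_occurrences": stats.n_occurrences,
                "n_bp_changes": stats.n_bp_changes,
                "total_length_bp": stats.total_length_bp,
                "changes_per_variant": stats.changes_per_variant,
                "changes_per_1000bp": stats.changes_per_1000bp,
                "n_length_only": stats.n_length_only,
                "pct_length_only": stats.pct_length_only,
            }
        )
        for comp in comparisons:
            comp_rows.append({"feature": group.base_name, **comp.__dict__})
        if group.is_coding:
            coding_pairs.append((group, comparisons))
    stats_df = pd.DataFrame(stat_rows)
    if not stats_df.empty:
        totals = {
            "feature": "Total",
            "coding": None,
            "n_variants": int(stats_df.n_variants.sum()),
            "n_occurrences": int(stats_df.n_occurrences.sum()),
            "n_bp_changes": int(stats_df.n_bp_changes.sum()),
            "total_length_bp": int(stats_df.total_length_bp.sum()),
            "n_length_only": int(stats_df.n_length_only.sum()),
        }
        derived = derived_variant_columns(
            totals["n_variants"],
            totals["n_bp_changes"],
            totals["total_length_bp"],
            totals["n_length_only"],
        )
        totals.update(derived)
        stats_df = pd.concat([stats_df, pd.DataFrame([totals])], ignore_index=True)
    coding_stats, coding_df = coding_summary(coding_pairs)
    if not coding_df.empty:
        coding_df = pd.concat(
            [
                coding_df,
                pd.DataFrame(
                    [
                        {
                            "feature": "Total",
                            "pct_synonymous": coding_stats.pct_synonymous,
                            "pct_conservative": coding_stats.pct_conservative,
                            "pct_nonconservative": coding_stats.pct_nonconservative,
                            "pct_variants_no_aa_change": coding_stats.pct_variants_no_aa_change,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return stats_df, pd.DataFrame(comp_rows), coding_df
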