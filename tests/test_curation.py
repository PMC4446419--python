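"""The five-step reduction to the Standard Features Library."""

import random
from collections import Counter, defaultdict

import pytest

from partcurator.curation import (
    FeatureLibrary,
    collapse_perfect_duplicates,
    curate,
    disambiguate_homonyms,
    flag_inconsistent,
    merge_description_variants,
    merge_name_variants,
    rematerialize,
)
from partcurator.feature_extraction import extract_all
from partcurator.synthetic_library import LibrarySpec, generate
from conftest import curated_synthetic, make_feature


class TestPerfectDuplicates:
    def test_shared_triples_collapse_with_provenance(self):
        feats = [
            make_feature("A", "ACGT", "d", parent=f"P{i}", location=f"{i}..{i+3}")
            for i in range(3)
        ] + [make_feature("A", "ACGT", "other"), make_feature("B", "ACGT", "d")]
        std = collapse_perfect_duplicates(feats)
        assert len(std) == 3
        counts = sorted(f.occurrence_count for f in std)
        assert counts == [1, 1, 3]
        assert sum(f.occurrence_count for f in std) == len(feats)

    def test_all_distinct_unchanged(self):
        feats = [make_feature(f"n{i}", "ACGT" + "A" * i) for i in range(4)]
        assert len(collapse_perfect_duplicates(feats)) == 4

    def test_sequence_identity_case_insensitive(self):
        std = collapse_perfect_duplicates(
            [make_feature("A", "acgt"), make_feature("A", "ACGT")]
        )
        assert len(std) == 1 and std[0].sequence == "ACGT"


class TestInconsistentRemoval:
    def test_ambiguous_bases_removed(self):
        std = collapse_perfect_duplicates([make_feature("A", "ATGNCA")])
        kept, removed = flag_inconsistent(std)
        assert kept == [] and len(removed) == 1

    def test_plain_single_interval_cds_kept(self):
        std = collapse_perfect_duplicates([make_feature("A", "ATGAAATAA", key="CDS")])
        kept, removed = flag_inconsistent(std)
        assert len(kept) == 1 and removed == []

    def test_joined_cds_removed_but_joined_noncoding_kept(self):
        std = collapse_perfect_duplicates(
            [
                make_feature("A", "ATGAAATAA", key="CDS", is_joined=True),
                make_feature("B", "ACGTACGT", key="misc_feature", is_joined=True),
            ]
        )
        kept, removed = flag_inconsistent(std)
        assert [f.base_name for f in removed] == ["A"]
        assert [f.base_name for f in kept] == ["B"]


class TestNameMerge:
    def test_most_used_name_wins_and_losers_become_synonyms(self):
        feats = (
            [make_feature("A", "ACGTACGT", parent=f"p{i}") for i in range(5)]
            + [make_feature("B", "ACGTACGT", parent=f"q{i}") for i in range(2)]
            + [make_feature("C", "ACGTACGT")]
        )
        merged = merge_name_variants(collapse_perfect_duplicates(feats))
        assert len(merged) == 1
        feat = merged[0]
        assert feat.base_name == "A"
        assert feat.synonyms == {"B", "C"}
        assert feat.occurrence_count == 8

    def test_tie_broken_lexicographically(self):
        feats = [make_feature("B", "ACGTACGT", parent=f"p{i}") for i in range(3)] + [
            make_feature("A", "ACGTACGT", parent=f"q{i}") for i in range(3)
        ]
        merged = merge_name_variants(collapse_perfect_duplicates(feats))
        assert merged[0].base_name == "A" and merged[0].synonyms == {"B"}

    def test_different_descriptions_not_merged_here(self):
        feats = [make_feature("A", "ACGTACGT", "d1"), make_feature("B", "ACGTACGT", "d2")]
        assert len(merge_name_variants(collapse_perfect_duplicates(feats))) == 2


class TestDescriptionMerge:
    def test_most_used_description_wins(self):
        feats = [make_feature("A", "ACGTACGT", "D1", parent=f"p{i}") for i in range(4)] + [
            make_feature("A", "ACGTACGT", "D2")
        ]
        merged = merge_description_variants(collapse_perfect_duplicates(feats))
        assert len(merged) == 1
        assert merged[0].description == "D1" and merged[0].occurrence_count == 5

    def test_nonempty_wins_when_more_used(self):
        feats = [make_feature("A", "ACGTACGT", "real", parent=f"p{i}") for i in range(2)] + [
            make_feature("A", "ACGTACGT", "")
        ]
        merged = merge_description_variants(collapse_perfect_duplicates(feats))
        assert merged[0].description == "real"

    def test_identical_descriptions_untouched(self):
        feats = [make_feature("A", "ACGTACGT", "d"), make_feature("B", "TTTTCCCC", "d")]
        assert len(merge_description_variants(collapse_perfect_duplicates(feats))) == 2


class TestHomonymDisambiguation:
    def test_numeric_suffixes_by_usage(self):
        feats = [make_feature("MCS", "AAAACCCC", parent=f"p{i}") for i in range(3)] + [
            make_feature("MCS", "GGGGTTTT")
        ]
        std = disambiguate_homonyms(collapse_perfect_duplicates(feats))
        names = sorted(f.display_name for f in std)
        assert names == ["MCS-001", "MCS-002"]
        by_name = {f.display_name: f for f in std}
        assert by_name["MCS-001"].occurrence_count == 3  # most used gets 001

    def test_unique_names_untouched_and_count_preserved(self):
        feats = [make_feature("unique", "ACGTACGT"), make_feature("MCS", "AAAACCCC"),
                 make_feature("MCS", "GGGGTTTT")]
        std = disambiguate_homonyms(collapse_perfect_duplicates(feats))
        assert len(std) == 3
        assert {f.display_name for f in std} == {"unique", "MCS-001", "MCS-002"}

    def test_nameless_features_get_placeholders(self):
        feats = [make_feature("", "ACGTACGT"), make_feature("", "TTTTAAAA")]
        std = disambiguate_homonyms(collapse_perfect_duplicates(feats))
        assert {f.display_name for f in std} == {"unnamed-0001", "unnamed-0002"}


def _brute_force_curate(feats):
    """Naive reference: enumerate groupings directly over plain tuples."""
    triples = defaultdict(list)
    for f in feats:
        triples[(f.sequence.upper(), f.name, f.description)].append(f)
    items = [
        {
            "seq": seq, "name": name, "desc": desc, "n": len(group),
            "bad": bool(set(seq) - set("ACGT"))
            or (any(g.is_joined for g in group) and group[0].feature_key.upper() == "CDS"),
        }
        for (seq, name, desc), group in triples.items()
    ]
    counts = {"n_raw": len(feats), "n_after_perfect_dedup": len(items)}
    items = [it for it in items if not it["bad"]]
    counts["n_after_inconsistent_removal"] = len(items)
    # step 3: same (seq, desc), different names
    by_sd = defaultdict(list)
    for it in items:
        by_sd[(it["seq"], it["desc"])].append(it)
    items = []
    for group in by_sd.values():
        usage = Counter()
        for it in group:
            usage[it["name"]] += it["n"]
        winner = min(sorted(usage), key=lambda n: (-usage[n], n))
        items.append({**group[0], "name": winner, "n": sum(it["n"] for it in group)})
    counts["n_after_name_merge"] = len(items)
    # step 4: same (name, seq), different descriptions
    by_ns = defaultdict(list)
    for it in items:
        by_ns[(it["name"], it["seq"])].append(it)
    items = []
    for group in by_ns.values():
        usage = Counter()
        for it in group:
            usage[it["desc"]] += it["n"]
        winner = min(sorted(usage), key=lambda d: (-usage[d], d))
        items.append({**group[0], "desc": winner, "n": sum(it["n"] for it in group)})
    counts["n_after_description_merge"] = counts["n_final"] = len(items)
    # step 5: suffix homonyms
    unnamed = 0
    for it in items:
        if not it["name"]:
            unnamed += 1
            it["name"] = f"unnamed-{unnamed:04d}"
    by_name = defaultdict(list)
    for it in items:
        by_name[it["name"]].append(it)
    final = set()
    renamed = 0
    for name, group in by_name.items():
        if len(group) == 1:
            final.add((name, group[0]["seq"], group[0]["n"]))
        else:
            group.sort(key=lambda it: (-it["n"], it["seq"]))
            for i, it in enumerate(group, 1):
                final.add((f"{name}-{i:03d}", it["seq"], it["n"]))
                renamed += 1
    counts["n_renamed"] = renamed
    return counts, final


class TestCuratePipeline:
    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_report_matches_generator_ground_truth(self, seed):
        synthetic, library, report = curated_synthetic(seed=seed)
        assert report.counts() == synthetic.ground_truth.report_counts
        histogram = Counter(f.occurrence_count for f in library)
        assert dict(histogram) == synthetic.ground_truth.usage_histogram

    def test_counts_monotone_and_step5_preserving(self, synthetic_curated):
        _, _, report = synthetic_curated
        c = report.counts()
        assert (
            c["n_raw"]
            >= c["n_after_perfect_dedup"]
            >= c["n_after_inconsistent_removal"]
            >= c["n_after_name_merge"]
            >= c["n_after_description_merge"]
            == c["n_final"]
        )

    def test_provenance_conserved_after_inconsistent_removal(self, synthetic_curated):
        synthetic, library, report = synthetic_curated
        features, _ = extract_all(synthetic.records)
        std = collapse_perfect_duplicates(features)
        kept, removed = flag_inconsistent(std)
        kept_instances = sum(f.occurrence_count for f in kept)
        assert sum(f.occurrence_count for f in library) == kept_instances

    def test_curation_idempotent(self, synthetic_curated):
        _, library, report = synthetic_curated
        second, report2 = curate(rematerialize(library))
        assert report2.n_raw == sum(f.occurrence_count for f in library)
        assert report2.n_after_perfect_dedup == report2.n_final == len(library)

    def test_order_invariance(self):
        lib = generate(LibrarySpec(seed=4))
        features, _ = extract_all(lib.records)
        library1, _ = curate(features)
        shuffled = features[:]
        random.Random(0).shuffle(shuffled)
        library2, _ = curate(shuffled)
        key = lambda lib: [
            (f.display_name, f.sequence, f.occurrence_count, sorted(f.synonyms))
            for f in lib.features
        ]
        assert key(library1) == key(library2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_reference_on_small_libraries(self, seed):
        lib = generate(
            LibrarySpec(seed=seed, n_base_features=8, n_plasmids=5,
                        duplicate_group_size=3, homonym_variants_per_family=2)
        )
        features, _ = extract_all(lib.records)
        assert len({(f.sequence, f.name, f.description) for f in features}) <= 50
        expected_counts, expected_final = _brute_force_curate(features)
        library, report = curate(features)
        assert report.counts() == expected_counts
        got = {(f.display_name, f.sequence, f.occurrence_count) for f in library}
        assert got == expected_final

    def test_rename_table_applied_before_name_merge(self):
        feats = [
            make_feature("HIV-1 5' LTR", "ACGTACGT", "ltr"),
            make_feature("HIV-1 3' LTR", "ACGTACGT", "ltr"),
        ]
        library, report = curate(feats, renames={"HIV-1 5' LTR": "HIV-1 LTR",
                                                 "HIV-1 3' LTR": "HIV-1 LTR"})
        assert len(library) == 1
        feat = library.features[0]
        assert feat.display_name == "HIV-1 LTR"
        assert feat.occurrence_count == 2


class TestLibraryPersistence:
    def test_save_load_round_trip(self, tmp_path, synthetic_curated):
        _, library, _ = synthetic_curated
        library.save(tmp_path / "lib")
        loaded = FeatureLibrary.load(tmp_path / "lib")
        original = [
            (f.display_name, f.base_name, f.sequence, f.description, f.feature_key,
             sorted(f.synonyms), sorted(f.hosts), sorted(f.instances))
            for f in library.features
        ]
        reloaded = [
            (f.display_name, f.base_name, f.sequence, f.description, f.feature_key,
             sorted(f.synonyms), sorted(f.hosts), sorted(f.instances))
            for f in loaded.features
        ]
        assert reloaded == original
        assert loaded.report.counts() == library.report.counts()
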