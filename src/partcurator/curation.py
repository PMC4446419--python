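"""Reduce the raw feature library to a non-redundant Standard Features Library.

The reduction runs five steps, each with per-step accounting:

1. collapse perfect duplicates — identical (sequence, name, description);
2. remove inconsistent features — sequences containing ambiguity codes, and
   CDS features with intron/exon joined locations;
3. merge name variants — identical sequence (and description) under different
   names; the most-used name wins, the others become synonyms;
4. merge description variants — identical (name, sequence) with different
   descriptions; the most-used description wins;
5. disambiguate homonyms — distinct sequences sharing one name receive
   numeric suffixes (``MCS-001``, ``MCS-002``, ...); nameless features get
   placeholder names.  Step 5 renames only and never changes the count.

Sequence identity is case-insensitive and strand-sensitive: sequences are
already in reading orientation, and reverse-complement pairs are *not*
merged (orientation is a plasmid-level concern, handled at file dedup).
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .feature_extraction import MaterializedFeature

ACGT = frozenset("ACGT")

#: provenance tuple: (record_id, GenBank location string, strand)
Provenance = tuple[str, str, str]


@dataclass
class StandardFeature:
    """A curated, non-redundant feature with full provenance."""

    base_name: str
    sequence: str
    description: str = ""
    feature_key: str = "misc_feature"
    display_name: str = ""
    synonyms: set[str] = field(default_factory=set)
    hosts: set[str] = field(default_factory=set)
    instances: list[Provenance] = field(default_factory=list)
    is_joined: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.display_name:
            self.display_name = self.base_name

    @property
    def occurrence_count(self) -> int:
        return len(self.instances)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sorted_instances(self) -> list[Provenance]:
        return sorted(self.instances)


@dataclass
class CurationReport:
    """Counts and logs for each curation step."""

    n_raw: int = 0
    n_after_perfect_dedup: int = 0
    n_after_inconsistent_removal: int = 0
    n_after_name_merge: int = 0
    n_after_description_merge: int = 0
    n_final: int = 0
    n_renamed: int = 0
    removed_inconsistent: list[dict] = field(default_factory=list)
    name_merges: list[dict] = field(default_factory=list)
    description_merges: list[dict] = field(default_factory=list)
    renames: list[dict] = field(default_factory=list)
    placeholder_named: list[str] = field(default_factory=list)
    applied_renames: list[dict] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "n_raw": self.n_raw,
            "n_after_perfect_dedup": self.n_after_perfect_dedup,
            "n_after_inconsistent_removal": self.n_after_inconsistent_removal,
            "n_after_name_merge": self.n_after_name_merge,
            "n_after_description_merge": self.n_after_description_merge,
            "n_final": self.n_final,
            "n_renamed": self.n_renamed,
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _feature_sort_key(feat: StandardFeature) -> tuple:
    return (feat.base_name, feat.sequence, feat.description)


# ---------------------------------------------------------------------------
# Step 1: perfect duplicates
# ---------------------------------------------------------------------------

def collapse_perfect_duplicates(
    features: Sequence[MaterializedFeature],
) -> list[StandardFeature]:
    """One StandardFeature per distinct (sequence, name, description) triple.

    Provenance records every source instance, so the occurrence counts sum to
    the number of input instances.
    """
    groups: dict[tuple[str, str, str], list[MaterializedFeature]] = defaultdict(list)
    for feat in features:
        groups[(feat.sequence.upper(), feat.name, feat.description)].append(feat)
    result = []
    for (seq, name, desc), members in groups.items():
        keys = Counter(m.feature_key for m in members)
        best_key = max(sorted(keys), key=lambda k: keys[k])
        result.append(
            StandardFeature(
                base_name=name,
                sequence=seq,
                description=desc,
                feature_key=best_key,
                hosts={m.parent_host for m in members},
                instances=[(m.parent_id, m.location, m.strand) for m in members],
                is_joined=any(m.is_joined for m in members),
            )
        )
    result.sort(key=_feature_sort_key)
    return result


# ---------------------------------------------------------------------------
# Step 2: inconsistent features
# ---------------------------------------------------------------------------

def flag_inconsistent(
    features: Sequence[StandardFeature],
) -> tuple[list[StandardFeature], list[StandardFeature]]:
    """Split off ambiguous-alphabet features and intron/exon-joined CDS."""
    kept, removed = [], []
    for feat in features:
        ambiguous = bool(set(feat.sequence) - ACGT)
        joined_cds = feat.is_joined and feat.feature_key.upper() == "CDS"
        (removed if ambiguous or joined_cds else kept).append(feat)
    return kept, removed


# ---------------------------------------------------------------------------
# Steps 3 and 4: usage-weighted merges
# ---------------------------------------------------------------------------

def _merge_group(members: list[StandardFeature], winner: StandardFeature) -> StandardFeature:
    for other in members:
        if other is winner:
            continue
        winner.instances.extend(other.instances)
        winner.hosts |= other.hosts
        winner.synonyms |= other.synonyms
    winner.synonyms.discard(winner.base_name)
    return winner


def merge_name_variants(
    features: Sequence[StandardFeature], report: CurationReport | None = None
) -> list[StandardFeature]:
    """Merge features with identical sequence and description but different names.

    The name with the highest summed occurrence count wins (ties broken
    lexicographically); losing names are retained as synonyms.
    """
    groups: dict[tuple[str, str], list[StandardFeature]] = defaultdict(list)
    for feat in features:
        groups[(feat.sequence, feat.description)].append(feat)
    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        usage: Counter = Counter()
        for m in members:
            usage[m.base_name] += m.occurrence_count
        win_name = max(sorted(usage), key=lambda n: usage[n])
        winner = next(m for m in members if m.base_name == win_name)
        losers = sorted(m.base_name for m in members if m is not winner)
        winner.synonyms |= set(losers)
        merged.append(_merge_group(members, winner))
        if report is not None:
            report.name_merges.append({"kept": win_name, "synonyms": losers})
    merged.sort(key=_feature_sort_key)
    return merged


def merge_description_variants(
    features: Sequence[StandardFeature], report: CurationReport | None = None
) -> list[StandardFeature]:
    """Merge features with identical (name, sequence) but different descriptions."""
    groups: dict[tuple[str, str], list[StandardFeature]] = defaultdict(list)
    for feat in features:
        groups[(feat.base_name, feat.sequence)].append(feat)
    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        usage: Counter = Counter()
        for m in members:
            usage[m.description] += m.occurrence_count
        win_desc = max(sorted(usage), key=lambda d: usage[d])
        winner = next(m for m in members if m.description == win_desc)
        alternates = sorted(m.description for m in members if m is not winner)
        merged.append(_merge_group(members, winner))
        if report is not None:
            report.description_merges.append(
                {"name": winner.base_name, "kept": win_desc, "alternates": alternates}
            )
    merged.sort(key=_feature_sort_key)
    return merged


# ---------------------------------------------------------------------------
# Step 5: homonym disambiguation
# ---------------------------------------------------------------------------

def disambiguate_homonyms(
    features: Sequence[StandardFeature], report: CurationReport | None = None
) -> list[StandardFeature]:
    """Suffix variants sharing one base name; name the nameless.

    Variants are numbered from 001 in order of descending occurrence count,
    ties broken by sequence.  Unique names are left untouched.  Feature count
    never changes.
    """
    result = list(features)
    counter = 0
    for feat in result:
        if not feat.base_name:
            counter += 1
            feat.base_name = f"unnamed-{counter:04d}"
            feat.display_name = feat.base_name
            if report is not None:
                report.placeholder_named.append(feat.base_name)
    by_name: dict[str, list[StandardFeature]] = defaultdict(list)
    for feat in result:
        by_name[feat.base_name].append(feat)
    for name in sorted(by_name):
        members = by_name[name]
        if len(members) == 1:
            members[0].display_name = members[0].base_name
            continue
        members.sort(key=lambda f: (-f.occurrence_count, f.sequence))
        for i, feat in enumerate(members, start=1):
            feat.display_name = f"{feat.base_name}-{i:03d}"
            if report is not None:
                report.renames.append(
                    {"base_name": feat.base_name, "display_name": feat.display_name}
                )
    result.sort(key=lambda f: (f.display_name, f.sequence))
    return result


# ---------------------------------------------------------------------------
# Full pipeline and library container
# ---------------------------------------------------------------------------

def apply_rename_table(
    features: Sequence[StandardFeature],
    renames: dict[str, str],
    report: CurationReport | None = None,
) -> None:
    """User-supplied manual renames (e.g. HIV-1 5'/3' LTR → HIV-1 LTR)."""
    for feat in features:
        if feat.base_name in renames:
            new = renames[feat.base_name]
            if report is not None:
                report.applied_renames.append({"from": feat.base_name, "to": new})
            feat.synonyms.add(feat.base_name)
            feat.base_name = new
            feat.display_name = new
            feat.synonyms.discard(new)


def curate(
    features: Sequence[MaterializedFeature],
    renames: dict[str, str] | None = None,
) -> tuple["FeatureLibrary", CurationReport]:
    """Run curation steps 1–5 in order and return the library plus report."""
    report = CurationReport(n_raw=len(features))
    std = collapse_perfect_duplicates(features)
    report.n_after_perfect_dedup = len(std)
    std, removed = flag_inconsistent(std)
    report.n_after_inconsistent_removal = len(std)
    report.removed_inconsistent = [
        {
            "name": f.base_name,
            "reason": "joined CDS" if f.is_joined and f.feature_key.upper() == "CDS" else "ambiguous bases",
        }
        for f in removed
    ]
    if renames:
        apply_rename_table(std, renames, report)
    std = merge_name_variants(std, report)
    report.n_after_name_merge = len(std)
    std = merge_description_variants(std, report)
    report.n_after_description_merge = len(std)
    std = disambiguate_homonyms(std, report)
    report.n_final = len(std)
    report.n_renamed = len(report.renames)
    library = FeatureLibrary(features=std, report=report)
    return library, report


class FeatureLibrary:
    """The Standard Features Library, persistable as a plain-text directory.

    Layout: ``features.tsv`` (one row per feature), ``sequences.fasta``
    (ids are display names), ``provenance.tsv`` and ``report.json``.
    """

    def __init__(self, features: list[StandardFeature], report: CurationReport | None = None):
        self.features = features
        self.report = report or CurationReport()

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def feature_by_display_name(self, display_name: str) -> StandardFeature:
        for feat in self.features:
            if feat.display_name == display_name:
                return feat
        raise KeyError(display_name)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "display_name": f.display_name,
                "base_name": f.base_name,
                "feature_key": f.feature_key,
                "hosts": ";".join(sorted(f.hosts)),
                "occurrence_count": f.occurrence_count,
                "description": f.description,
                "synonyms": ";".join(sorted(f.synonyms)),
            }
            for f in self.features
        ]
        pd.DataFrame(
            rows,
            columns=[
                "display_name",
                "base_name",
                "feature_key",
                "hosts",
                "occurrence_count",
                "description",
                "synonyms",
            ],
        ).to_csv(directory / "features.tsv", sep="\t", index=False)
        with open(directory / "sequences.fasta", "w") as fasta:
            for f in self.features:
                fasta.write(f">{f.display_name}\n")
                for i in range(0, len(f.sequence), 70):
                    fasta.write(f.sequence[i : i + 70] + "\n")
        prov_rows = [
            {
                "display_name": f.display_name,
                "record_id": rid,
                "location": loc,
                "strand": strand,
            }
            for f in self.features
            for rid, loc, strand in f.sorted_instances()
        ]
        pd.DataFrame(
            prov_rows, columns=["display_name", "record_id", "location", "strand"]
        ).to_csv(directory / "provenance.tsv", sep="\t", index=False)
        (directory / "report.json").write_text(self.report.to_json())

    @classmethod
    def load(cls, directory) -> "FeatureLibrary":
        directory = Path(directory)
        table = pd.read_csv(directory / "features.tsv", sep="\t", keep_default_na=False)
        sequences: dict[str, str] = {}
        name = None
        chunks: list[str] = []
        with open(directory / "sequences.fasta") as fasta:
            for line in fasta:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if name is not None:
                        sequences[name] = "".join(chunks)
                    name = line[1:].strip()
                    chunks = []
                else:
                    chunks.append(line.strip())
            if name is not None:
                sequences[name] = "".join(chunks)
        prov = pd.read_csv(directory / "provenance.tsv", sep="\t", keep_default_na=False)
        prov_map: dict[str, list[Provenance]] = defaultdict(list)
        for row in prov.itertuples(index=False):
            prov_map[row.display_name].append((row.record_id, row.location, row.strand))
        features = []
        for row in table.itertuples(index=False):
            feat = StandardFeature(
                base_name=row.base_name,
                sequence=sequences[row.display_name],
                description=row.description,
                feature_key=row.feature_key,
                display_name=row.display_name,
                synonyms=set(filter(None, str(row.synonyms).split(";"))),
                hosts=set(filter(None, str(row.hosts).split(";"))),
                instances=prov_map.get(row.display_name, []),
            )
            features.append(feat)
        report = CurationReport()
        report_path = directory / "report.json"
        if report_path.exists():
            data = json.loads(report_path.read_text())
            for key, value in data.items():
                if hasattr(report, key):
                    setattr(report, key, value)
        return cls(features=features, report=report)


def rematerialize(library: FeatureLibrary) -> list[MaterializedFeature]:
    """View library features as materialized instances (for idempotence checks)."""
    out = []
    for f in library.features:
        for rid, loc, strand in f.instances:
            out.append(
                MaterializedFeature(
                    feature_key=f.feature_key,
                    name=f.display_name,
                    description=f.description,
                    parent_id=rid,
                    strand=strand,
                    location=loc,
                    sequence=f.sequence,
                    is_joined=False,
                )
            )
    return out
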