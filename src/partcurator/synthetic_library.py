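"""Synthetic GenBank plasmid libraries with planted, fully known structure.

The generator plants perfect-duplicate groups, inconsistent features
(ambiguous bases, intron/exon-joined CDS), name-synonym groups, description
variants and homonym families (with border trims, substitutions and indels —
for coding families with declared synonymous / conservative /
non-conservative intent, verified against the codon table and BLOSUM62 at
generation time).  Every expected pipeline outcome is computed from the
generation plan alone, before any file is written, so curation, variant
analysis and statistics can be checked exactly.

The generator emulates the *structure* of a curated vendor plasmid library
(duplication, annotation inconsistency, host metadata, circular topology),
not its biological sequence composition: backgrounds are uniform random DNA.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

from .plasmid_io import (
    CIRCULAR,
    FORWARD,
    LINEAR,
    REVERSE,
    UNSPECIFIED,
    FeatureInstance,
    PlasmidRecord,
    reverse_complement,
    write_genbank,
)

_BASES = "ACGT"
_KEY_CYCLE = ("CDS", "promoter", "terminator", "misc_feature", "rep_origin", "primer_bind")
_DOMAIN_CYCLE = ("Basic Cloning Vectors", "Expression Vectors", "Shuttle Vectors")


class InfeasibleSpecError(ValueError):
    """The requested features cannot fit on the requested plasmids."""


@dataclass(frozen=True)
class VariantEditPlan:
    """Planted edits of one homonym-family variant relative to the consensus."""

    occurrences: int = 1
    border5: int = 0
    border3: int = 0
    n_substitutions: int = 0  # non-coding substitutions
    indel_lengths: tuple[int, ...] = ()
    n_synonymous: int = 0  # coding substitutions, by intent
    n_conservative: int = 0
    n_nonconservative: int = 0

    @property
    def n_mismatches(self) -> int:
        return (
            self.n_substitutions
            + self.n_synonymous
            + self.n_conservative
            + self.n_nonconservative
        )

    @property
    def n_indel_columns(self) -> int:
        return sum(self.indel_lengths)

    @property
    def n_bp_changes(self) -> int:
        return self.n_mismatches + self.n_indel_columns

    @property
    def border_only(self) -> bool:
        return self.n_bp_changes == 0 and (self.border5 + self.border3) > 0

    @property
    def identical_protein(self) -> bool:
        return self.n_conservative == 0 and self.n_nonconservative == 0 and not self.indel_lengths


def _default_noncoding_plans(n_variants: int) -> tuple[VariantEditPlan, ...]:
    cycle = (
        VariantEditPlan(occurrences=2, border5=5),
        VariantEditPlan(occurrences=1, n_substitutions=2),
        VariantEditPlan(occurrences=1, n_substitutions=1, indel_lengths=(2,)),
        VariantEditPlan(occurrences=1, border3=4, n_substitutions=1),
    )
    return tuple(cycle[i % len(cycle)] for i in range(n_variants - 1))


def _default_coding_plans(n_variants: int) -> tuple[VariantEditPlan, ...]:
    cycle = (
        VariantEditPlan(occurrences=2, n_synonymous=1),
        VariantEditPlan(occurrences=1, n_synonymous=1, n_conservative=1),
        VariantEditPlan(occurrences=1, n_nonconservative=2),
        VariantEditPlan(occurrences=1, border5=3),
        VariantEditPlan(occurrences=1, indel_lengths=(3,)),
    )
    return tuple(cycle[i % len(cycle)] for i in range(n_variants - 1))


@dataclass
class LibrarySpec:
    """Study conditions for one synthetic library."""

    seed: int = 0
    n_plasmids: int = 8
    n_base_features: int = 20
    n_perfect_duplicate_groups: int = 3
    duplicate_group_size: int = 3
    n_ambiguous: int = 2
    n_joined_cds: int = 1
    n_name_synonym_groups: int = 2
    synonym_group_size: int = 3
    n_description_variant_groups: int = 2
    description_group_size: int = 2
    n_homonym_families: int = 2
    homonym_variants_per_family: int = 3
    coding_family: bool = True  # make the first family a CDS with codon-level plants
    n_nameless: int = 0
    hosts: tuple[str, ...] = ("Escherichia coli", "Saccharomyces cerevisiae")
    unspecified_fraction: float = 0.25
    circular_fraction: float = 0.5
    reverse_fraction: float = 0.3
    feature_length: tuple[int, int] = (90, 240)
    plasmid_max_length: int = 30000
    n_origin_spanning: int = 1
    plant_shared_upstream: bool = True  # identical 300 bp upstream of one duplicated CDS
    upstream_window: int = 300
    n_duplicate_plasmid_files: int = 0  # rotated/reverse-complement whole-file copies

    def validate(self) -> None:
        if self.n_plasmids < 1:
            raise InfeasibleSpecError("need at least one plasmid")
        if self.duplicate_group_size > self.n_plasmids:
            raise InfeasibleSpecError("duplicate group larger than plasmid count")
        if self.n_perfect_duplicate_groups > self.n_base_features:
            raise InfeasibleSpecError("more duplicate groups than base features")
        if min(self.feature_length) < 30:
            raise InfeasibleSpecError("feature length must be at least 30 bp")
        if self.homonym_variants_per_family < 1:
            raise InfeasibleSpecError("a homonym family needs at least one variant")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LibrarySpec":
        data = json.loads(text)
        for key in ("hosts", "feature_length"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class ExpectedVariant:
    sequence: str
    occurrences: int
    is_consensus: bool
    n_mismatches: int
    n_indel_columns: int
    border_only: bool
    n_synonymous: int = 0
    n_conservative: int = 0
    n_nonconservative: int = 0
    identical_protein: bool = True


@dataclass
class GroundTruth:
    """Exact expected outputs, derived from the plan before generation."""

    n_plasmids: int
    n_files: int
    n_duplicate_files: int
    report_counts: dict[str, int]
    usage_histogram: dict[int, int]
    host_cardinality: dict[str, int]
    families: dict[str, list[ExpectedVariant]]
    n_shared_upstream: int
    coding_family: str = ""

    def to_json(self) -> str:
        data = asdict(self)
        data["usage_histogram"] = {str(k): v for k, v in sorted(self.usage_histogram.items())}
        return json.dumps(data, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Plan construction
# ---------------------------------------------------------------------------

@dataclass
class _PlannedFeature:
    name: str
    description: str
    key: str
    sequence: str
    n_instances: int = 1
    inconsistent: bool = False
    joined: bool = False
    family: str | None = None
    plan: VariantEditPlan | None = None
    is_consensus: bool = False
    shared_upstream: bool = False
    origin_span: bool = False
    plasmids: list[int] = field(default_factory=list)
    forced_forward: bool = False


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _random_orf(rng: random.Random, length: int) -> str:
    """ATG + sense codons (no stops) + TAA, total ``length`` rounded to codons."""
    n_codons = max(length // 3, 4)
    body = []
    while len(body) < n_codons - 2:
        codon = _random_dna(rng, 3)
        if codon in ("TAA", "TAG", "TGA"):
            continue
        body.append(codon)
    return "ATG" + "".join(body) + "TAA"


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _plant_coding_substitution(
    consensus: str, codon_idx: int, intent: str
) -> tuple[int, str] | None:
    """Find a single-base change in the given codon matching the intent.

    Returns (absolute position, new base) or None if the codon offers no such
    change.  Verified against the codon table / BLOSUM62 here, so generation
    and analysis share one definition.
    """
    start = codon_idx * 3
    codon = consensus[start : start + 3]
    aa_old = _translate(codon)
    blosum = _blosum62()
    for offset in range(3):
        for base in _BASES:
            if base == codon[offset]:
                continue
            new_codon = codon[:offset] + base + codon[offset + 1 :]
            aa_new = _translate(new_codon)
            if aa_new == "*":
                continue  # never plant premature stops
            if intent == "synonymous" and aa_new == aa_old:
                return start + offset, base
            if intent == "conservative" and aa_new != aa_old and blosum[aa_old, aa_new] > 0:
                return start + offset, base
            if intent == "nonconservative" and aa_new != aa_old and blosum[aa_old, aa_new] <= 0:
                return start + offset, base
    return None


def _apply_noncoding_edits(
    rng: random.Random, consensus: str, plan: VariantEditPlan
) -> str:
    seq = consensus
    # substitutions: fixed interior positions, well separated from borders/indels
    pos = 15
    positions = []
    for _ in range(plan.n_substitutions):
        positions.append(pos)
        pos += 9
    edited = list(seq)
    for p in positions:
        old = edited[p]
        edited[p] = _BASES[(_BASES.index(old) + 1) % 4]
    seq = "".join(edited)
    # deletions at ~3/4 of the sequence, away from the substitutions
    cut = 3 * len(seq) // 4
    for length in plan.indel_lengths:
        seq = seq[:cut] + seq[cut + length :]
    return seq[plan.border5 : len(seq) - plan.border3 if plan.border3 else len(seq)]


def _apply_coding_edits(consensus: str, plan: VariantEditPlan) -> str:
    seq = consensus
    edited = list(seq)
    n_codons = len(seq) // 3
    codon_idx = 2
    intents = (
        ["synonymous"] * plan.n_synonymous
        + ["conservative"] * plan.n_conservative
        + ["nonconservative"] * plan.n_nonconservative
    )
    for intent in intents:
        found = None
        while codon_idx < n_codons - 2:
            found = _plant_coding_substitution(consensus, codon_idx, intent)
            codon_idx += 2  # skip a codon between edits
            if found is not None:
                break
        if found is None:
            raise InfeasibleSpecError(f"could not plant a {intent} change")
        p, base = found
        edited[p] = base
    seq = "".join(edited)
    cut = (2 * (len(seq) // 3) // 3) * 3  # codon boundary at ~2/3 of the ORF
    for length in plan.indel_lengths:
        seq = seq[:cut] + seq[cut + length :]
    return seq[plan.border5 : len(seq) - plan.border3 if plan.border3 else len(seq)]


@dataclass
class _Plan:
    spec: LibrarySpec
    features: list[_PlannedFeature]
    topologies: list[str]
    plasmid_hosts: list[str]
    plasmid_domains: list[str]
    shared_upstream_seq: str = ""


def build_plan(spec: LibrarySpec) -> _Plan:
    """Deterministically expand a spec into planted features and placements."""
    spec.validate()
    rng = random.Random(spec.seed)
    lo, hi = spec.feature_length
    seen_seqs: set[str] = set()

    def unique(seq_maker) -> str:
        while True:
            seq = seq_maker()
            if seq not in seen_seqs:
                seen_seqs.add(seq)
                return seq

    features: list[_PlannedFeature] = []

    # base features (first n_perfect_duplicate_groups are duplicated verbatim)
    for i in range(spec.n_base_features):
        key = _KEY_CYCLE[i % len(_KEY_CYCLE)]
        length = rng.randint(lo, hi)
        seq = unique(
            (lambda L=length: _random_orf(rng, L)) if key == "CDS" else (lambda L=length: _random_dna(rng, L))
        )
        duplicated = i < spec.n_perfect_duplicate_groups
        features.append(
            _PlannedFeature(
                name=f"feat-{i:04d}",
                description=f"synthetic feature {i}",
                key=key,
                sequence=seq,
                n_instances=spec.duplicate_group_size if duplicated else 1,
                shared_upstream=(
                    spec.plant_shared_upstream and i == 0 and duplicated and key == "CDS"
                ),
            )
        )

    # inconsistent features: ambiguous alphabet, and intron/exon-joined CDS
    for i in range(spec.n_ambiguous):
        raw = list(unique(lambda: _random_dna(rng, rng.randint(lo, hi))))
        raw[len(raw) // 2] = "N"
        features.append(
            _PlannedFeature(
                name=f"ambiguous-{i:02d}",
                description="feature with ambiguous bases",
                key="misc_feature",
                sequence="".join(raw),
                inconsistent=True,
            )
        )
    for i in range(spec.n_joined_cds):
        seq = unique(lambda: _random_orf(rng, rng.randint(lo, hi)))
        features.append(
            _PlannedFeature(
                name=f"joined-cds-{i:02d}",
                description="CDS with intron/exon join",
                key="CDS",
                sequence=seq,
                inconsistent=True,
                joined=True,
                forced_forward=True,
            )
        )

    # name-synonym groups: one (sequence, description), several names
    for g in range(spec.n_name_synonym_groups):
        seq = unique(lambda: _random_dna(rng, rng.randint(lo, hi)))
        desc = f"shared description {g}"
        for j in range(spec.synonym_group_size):
            features.append(
                _PlannedFeature(
                    name=f"synonym-{g:02d}-{chr(97 + j)}",
                    description=desc,
                    key="promoter",
                    sequence=seq,
                )
            )

    # description-variant groups: one (name, sequence), several descriptions
    for g in range(spec.n_description_variant_groups):
        seq = unique(lambda: _random_dna(rng, rng.randint(lo, hi)))
        for j in range(spec.description_group_size):
            features.append(
                _PlannedFeature(
                    name=f"desc-variant-{g:02d}",
                    description=f"description variant {j}",
                    key="terminator",
                    sequence=seq,
                )
            )

    # homonym families: one name, several sequences (planted edits)
    for f in range(spec.n_homonym_families):
        coding = spec.coding_family and f == 0
        name = f"family-{f:02d}"
        desc = f"family {f} description"
        if coding:
            consensus = unique(lambda: _random_orf(rng, max(150, lo)))
            plans = _default_coding_plans(spec.homonym_variants_per_family)
        else:
            consensus = unique(lambda: _random_dna(rng, max(200, lo)))
            plans = _default_noncoding_plans(spec.homonym_variants_per_family)
        features.append(
            _PlannedFeature(
                name=name,
                description=desc,
                key="CDS" if coding else "promoter",
                sequence=consensus,
                n_instances=4,
                family=name,
                is_consensus=True,
            )
        )
        for plan in plans:
            if coding:
                variant = _apply_coding_edits(consensus, plan)
            else:
                variant = _apply_noncoding_edits(rng, consensus, plan)
            if variant in seen_seqs:
                raise InfeasibleSpecError("planted variant collided with another sequence")
            seen_seqs.add(variant)
            features.append(
                _PlannedFeature(
                    name=name,
                    description=desc,
                    key="CDS" if coding else "promoter",
                    sequence=variant,
                    n_instances=plan.occurrences,
                    family=name,
                    plan=plan,
                )
            )

    for i in range(spec.n_nameless):
        seq = unique(lambda: _random_dna(rng, rng.randint(lo, hi)))
        features.append(
            _PlannedFeature(name="", description="", key="misc_feature", sequence=seq)
        )

    # origin-spanning feature (plasmid 0 is forced circular to host it)
    for i in range(spec.n_origin_spanning):
        seq = unique(lambda: _random_dna(rng, rng.randint(lo, hi)))
        features.append(
            _PlannedFeature(
                name=f"origin-span-{i:02d}",
                description="feature wrapping the origin",
                key="promoter",
                sequence=seq,
                origin_span=True,
                forced_forward=True,
            )
        )

    # plasmid topologies, hosts, domains
    topologies = [
        CIRCULAR if rng.random() < spec.circular_fraction else LINEAR
        for _ in range(spec.n_plasmids)
    ]
    if spec.n_origin_spanning:
        topologies[0] = CIRCULAR
    n_unspec = round(spec.unspecified_fraction * spec.n_plasmids)
    hosts = [UNSPECIFIED] * n_unspec + [
        spec.hosts[i % len(spec.hosts)] for i in range(spec.n_plasmids - n_unspec)
    ]
    rng.shuffle(hosts)
    domains = [_DOMAIN_CYCLE[i % len(_DOMAIN_CYCLE)] for i in range(spec.n_plasmids)]

    # round-robin placement; consecutive instances land on distinct plasmids
    counter = 0
    for feat in features:
        if feat.origin_span:
            feat.plasmids = [0]
            continue
        for _ in range(feat.n_instances):
            feat.plasmids.append(counter % spec.n_plasmids)
            counter += 1

    plan = _Plan(
        spec=spec,
        features=features,
        topologies=topologies,
        plasmid_hosts=hosts,
        plasmid_domains=domains,
        shared_upstream_seq=_random_dna(rng, spec.upstream_window),
    )
    return plan


# ---------------------------------------------------------------------------
# Ground truth (closed form over the plan)
# ---------------------------------------------------------------------------

def _ground_truth(plan: _Plan) -> GroundTruth:
    spec = plan.spec
    features = plan.features
    n_raw = sum(f.n_instances for f in features)
    n_distinct = len(features)  # every planted triple is distinct by construction
    n_inconsistent = sum(1 for f in features if f.inconsistent)
    after_step2 = n_distinct - n_inconsistent
    step3_reduction = spec.n_name_synonym_groups * (spec.synonym_group_size - 1)
    step4_reduction = spec.n_description_variant_groups * (spec.description_group_size - 1)
    after_step3 = after_step2 - step3_reduction
    after_step4 = after_step3 - step4_reduction
    n_renamed = sum(
        spec.homonym_variants_per_family for f in range(spec.n_homonym_families)
    )
    report_counts = {
        "n_raw": n_raw,
        "n_after_perfect_dedup": n_distinct,
        "n_after_inconsistent_removal": after_step2,
        "n_after_name_merge": after_step3,
        "n_after_description_merge": after_step4,
        "n_final": after_step4,
        "n_renamed": n_renamed,
    }

    # usage histogram and host cardinality over the *final* merged features
    final_counts: list[int] = []
    final_hosts: list[set[str]] = []
    consumed: set[int] = set()
    by_synonym_key: dict[tuple[str, str], list[_PlannedFeature]] = {}
    by_desc_key: dict[tuple[str, str], list[_PlannedFeature]] = {}
    for feat in features:
        if feat.inconsistent:
            continue
        if feat.name.startswith("synonym-"):
            by_synonym_key.setdefault((feat.sequence, feat.description), []).append(feat)
        elif feat.name.startswith("desc-variant-"):
            by_desc_key.setdefault((feat.name, feat.sequence), []).append(feat)
        else:
            final_counts.append(feat.n_instances)
            final_hosts.append({plan.plasmid_hosts[p] for p in feat.plasmids})
    for group in list(by_synonym_key.values()) + list(by_desc_key.values()):
        final_counts.append(sum(f.n_instances for f in group))
        final_hosts.append({plan.plasmid_hosts[p] for f in group for p in f.plasmids})

    usage_histogram: dict[int, int] = {}
    for count in final_counts:
        usage_histogram[count] = usage_histogram.get(count, 0) + 1
    n_single = sum(1 for h in final_hosts if len(h) == 1)
    host_cardinality = {
        "n_single_host": n_single,
        "n_multi_host": len(final_hosts) - n_single,
        "n_five_plus_hosts": sum(1 for h in final_hosts if len(h) >= 5),
        "n_unspecified_only": sum(1 for h in final_hosts if h == {UNSPECIFIED}),
    }

    families: dict[str, list[ExpectedVariant]] = {}
    coding_family_name = ""
    for feat in features:
        if feat.family is None:
            continue
        if feat.key == "CDS":
            coding_family_name = feat.family
        if feat.is_consensus:
            expected = ExpectedVariant(
                sequence=feat.sequence,
                occurrences=feat.n_instances,
                is_consensus=True,
                n_mismatches=0,
                n_indel_columns=0,
                border_only=False,
            )
        else:
            plan_ = feat.plan
            expected = ExpectedVariant(
                sequence=feat.sequence,
                occurrences=feat.n_instances,
                is_consensus=False,
                n_mismatches=plan_.n_mismatches,
                n_indel_columns=plan_.n_indel_columns,
                border_only=plan_.border_only,
                n_synonymous=plan_.n_synonymous,
                n_conservative=plan_.n_conservative,
                n_nonconservative=plan_.n_nonconservative
                + (plan_.n_indel_columns if feat.key == "CDS" else 0),
                identical_protein=plan_.identical_protein,
            )
        families.setdefault(feat.family, []).append(expected)

    shared = next((f for f in features if f.shared_upstream), None)
    return GroundTruth(
        n_plasmids=spec.n_plasmids,
        n_files=spec.n_plasmids + spec.n_duplicate_plasmid_files,
        n_duplicate_files=spec.n_duplicate_plasmid_files,
        report_counts=report_counts,
        usage_histogram=usage_histogram,
        host_cardinality=host_cardinality,
        families=families,
        n_shared_upstream=shared.n_instances if shared else 0,
        coding_family=coding_family_name,
    )


def expected_report(spec: LibrarySpec) -> GroundTruth:
    """Closed-form expectations, computed without generating any file."""
    return _ground_truth(build_plan(spec))


# ---------------------------------------------------------------------------
# Record assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLibrary:
    spec: LibrarySpec
    records: list[PlasmidRecord]
    metadata: dict[str, tuple[str, str]]  # record_id -> (host, domain)
    ground_truth: GroundTruth


def _rotate_record(record: PlasmidRecord, offset: int) -> None:
    """Rotate a circular record in place; features crossing the cut wrap."""
    L = record.length
    record.sequence = record.sequence[offset:] + record.sequence[:offset]
    for feat in record.features:
        new_parts = []
        for s, e in feat.parts:
            ns = (s - offset) % L
            ne = ns + (e - s)
            if ne <= L:
                new_parts.append((ns, ne))
            else:
                new_parts.append((ns, L))
                new_parts.append((0, ne - L))
        feat.parts = new_parts


def generate(spec: LibrarySpec, out_dir=None) -> SyntheticLibrary:
    """Generate the library (deterministic for a fixed seed).

    When ``out_dir`` is given, writes one GenBank file per record, a sidecar
    ``hosts.tsv`` and the ground truth as ``ground_truth.json``.
    """
    plan = build_plan(spec)
    truth = _ground_truth(plan)
    rng = random.Random(spec.seed + 1_000_003)  # placement noise, separate stream

    # collect (feature, instance_index) per plasmid, preserving plan order
    per_plasmid: list[list[tuple[_PlannedFeature, int]]] = [[] for _ in range(spec.n_plasmids)]
    for feat in plan.features:
        for k, plasmid_idx in enumerate(feat.plasmids):
            per_plasmid[plasmid_idx].append((feat, k))

    records: list[PlasmidRecord] = []
    metadata: dict[str, tuple[str, str]] = {}
    for idx in range(spec.n_plasmids):
        record_id = f"SYN{idx + 1:04d}"
        chunks: list[str] = []
        cursor = 0
        instances: list[FeatureInstance] = []
        origin_span_feature: FeatureInstance | None = None
        for feat, _k in per_plasmid[idx]:
            spacer = (
                plan.shared_upstream_seq
                if feat.shared_upstream
                else _random_dna(rng, rng.randint(40, 70))
            )
            chunks.append(spacer)
            cursor += len(spacer)
            reverse = (
                not feat.forced_forward
                and not feat.shared_upstream
                and rng.random() < spec.reverse_fraction
            )
            if feat.joined:
                # two exons with an unannotated intron between them
                split = len(feat.sequence) // 2
                exon1, exon2 = feat.sequence[:split], feat.sequence[split:]
                intron = _random_dna(rng, 30)
                chunks.append(exon1 + intron + exon2)
                parts = [
                    (cursor, cursor + len(exon1)),
                    (cursor + len(exon1) + len(intron), cursor + len(exon1) + len(intron) + len(exon2)),
                ]
                cursor += len(exon1) + len(intron) + len(exon2)
            else:
                block = reverse_complement(feat.sequence) if reverse else feat.sequence
                chunks.append(block)
                parts = [(cursor, cursor + len(block))]
                cursor += len(block)
            instance = FeatureInstance(
                feature_key=feat.key,
                parts=parts,
                strand=REVERSE if reverse else FORWARD,
                name=feat.name,
                description=feat.description,
                parent_id=record_id,
            )
            instances.append(instance)
            if feat.origin_span:
                origin_span_feature = instance
        chunks.append(_random_dna(rng, rng.randint(40, 70)))
        sequence = "".join(chunks)
        if len(sequence) > spec.plasmid_max_length:
            raise InfeasibleSpecError(
                f"plasmid {record_id} would be {len(sequence)} bp "
                f"(limit {spec.plasmid_max_length})"
            )
        record = PlasmidRecord(
            record_id=record_id,
            sequence=sequence,
            definition=f"synthetic plasmid {record_id}",
            topology=plan.topologies[idx],
            host=plan.plasmid_hosts[idx],
            application_domain=plan.plasmid_domains[idx],
            features=instances,
        )
        if origin_span_feature is not None and record.topology == CIRCULAR:
            s, e = origin_span_feature.parts[0]
            _rotate_record(record, s + (e - s) // 2)
        record.validate()
        records.append(record)
        metadata[record_id] = (record.host, record.application_domain)

    # whole-file duplicates: a rotation of the first circular record and a
    # reverse complement of the first linear one (sequence-level copies)
    dup_count = 0
    for i in range(spec.n_duplicate_plasmid_files):
        if i % 2 == 0:
            source = next((r for r in records if r.topology == CIRCULAR), records[0])
            seq = source.sequence[97:] + source.sequence[:97] if source.topology == CIRCULAR else source.sequence
        else:
            source = next((r for r in records if r.topology == LINEAR), records[0])
            seq = reverse_complement(source.sequence)
        dup_count += 1
        dup_id = f"ZDUP{dup_count:04d}"
        records.append(
            PlasmidRecord(
                record_id=dup_id,
                sequence=seq,
                definition=f"duplicate of {source.record_id}",
                topology=source.topology,
                host=source.host,
            )
        )
        metadata[dup_id] = (source.host, "")

    library = SyntheticLibrary(spec=spec, records=records, metadata=metadata, ground_truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for record in records:
            write_genbank([record], out_dir / f"{record.record_id}.gb")
        with open(out_dir / "hosts.tsv", "w") as handle:
            handle.write("# record_id\thost\tapplication_domain\n")
            for record_id, (host, domain) in sorted(metadata.items()):
                handle.write(f"{record_id}\t{host}\t{domain}\n")
        (out_dir / "ground_truth.json").write_text(truth.to_json())
        (out_dir / "spec.json").write_text(spec.to_json())
    return library
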