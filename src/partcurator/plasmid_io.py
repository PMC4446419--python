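"""GenBank plasmid input/output and the plasmid-level data model.

This module reads and writes GenBank flat files (multi-record, circular or
linear), normalizes expression-host names against a shipped synonym table,
and collapses file-level duplicates of whole plasmids (identical sequence up
to rotation of circular molecules and reverse complement).

Coordinates are stored 0-based half-open internally and converted to GenBank
1-based inclusive notation at the file boundary.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"
CIRCULAR = "circular"
LINEAR = "linear"
UNSPECIFIED = "Unspecified"

#: The canonical expression hosts recognized by :func:`normalize_host`
#: (plus ``Unspecified`` for records without host metadata).
CANONICAL_HOSTS = (
    "Escherichia coli",
    "Mammalian Cells",
    "Bacillus subtilis",
    "Gram-negative bacteria",
    "Drosophila melanogaster",
    "Saccharomyces cerevisiae",
    "Insect Cells",
    "Plant Cells",
    "Schizosaccharomyces pombe",
    "Pichia pastoris",
    "Aspergillus nidulans",
    "Kluyveromyces lactis",
)


class GenBankParseError(ValueError):
    """Raised when a GenBank record cannot be parsed."""


class InvalidRecordError(ValueError):
    """Raised when a record violates the plasmid data-model invariants."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class FeatureInstance:
    """One located feature on a plasmid.

    ``parts`` is a list of (start, end) pairs, 0-based half-open, in reading
    order.  An origin-spanning feature on a circular record is represented as
    an ordered two-part location ``[(a, L), (0, b)]``.
    """

    feature_key: str
    parts: list[tuple[int, int]]
    strand: str = FORWARD
    name: str = ""
    description: str = ""
    parent_id: str = ""

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def genbank_parts(self) -> list[tuple[int, int]]:
        """Location parts in GenBank 1-based inclusive coordinates."""
        return [(s + 1, e) for s, e in self.parts]

    def location_string(self) -> str:
        """GenBank-style location string (``complement``/``join`` syntax)."""
        inner = ",".join(f"{s}..{e}" for s, e in self.genbank_parts())
        if len(self.parts) > 1:
            inner = f"join({inner})"
        if self.strand == REVERSE:
            inner = f"complement({inner})"
        return inner


@dataclass
class PlasmidRecord:
    """One annotated sequence file (a plasmid or a single-feature record)."""

    record_id: str
    sequence: str
    definition: str = ""
    topology: str = LINEAR
    host: str = UNSPECIFIED
    application_domain: str = ""
    features: list[FeatureInstance] = field(default_factory=list)
    raw_text: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def spans_origin(self, feature: FeatureInstance) -> bool:
        return (
            self.topology == CIRCULAR
            and len(feature.parts) == 2
            and feature.parts[0][1] == self.length
            and feature.parts[1][0] == 0
        )

    def validate(self) -> None:
        if self.length == 0:
            raise InvalidRecordError(f"{self.record_id}: empty sequence")
        for feat in self.features:
            for s, e in feat.parts:
                if not (0 <= s < e <= self.length):
                    raise InvalidRecordError(
                        f"{self.record_id}: feature {feat.name!r} location "
                        f"({s + 1}..{e}) outside [1, {self.length}]"
                    )
            if len(feat.parts) > 1 and self.topology == LINEAR and _looks_origin_wrap(feat, self.length):
                raise InvalidRecordError(
                    f"{self.record_id}: origin-spanning feature {feat.name!r} on a linear record"
                )


def _looks_origin_wrap(feature: FeatureInstance, length: int) -> bool:
    return (
        len(feature.parts) == 2
        and feature.parts[0][1] == length
        and feature.parts[1][0] == 0
    )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_NAME_FALLBACK_QUALIFIERS = ("label", "gene", "product")


def _feature_name_description(qualifiers) -> tuple[str, str]:
    # First note qualifier is the name, the second (if present) the
    # description; /label, /gene, /product are fallbacks for the name.
    notes = [n.strip() for n in qualifiers.get("note", [])]
    name = notes[0] if notes else ""
    description = notes[1] if len(notes) > 1 else ""
    if not name:
        for key in _NAME_FALLBACK_QUALIFIERS:
            values = qualifiers.get(key, [])
            if values and values[0].strip():
                name = values[0].strip()
                break
    return name, description


def _convert_feature(bio_feature, parent_id: str) -> FeatureInstance:
    loc = bio_feature.location
    parts = [(int(p.start), int(p.end)) for p in loc.parts]
    strand = REVERSE if loc.strand == -1 else FORWARD
    name, description = _feature_name_description(bio_feature.qualifiers)
    return FeatureInstance(
        feature_key=bio_feature.type,
        parts=parts,
        strand=strand,
        name=name,
        description=description,
        parent_id=parent_id,
    )


def _split_raw_records(text: str) -> list[str]:
    """Split multi-record GenBank text into per-record chunks (verbatim)."""
    chunks, current = [], []
    for line in text.splitlines(keepends=True):
        current.append(line)
        if line.rstrip() == "//":
            chunks.append("".join(current))
            current = []
    if current and any(l.strip() for l in current):
        chunks.append("".join(current))
    return chunks


def read_genbank(path_or_stream, include_source: bool = False) -> list[PlasmidRecord]:
    """Read a GenBank flat file (possibly multi-record) into the data model.

    ``source`` features are skipped by default: they describe the whole
    record, not an annotated part.
    """
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
        origin = "<stream>"
    else:
        origin = str(path_or_stream)
        text = Path(path_or_stream).read_text()
    if not text.strip():
        return []
    raw_chunks = _split_raw_records(text)
    try:
        bio_records = list(SeqIO.parse(io.StringIO(text), "genbank"))
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise GenBankParseError(f"{origin}: malformed GenBank record: {exc}") from exc
    if not bio_records:
        raise GenBankParseError(f"{origin}: no LOCUS record found in non-empty input")

    records = []
    for i, rec in enumerate(bio_records):
        record_id = rec.name or rec.id
        sequence = str(rec.seq).upper()
        if not sequence:
            raise GenBankParseError(f"{origin}: record {record_id} has an empty ORIGIN")
        features = [
            _convert_feature(f, record_id)
            for f in rec.features
            if include_source or f.type != "source"
        ]
        plasmid = PlasmidRecord(
            record_id=record_id,
            sequence=sequence,
            definition=rec.description.rstrip(".") if rec.description != "<unknown description>" else "",
            topology=rec.annotations.get("topology", LINEAR),
            features=features,
            raw_text=raw_chunks[i] if i < len(raw_chunks) else "",
        )
        plasmid.validate()
        records.append(plasmid)
    return records


def read_genbank_dir(directory, pattern: str = "*.gb*", include_source: bool = False) -> list[PlasmidRecord]:
    """Read every GenBank file matching ``pattern`` under ``directory``."""
    records: list[PlasmidRecord] = []
    for path in sorted(Path(directory).glob(pattern)):
        records.extend(read_genbank(path, include_source=include_source))
    return records


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _to_bio_record(record: PlasmidRecord) -> SeqRecord:
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.record_id,
        name=record.record_id[:30],
        description=record.definition,
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    rec.annotations["data_file_division"] = "SYN"
    for feat in record.features:
        strand = -1 if feat.strand == REVERSE else 1
        simple = [SimpleLocation(s, e, strand=strand) for s, e in feat.parts]
        location = simple[0] if len(simple) == 1 else CompoundLocation(simple)
        qualifiers: dict[str, list[str]] = {}
        if feat.name:
            qualifiers["note"] = [feat.name]
            if feat.description:
                qualifiers["note"].append(feat.description)
        rec.features.append(SeqFeature(location, type=feat.feature_key, qualifiers=qualifiers))
    return rec


def write_genbank(records: Sequence[PlasmidRecord], path=None) -> str:
    """Serialize records to GenBank flat-file text; optionally write ``path``."""
    for record in records:
        record.validate()
    handle = io.StringIO()
    SeqIO.write([_to_bio_record(r) for r in records], handle, "genbank")
    text = handle.getvalue() if records else ""
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# File-level deduplication
# ---------------------------------------------------------------------------

def _least_rotation(s: str) -> str:
    """Lexicographically smallest rotation (Booth's algorithm)."""
    doubled = s + s
    n = len(doubled)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = doubled[j]
        i = f[j - k - 1]
        while i != -1 and sj != doubled[k + i + 1]:
            if sj < doubled[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != doubled[k + i + 1]:
            if sj < doubled[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return doubled[k : k + len(s)]


def _rotation_key(sequence: str) -> str:
    return min(_least_rotation(sequence), _least_rotation(reverse_complement(sequence)))


def _linear_key(sequence: str) -> str:
    return min(sequence, reverse_complement(sequence))


def dedup_files(records: Sequence[PlasmidRecord]) -> tuple[list[PlasmidRecord], list[dict]]:
    """Collapse duplicated whole-sequence files.

    Two records are duplicates when their sequences are identical after
    uppercasing, allowing reverse complement for all records and any rotation
    for circular records.  A linear record whose sequence matches a rotation
    of a circular record is a topological variant and collapses with it.
    The representative of each group is the lexicographically smallest
    record_id; the report lists every removed record and its retained twin.
    """
    groups: dict[str, list[PlasmidRecord]] = {}
    linear_only: dict[str, list[PlasmidRecord]] = {}
    for rec in records:
        if rec.topology == CIRCULAR:
            groups.setdefault(_rotation_key(rec.sequence), []).append(rec)
        else:
            linear_only.setdefault(_linear_key(rec.sequence), []).append(rec)
    for key, recs in linear_only.items():
        rot = _rotation_key(recs[0].sequence)
        if rot in groups:
            groups[rot].extend(recs)  # topological variant of a circular record
        else:
            groups.setdefault("L:" + key, []).extend(recs)

    kept: list[PlasmidRecord] = []
    report: list[dict] = []
    for recs in groups.values():
        recs = sorted(recs, key=lambda r: r.record_id)
        kept.append(recs[0])
        for twin in recs[1:]:
            report.append({"removed": twin.record_id, "kept": recs[0].record_id})
    kept.sort(key=lambda r: r.record_id)
    report.sort(key=lambda row: row["removed"])
    return kept, report


# ---------------------------------------------------------------------------
# Host normalization and sidecar metadata
# ---------------------------------------------------------------------------

def _read_tsv_pairs(handle) -> dict[str, str]:
    table = {}
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 2:
            table[fields[0].strip().lower()] = fields[1].strip()
    return table


def load_host_table(path=None) -> dict[str, str]:
    """Load a synonym→canonical host table (2-column TSV); default shipped."""
    if path is None:
        ref = resources.files("partcurator.data").joinpath("host_synonyms.tsv")
        with ref.open() as handle:
            return _read_tsv_pairs(handle)
    with open(path) as handle:
        return _read_tsv_pairs(handle)


_DEFAULT_HOST_TABLE: dict[str, str] | None = None


def normalize_host(raw_host: str | None, table: dict[str, str] | None = None) -> str:
    """Map a raw host string onto the canonical host list.

    Empty input maps to ``Unspecified``; unknown strings pass through
    unchanged with a logged warning.  Idempotent.
    """
    global _DEFAULT_HOST_TABLE
    if table is None:
        if _DEFAULT_HOST_TABLE is None:
            _DEFAULT_HOST_TABLE = load_host_table()
        table = _DEFAULT_HOST_TABLE
    if raw_host is None or not raw_host.strip():
        return UNSPECIFIED
    raw = " ".join(raw_host.split())
    if raw == UNSPECIFIED or raw in CANONICAL_HOSTS:
        return raw
    canonical = table.get(raw.lower())
    if canonical is not None:
        return canonical
    logger.warning("unknown expression host %r left unchanged", raw)
    return raw


def load_metadata_tsv(path) -> dict[str, tuple[str, str]]:
    """Sidecar metadata: record_id → (host, application_domain)."""
    table: dict[str, tuple[str, str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            record_id = fields[0].strip()
            host = fields[1].strip() if len(fields) > 1 else ""
            domain = fields[2].strip() if len(fields) > 2 else ""
            table[record_id] = (host, domain)
    return table


def apply_metadata(
    records: Iterable[PlasmidRecord],
    metadata: dict[str, tuple[str, str]],
    host_table: dict[str, str] | None = None,
) -> None:
    """Apply sidecar host/domain metadata in place, normalizing hosts."""
    for rec in records:
        if rec.record_id in metadata:
            host, domain = metadata[rec.record_id]
            rec.host = normalize_host(host, table=host_table)
            if domain:
                rec.application_domain = domain
        else:
            rec.host = normalize_host(rec.host, table=host_table)
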