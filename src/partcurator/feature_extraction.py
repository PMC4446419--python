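"""Materialize feature sequences from plasmid records.

Every annotated feature is turned into a :class:`MaterializedFeature` whose
``sequence`` is in reading orientation (reverse-complemented for
reverse-strand features, concatenated across the origin for circular
records).  The flat list over all records is the raw feature library that the
curation step reduces.  The module also extracts fixed-width 5' upstream
regions of coding sequences, used to hunt for un-annotated promoters, and
groups identical upstream regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .plasmid_io import (
    CIRCULAR,
    FORWARD,
    LINEAR,
    REVERSE,
    FeatureInstance,
    PlasmidRecord,
    reverse_complement,
)


class FeatureLocationError(ValueError):
    """A feature location falls outside its (linear) parent sequence."""


@dataclass
class MaterializedFeature:
    """A feature instance together with its extracted sequence."""

    feature_key: str
    name: str
    description: str
    parent_id: str
    strand: str
    location: str  # GenBank-style location string, for provenance
    sequence: str
    spans_origin: bool = False
    is_joined: bool = False
    parent_host: str = "Unspecified"

    @property
    def length(self) -> int:
        return len(self.sequence)


def materialize(plasmid: PlasmidRecord, feature: FeatureInstance) -> MaterializedFeature:
    """Extract the located subsequence of ``feature`` in reading orientation.

    A two-part location of the form ``(a..L, 1..b)`` on a circular record is
    an origin wrap and concatenates across the origin; any other multi-part
    location is flagged ``is_joined`` (an intron/exon join).
    """
    length = plasmid.length
    for s, e in feature.parts:
        if not (0 <= s < e <= length):
            raise FeatureLocationError(
                f"{plasmid.record_id}: location {s + 1}..{e} outside sequence "
                f"of length {length}"
            )
    spans_origin = plasmid.spans_origin(feature)
    is_joined = len(feature.parts) > 1 and not spans_origin
    seq = "".join(plasmid.sequence[s:e] for s, e in feature.parts)
    if feature.strand == REVERSE:
        seq = reverse_complement(seq)
    return MaterializedFeature(
        feature_key=feature.feature_key,
        name=feature.name,
        description=feature.description,
        parent_id=feature.parent_id or plasmid.record_id,
        strand=feature.strand,
        location=feature.location_string(),
        sequence=seq.upper(),
        spans_origin=spans_origin,
        is_joined=is_joined,
        parent_host=plasmid.host,
    )


def extract_all(records: Sequence[PlasmidRecord]) -> tuple[list[MaterializedFeature], list[str]]:
    """Materialize every feature of every record.

    Per-feature errors are collected (as messages), not fatal; the feature
    count of error-free input equals the sum of per-record feature counts.
    """
    features: list[MaterializedFeature] = []
    errors: list[str] = []
    for record in records:
        for feature in record.features:
            try:
                features.append(materialize(record, feature))
            except FeatureLocationError as exc:
                errors.append(str(exc))
    return features, errors


class UpstreamRegion(NamedTuple):
    sequence: str
    truncated: bool


def extract_upstream(
    plasmid: PlasmidRecord, cds_feature: FeatureInstance, window: int = 300
) -> UpstreamRegion:
    """The ``window`` bases immediately 5' of a feature, in reading orientation.

    Wraps the origin on circular records; on linear records the window is
    truncated at the sequence boundary and flagged.  Overlapping annotations
    are ignored: the raw plasmid sequence is returned regardless.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    seq = plasmid.sequence
    length = plasmid.length
    if cds_feature.strand == REVERSE:
        # Reading 5' upstream of a reverse feature lies after its top-strand end.
        anchor = max(e for _, e in cds_feature.parts)
        if plasmid.topology == CIRCULAR:
            take = min(window, length)
            doubled = seq + seq
            region = doubled[anchor : anchor + take]
            return UpstreamRegion(reverse_complement(region), take < window)
        end = min(anchor + window, length)
        region = seq[anchor:end]
        return UpstreamRegion(reverse_complement(region), len(region) < window)
    anchor = min(s for s, _ in cds_feature.parts)
    if plasmid.topology == CIRCULAR:
        take = min(window, length)
        doubled = seq + seq
        start = anchor - take
        region = doubled[start + length : anchor + length] if start < 0 else seq[start:anchor]
        return UpstreamRegion(region, take < window)
    start = max(anchor - window, 0)
    region = seq[start:anchor]
    return UpstreamRegion(region, len(region) < window)


def group_identical_upstream(
    regions: Iterable[tuple[str, str]] | Iterable[str],
) -> list[list[str]]:
    """Group identical upstream sequences; one representative group per string.

    Accepts either bare sequences or (identifier, sequence) pairs; returns a
    list of groups, each a list of identifiers (the sequence itself when bare
    strings were supplied), in first-seen order.
    """
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for item in regions:
        if isinstance(item, str):
            ident, seq = item, item
        else:
            ident, seq = item
        if seq not in groups:
            groups[seq] = []
            order.append(seq)
        groups[seq].append(ident)
    return [groups[seq] for seq in order]
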