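"""Descriptive statistics of the Standard Features Library.

Usage distribution, sequence-length distribution, feature-key distribution
(validated against the INSDC feature-key vocabulary), segmentation of
features by expression host, per-plasmid summaries and plasmid-usage
percentages.  "Occurs in N plasmids" always counts distinct plasmids, not
instances; the same plasmid may carry a feature more than once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curation import FeatureLibrary, StandardFeature
from .plasmid_io import UNSPECIFIED, PlasmidRecord
from .variant_analysis import round_half_up

#: INSDC feature-table keys (www.insdc.org/documents/feature-table).
INSDC_FEATURE_KEYS = frozenset(
    """assembly_gap C_region CDS centromere D-loop D_segment exon gap gene iDNA
    intron J_segment mat_peptide misc_binding misc_difference misc_feature
    misc_recomb misc_RNA misc_structure mobile_element modified_base mRNA
    ncRNA N_region old_sequence operon oriT polyA_site precursor_RNA
    prim_transcript primer_bind propeptide protein_bind regulatory
    repeat_region rep_origin rRNA S_region sig_peptide source stem_loop STS
    telomere tmRNA transit_peptide tRNA unsure V_region V_segment variation
    3'UTR 5'UTR""".split()
) | frozenset(
    # Widely used legacy keys still common in plasmid annotation files.
    {"promoter", "terminator", "enhancer", "RBS", "polyA_signal", "LTR",
     "misc_signal", "attenuator", "CAAT_signal", "TATA_signal", "-35_signal",
     "-10_signal"}
)


def usage_distribution(library: FeatureLibrary | Iterable[StandardFeature]) -> tuple[Counter, int]:
    """Histogram of occurrence counts, plus the number of singleton features."""
    histogram: Counter = Counter(f.occurrence_count for f in library)
    return histogram, histogram.get(1, 0)


def lower_median(values: Sequence[int]) -> int:
    """Lower median (the (n-1)//2-th order statistic); deterministic on even n."""
    ordered = sorted(values)
    if not ordered:
        raise ValueError("median of empty sequence")
    return ordered[(len(ordered) - 1) // 2]


@dataclass
class LengthSummary:
    min: int
    median: int
    max: int
    bin_edges: list[float]
    bin_counts: list[int]


def length_summary(
    library: FeatureLibrary | Iterable[StandardFeature], bins: int = 20
) -> LengthSummary:
    lengths = [f.length for f in library]
    if not lengths:
        return LengthSummary(0, 0, 0, [], [])
    counts, edges = np.histogram(lengths, bins=bins)
    return LengthSummary(
        min=min(lengths),
        median=lower_median(lengths),
        max=max(lengths),
        bin_edges=[float(e) for e in edges],
        bin_counts=[int(c) for c in counts],
    )


def feature_key_distribution(
    library: FeatureLibrary | Iterable[StandardFeature],
) -> tuple[Counter, set[str]]:
    """Count distinct standard features per GenBank key; flag unknown keys."""
    counts: Counter = Counter(f.feature_key for f in library)
    unknown = {key for key in counts if key not in INSDC_FEATURE_KEYS}
    return counts, unknown


@dataclass
class HostSegmentation:
    feature_hosts: dict[str, set[str]]
    n_single_host: int
    n_multi_host: int
    n_five_plus_hosts: int
    n_unspecified_only: int
    host_feature_counts: Counter = field(default_factory=Counter)


def host_segmentation(library: FeatureLibrary | Iterable[StandardFeature]) -> HostSegmentation:
    """Associate each feature with the hosts of the plasmids carrying it.

    ``Unspecified`` counts as a host value: a feature seen only on host-free
    plasmids is a single-host, unspecified-only feature.
    """
    feature_hosts: dict[str, set[str]] = {}
    host_counts: Counter = Counter()
    n_single = n_multi = n_five = n_unspec = 0
    for feat in library:
        hosts = set(feat.hosts) or {UNSPECIFIED}
        feature_hosts[feat.display_name] = hosts
        for host in hosts:
            host_counts[host] += 1
        if len(hosts) == 1:
            n_single += 1
            if hosts == {UNSPECIFIED}:
                n_unspec += 1
        else:
            n_multi += 1
        if len(hosts) >= 5:
            n_five += 1
    return HostSegmentation(
        feature_hosts=feature_hosts,
        n_single_host=n_single,
        n_multi_host=n_multi,
        n_five_plus_hosts=n_five,
        n_unspecified_only=n_unspec,
        host_feature_counts=host_counts,
    )


def plasmid_summary(records: Sequence[PlasmidRecord]) -> pd.DataFrame:
    """Per-plasmid length, feature count, host and application domain."""
    rows = [
        {
            "record_id": r.record_id,
            "length_bp": r.length,
            "n_features": len(r.features),
            "host": r.host,
            "application_domain": r.application_domain,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["record_id", "length_bp", "n_features", "host", "application_domain"]
    )


def plasmid_usage_percent(n_plasmids_with_feature: int, n_plasmids: int) -> int:
    """Percent of plasmids carrying a feature, rounded half-up to an integer."""
    if n_plasmids <= 0:
        raise ValueError("n_plasmids must be positive")
    return round_half_up(100 * n_plasmids_with_feature / n_plasmids)


def usage_percentages(
    library: FeatureLibrary | Iterable[StandardFeature], n_plasmids: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distinct-plasmid usage per feature and per variant family (base name)."""
    if n_plasmids <= 0:
        raise ValueError("n_plasmids must be positive")
    features = list(library)
    feat_rows = []
    family_plasmids: dict[str, set[str]] = {}
    for feat in features:
        plasmids = {rid for rid, _, _ in feat.instances}
        feat_rows.append(
            {
                "display_name": feat.display_name,
                "base_name": feat.base_name,
                "n_plasmids": len(plasmids),
                "pct_plasmids": plasmid_usage_percent(len(plasmids), n_plasmids),
            }
        )
        family_plasmids.setdefault(feat.base_name, set()).update(plasmids)
    family_rows = [
        {
            "base_name": name,
            "n_plasmids": len(plasmids),
            "pct_plasmids": plasmid_usage_percent(len(plasmids), n_plasmids),
        }
        for name, plasmids in sorted(family_plasmids.items())
    ]
    return pd.DataFrame(feat_rows), pd.DataFrame(family_rows)


def top_used_features(
    library: FeatureLibrary | Iterable[StandardFeature], threshold: int = 200
) -> pd.DataFrame:
    """Features used at least ``threshold`` times (most-used first)."""
    rows = [
        {"display_name": f.display_name, "occurrence_count": f.occurrence_count}
        for f in library
        if f.occurrence_count >= threshold
    ]
    rows.sort(key=lambda r: (-r["occurrence_count"], r["display_name"]))
    return pd.DataFrame(rows, columns=["display_name", "occurrence_count"])


def summarize(library: FeatureLibrary, records: Sequence[PlasmidRecord] | None = None) -> dict:
    """JSON-serializable summary of the library (and optionally its plasmids)."""
    histogram, n_singletons = usage_distribution(library)
    lengths = length_summary(library)
    keys, unknown = feature_key_distribution(library)
    hosts = host_segmentation(library)
    summary = {
        "n_features": len(library.features),
        "n_singletons": n_singletons,
        "usage_histogram": {str(k): v for k, v in sorted(histogram.items())},
        "length": {"min": lengths.min, "median": lengths.median, "max": lengths.max},
        "feature_keys": dict(sorted(keys.items())),
        "unknown_feature_keys": sorted(unknown),
        "host_segmentation": {
            "n_single_host": hosts.n_single_host,
            "n_multi_host": hosts.n_multi_host,
            "n_five_plus_hosts": hosts.n_five_plus_hosts,
            "n_unspecified_only": hosts.n_unspecified_only,
            "features_per_host": dict(sorted(hosts.host_feature_counts.items())),
        },
    }
    if records is not None:
        summary["n_plasmids"] = len(records)
    return summary
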