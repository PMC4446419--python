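import io

import pytest

from partcurator.curation import curate
from partcurator.feature_extraction import MaterializedFeature, extract_all
from partcurator.plasmid_io import dedup_files, read_genbank, write_genbank
from partcurator.synthetic_library import LibrarySpec, generate


def make_feature(
    name="f",
    sequence="ACGTACGTACGT",
    description="",
    key="misc_feature",
    parent="P1",
    location="1..12",
    strand="forward",
    host="Unspecified",
    is_joined=False,
):
    return MaterializedFeature(
        feature_key=key,
        name=name,
        description=description,
        parent_id=parent,
        strand=strand,
        location=location,
        sequence=sequence,
        is_joined=is_joined,
        parent_host=host,
    )


def curated_synthetic(seed=0, **spec_kwargs):
    """Generate a synthetic library, round-trip it through GenBank text and
    curate it; returns (SyntheticLibrary, FeatureLibrary, CurationReport)."""
    spec = LibrarySpec(seed=seed, **spec_kwargs)
    synthetic = generate(spec)
    text = write_genbank(synthetic.records)
    records = read_genbank(io.StringIO(text))
    records, _ = dedup_files(records)
    host_by_id = {r: h for r, (h, _) in synthetic.metadata.items()}
    for record in records:
        record.host = host_by_id.get(record.record_id, record.host)
    features, errors = extract_all(records)
    assert not errors
    library, report = curate(features)
    return synthetic, library, report


@pytest.fixture
def synthetic_curated():
    return curated_synthetic(seed=42)
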