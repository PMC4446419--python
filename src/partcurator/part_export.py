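"""Export curated features as SO-typed part libraries and a design grammar.

Features are mapped from GenBank feature keys to Sequence Ontology terms via
an editable TSV table, CDS parts have terminal START/STOP codons stripped
(introducing START and STOP as standalone parts), and per-host part
collections are written as versioned JSON documents (one per host, one for
unspecified-host parts, one combined).  A small rewrite grammar — part
categories plus composition and subset rules — supports validation of
construct designs (e.g. a CDS is composed of a START codon, an ORF and a
STOP codon; a bacterial terminator *is a* terminator).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .curation import FeatureLibrary, StandardFeature
from .plasmid_io import UNSPECIFIED

logger = logging.getLogger(__name__)

SO_GENERIC_FEATURE = "SO:0000110"  # sequence_feature, the fallback term
SO_ACCESSION_RE = re.compile(r"^SO:\d{7}$")
DEFAULT_STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"
SO_START_CODON = "SO:0000318"
SO_STOP_CODON = "SO:0000319"
FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# GenBank key -> SO term mapping
# ---------------------------------------------------------------------------

def load_so_table(path=None) -> dict[str, str]:
    """Load the GenBank-key→SO-accession table (TSV); default shipped."""
    if path is None:
        ref = resources.files("partcurator.data").joinpath("genbank_so.tsv")
        handle = ref.open()
    else:
        handle = open(path)
    table: dict[str, str] = {}
    with handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 2 and SO_ACCESSION_RE.match(fields[1].strip()):
                table[fields[0].strip().lower()] = fields[1].strip()
    return table


_DEFAULT_SO_TABLE: dict[str, str] | None = None


def map_key_to_so(genbank_key: str, table: dict[str, str] | None = None) -> str:
    """SO accession for a GenBank feature key; unmapped keys fall back to the
    generic sequence-feature term with a warning."""
    global _DEFAULT_SO_TABLE
    if table is None:
        if _DEFAULT_SO_TABLE is None:
            _DEFAULT_SO_TABLE = load_so_table()
        table = _DEFAULT_SO_TABLE
    term = table.get(genbank_key.lower())
    if term is None:
        logger.warning("no SO mapping for feature key %r; using %s", genbank_key, SO_GENERIC_FEATURE)
        return SO_GENERIC_FEATURE
    return term


# ---------------------------------------------------------------------------
# Parts
# ---------------------------------------------------------------------------

@dataclass
class Part:
    display_id: str
    name: str
    sequence: str
    so_term: str
    description: str = ""
    hosts: set[str] = field(default_factory=set)
    category_code: str = ""
    base_name: str = ""
    occurrence_count: int = 1
    stripped_start: bool = False
    stripped_stop: bool = False

    def to_dict(self) -> dict:
        return {
            "display_id": self.display_id,
            "name": self.name,
            "description": self.description,
            "sequence": self.sequence,
            "so_term": self.so_term,
            "hosts": sorted(self.hosts),
            "category_code": self.category_code,
        }


def make_display_id(name: str, taken: set[str] | None = None) -> str:
    """URL-safe identifier from a display name, with collision suffixes."""
    base = re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_").lower() or "part"
    if base[0].isdigit():
        base = "p_" + base
    if taken is None:
        return base
    candidate, n = base, 1
    while candidate in taken:
        n += 1
        candidate = f"{base}_{n}"
    taken.add(candidate)
    return candidate


def library_to_parts(
    library: FeatureLibrary | Iterable[StandardFeature],
    so_table: dict[str, str] | None = None,
) -> list[Part]:
    """Convert standard features to parts with SO terms and unique ids."""
    taken: set[str] = set()
    parts = []
    for feat in library:
        parts.append(
            Part(
                display_id=make_display_id(feat.display_name, taken),
                name=feat.display_name,
                sequence=feat.sequence,
                so_term=map_key_to_so(feat.feature_key, so_table),
                description=feat.description,
                hosts=set(feat.hosts),
                base_name=feat.base_name,
                occurrence_count=feat.occurrence_count,
            )
        )
    return parts


# ---------------------------------------------------------------------------
# START/STOP codon handling
# ---------------------------------------------------------------------------

def strip_terminal_codons(
    cds_part: Part,
    stop_codons: Sequence[str] = DEFAULT_STOP_CODONS,
) -> tuple[Part, bool, bool]:
    """Remove a leading ATG and a trailing stop codon from a CDS part.

    Returns (part, stripped_start, stripped_stop).  If stripping would leave
    less than one codon of ORF body the part is kept unstripped with a warning.
    Idempotent: a part that already had codons stripped (``stripped_start`` /
    ``stripped_stop`` set) is returned unchanged, so the ORF body is never
    eroded by repeated application.
    """
    if cds_part.stripped_start or cds_part.stripped_stop:
        return cds_part, cds_part.stripped_start, cds_part.stripped_stop
    seq = cds_part.sequence.upper()
    stripped_start = seq.startswith(START_CODON)
    stripped_stop = any(seq.endswith(c) for c in stop_codons)
    new_seq = seq
    if stripped_start:
        new_seq = new_seq[3:]
    if stripped_stop:
        new_seq = new_seq[:-3]
    if (stripped_start or stripped_stop) and len(new_seq) < 3:
        # nothing but terminal codons: stripping would leave no ORF body
        logger.warning("part %s too short after codon stripping; kept unstripped", cds_part.display_id)
        return cds_part, False, False
    if not (stripped_start or stripped_stop):
        return cds_part, False, False
    orf = Part(
        display_id=cds_part.display_id,
        name=cds_part.name,
        sequence=new_seq,
        so_term=cds_part.so_term,
        description=cds_part.description,
        hosts=set(cds_part.hosts),
        category_code=cds_part.category_code,
        base_name=cds_part.base_name,
        occurrence_count=cds_part.occurrence_count,
        stripped_start=stripped_start,
        stripped_stop=stripped_stop,
    )
    return orf, stripped_start, stripped_stop


def merge_after_strip(
    parts: Sequence[Part],
    stop_codons: Sequence[str] = DEFAULT_STOP_CODONS,
) -> tuple[list[Part], list[dict]]:
    """Merge parts left identical (same base name and sequence) by codon
    stripping, and introduce START and STOP as standalone parts."""
    merged: dict[tuple[str, str], Part] = {}
    report: list[dict] = []
    for part in parts:
        key = (part.base_name, part.sequence.upper())
        if key in merged:
            keeper = merged[key]
            keeper.hosts |= part.hosts
            keeper.occurrence_count += part.occurrence_count
            report.append({"merged": part.name, "into": keeper.name})
        else:
            merged[key] = part
    result = list(merged.values())
    taken = {p.display_id for p in result}
    all_hosts = set().union(*(p.hosts for p in result)) if result else set()
    result.append(
        Part(
            display_id=make_display_id("START", taken),
            name="START",
            sequence=START_CODON,
            so_term=SO_START_CODON,
            hosts=set(all_hosts),
            category_code="START",
        )
    )
    result.append(
        Part(
            display_id=make_display_id("STOP", taken),
            name="STOP",
            sequence=stop_codons[0],
            so_term=SO_STOP_CODON,
            hosts=set(all_hosts),
            category_code="STOP",
        )
    )
    return result, report


# ---------------------------------------------------------------------------
# Part-collection documents
# ---------------------------------------------------------------------------

def _collection_document(name: str, host: str, parts: Sequence[Part]) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "collection": {"name": name, "host": host, "description": ""},
        "parts": [p.to_dict() for p in sorted(parts, key=lambda p: p.display_id)],
    }


def export_collections(parts: Sequence[Part], out_dir) -> list[Path]:
    """Write one JSON part-collection per host present, plus a combined file.

    ``Unspecified`` counts as a host value, so a library with hosts {A, B}
    plus unspecified parts yields 4 files; an empty library yields only the
    combined file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hosts = sorted({h for p in parts for h in (p.hosts or {UNSPECIFIED})})
    written = []
    for host in hosts:
        members = [p for p in parts if host in (p.hosts or {UNSPECIFIED})]
        slug = re.sub(r"[^A-Za-z0-9]+", "_", host).strip("_").lower()
        path = out_dir / f"parts_{slug}.json"
        path.write_text(json.dumps(_collection_document(host, host, members), indent=1, sort_keys=True))
        written.append(path)
    path = out_dir / "parts_all.json"
    path.write_text(json.dumps(_collection_document("all", "all", parts), indent=1, sort_keys=True))
    written.append(path)
    return written


def import_collection(path) -> list[Part]:
    """Read a part-collection JSON document back into Part objects."""
    data = json.loads(Path(path).read_text())
    if data.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported part-collection format")
    parts = []
    for entry in data["parts"]:
        parts.append(
            Part(
                display_id=entry["display_id"],
                name=entry["name"],
                sequence=entry["sequence"],
                so_term=entry["so_term"],
                description=entry.get("description", ""),
                hosts=set(entry.get("hosts", [])),
                category_code=entry.get("category_code", ""),
            )
        )
    return parts


# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartCategory:
    long_name: str
    code: str
    so_term: str = ""  # empty for categories without a corresponding SO term
    genbank_key: str = ""
    icon_id: str = ""

    @property
    def is_custom(self) -> bool:
        # Convention: names of categories without an SO term start with "+";
        # user-defined (project) categories start with "c-".
        return self.long_name.startswith("+") or self.long_name.startswith("c-")


@dataclass(frozen=True)
class GrammarRule:
    kind: str  # "composition" (left -> sequence) or "subset" (left -> one code)
    left: str
    right: tuple[str, ...]

    def __post_init__(self):
        if self.kind not in ("composition", "subset"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "subset" and len(self.right) != 1:
            raise ValueError("subset rule must have exactly one right-hand code")
        if self.right == (self.left,):
            raise ValueError("a category may not derive itself directly")


@dataclass
class Grammar:
    categories: dict[str, PartCategory]
    rules: list[GrammarRule]
    start: str
    libraries: dict[str, list[str]] = field(default_factory=dict)  # name -> display_ids
    parts: list[Part] = field(default_factory=list)

    def validate(self) -> None:
        if self.start not in self.categories:
            raise ValueError(f"start category {self.start!r} undefined")
        for rule in self.rules:
            for code in (rule.left, *rule.right):
                if code not in self.categories:
                    raise ValueError(f"rule references unknown category {code!r}")
        for part in self.parts:
            if part.category_code and part.category_code not in self.categories:
                raise ValueError(
                    f"part {part.display_id} has unknown category {part.category_code!r}"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "start": self.start,
                "categories": [c.__dict__ for c in self.categories.values()],
                "rules": [
                    {"kind": r.kind, "left": r.left, "right": list(r.right)} for r in self.rules
                ],
                "libraries": self.libraries,
                "parts": [p.to_dict() for p in self.parts],
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Grammar":
        data = json.loads(text)
        categories = {c["code"]: PartCategory(**c) for c in data["categories"]}
        rules = [
            GrammarRule(kind=r["kind"], left=r["left"], right=tuple(r["right"]))
            for r in data["rules"]
        ]
        grammar = cls(
            categories=categories,
            rules=rules,
            start=data["start"],
            libraries={k: list(v) for k, v in data.get("libraries", {}).items()},
            parts=[
                Part(
                    display_id=p["display_id"],
                    name=p["name"],
                    sequence=p["sequence"],
                    so_term=p["so_term"],
                    description=p.get("description", ""),
                    hosts=set(p.get("hosts", [])),
                    category_code=p.get("category_code", ""),
                )
                for p in data.get("parts", [])
            ],
        )
        grammar.validate()
        return grammar


_DEFAULT_CATEGORIES = [
    PartCategory("Expression cassette", "CAS", "", "", "cassette"),
    PartCategory("Promoter", "PROM", "SO:0000167", "promoter", "promoter"),
    PartCategory("CDS", "CDS", "SO:0000316", "CDS", "cds"),
    PartCategory("START codon", "START", SO_START_CODON, "", "start"),
    PartCategory("ORF", "ORF", "SO:0000236", "", "orf"),
    PartCategory("STOP codon", "STOP", SO_STOP_CODON, "", "stop"),
    PartCategory("Terminator", "TERM", "SO:0000141", "terminator", "terminator"),
    PartCategory("Bacterial terminator", "BTERM", "SO:0000614", "terminator", "terminator"),
    PartCategory("Origin of replication", "ORI", "SO:0000296", "rep_origin", "origin"),
    PartCategory("Primer binding site", "PRIMER", "SO:0005850", "primer_bind", "primer"),
    PartCategory("+Multiple cloning site", "MCS", "", "misc_feature", "mcs"),
    PartCategory("Sequence feature", "FEAT", "SO:0000110", "misc_feature", "feature"),
]

_DEFAULT_RULES = [
    GrammarRule("composition", "CAS", ("PROM", "CDS", "TERM")),
    GrammarRule("composition", "CDS", ("START", "ORF", "STOP")),
    GrammarRule("subset", "TERM", ("BTERM",)),
]

def build_grammar(
    parts: Sequence[Part],
    hosts: Iterable[str] = (),
    popular_threshold: int = 17,
) -> Grammar:
    """Assemble the default grammar over a part set.

    Parts are binned into categories from their source feature keys (via
    their SO terms); libraries are built per host, for all parts, and for the
    popular parts (used in at least ``popular_threshold`` plasmids).
    """
    so_to_category = {
        "SO:0000167": "PROM",
        "SO:0000316": "ORF",
        "SO:0000141": "TERM",
        "SO:0000614": "BTERM",
        "SO:0000296": "ORI",
        "SO:0005850": "PRIMER",
        SO_START_CODON: "START",
        SO_STOP_CODON: "STOP",
    }
    for part in parts:
        if not part.category_code:
            part.category_code = so_to_category.get(part.so_term, "FEAT")
    libraries: dict[str, list[str]] = {"all": [p.display_id for p in parts]}
    for host in sorted(set(hosts) | {h for p in parts for h in p.hosts}):
        members = [p.display_id for p in parts if host in p.hosts]
        if members:
            libraries[f"host:{host}"] = members
    popular = [p.display_id for p in parts if p.occurrence_count >= popular_threshold]
    if popular:
        libraries["popular"] = popular
    grammar = Grammar(
        categories={c.code: c for c in _DEFAULT_CATEGORIES},
        rules=list(_DEFAULT_RULES),
        start="CAS",
        libraries=libraries,
        parts=list(parts),
    )
    grammar.validate()
    return grammar


def validate_construct(
    grammar: Grammar, category_sequence: Sequence[str]
) -> tuple[bool, list[str]]:
    """Decide whether a sequence of category codes is derivable from the
    grammar's start category; return (valid, derivation trace).

    Composition rules expand one category into a sequence; subset rules
    substitute a category by a more specific one.  Derivation is checked by
    memoized recursive descent with split-point enumeration.
    """
    for code in category_sequence:
        if code not in grammar.categories:
            raise ValueError(f"unknown category {code!r} in construct")
    target = tuple(category_sequence)
    comp_rules = [r for r in grammar.rules if r.kind == "composition"]
    subset_rules = [r for r in grammar.rules if r.kind == "subset"]

    def derive(symbol: str, span: tuple[str, ...], seen: frozenset) -> list[str] | None:
        if span == (symbol,):
            return []
        if (symbol, span) in seen:
            return None  # cycle guard over unit derivations
        seen = seen | {(symbol, span)}
        for rule in subset_rules:
            if rule.left != symbol:
                continue
            sub = derive(rule.right[0], span, seen)
            if sub is not None:
                return [f"{symbol} => {rule.right[0]}"] + sub
        for rule in comp_rules:
            if rule.left != symbol:
                continue
            split = _split_derivation(rule.right, span, seen, derive)
            if split is not None:
                return [f"{symbol} -> {' '.join(rule.right)}"] + split
        return None

    def _split_derivation(symbols, span, seen, derive_fn):
        # Partition span into len(symbols) consecutive chunks, each derivable.
        def rec(si: int, pos: int) -> list[str] | None:
            if si == len(symbols):
                return [] if pos == len(span) else None
            remaining = len(symbols) - si - 1
            for end in range(pos + 1, len(span) - remaining + 1):
                head = derive_fn(symbols[si], span[pos:end], seen)
                if head is None:
                    continue
                tail = rec(si + 1, end)
                if tail is not None:
                    return head + tail
            return None

        return rec(0, 0)

    if not target:
        return False, []
    trace = derive(grammar.start, target, frozenset())
    return (trace is not None), (trace or [])


def export_library(
    library: FeatureLibrary,
    out_dir,
    so_table: dict[str, str] | None = None,
    stop_codons: Sequence[str] = DEFAULT_STOP_CODONS,
    popular_threshold: int = 17,
) -> dict:
    """Full export: parts with stripped CDS codons, per-host collections,
    FASTA of part sequences and the grammar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parts = library_to_parts(library, so_table)
    stripped = []
    n_stripped = 0
    for part in parts:
        if part.so_term == "SO:0000316":
            part, s, e = strip_terminal_codons(part, stop_codons)
            n_stripped += int(s or e)
        stripped.append(part)
    merged, merge_report = merge_after_strip(stripped, stop_codons)
    files = export_collections(merged, out_dir / "collections")
    with open(out_dir / "parts.fasta", "w") as fasta:
        for part in sorted(merged, key=lambda p: p.display_id):
            fasta.write(f">{part.display_id} {part.so_term}\n")
            for i in range(0, len(part.sequence), 70):
                fasta.write(part.sequence[i : i + 70] + "\n")
    grammar = build_grammar(merged, popular_threshold=popular_threshold)
    (out_dir / "grammar.json").write_text(grammar.to_json())
    return {
        "n_parts": len(merged),
        "n_stripped": n_stripped,
        "n_merged_after_strip": len(merge_report),
        "collection_files": [str(f) for f in files],
        "merge_report": merge_report,
    }
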