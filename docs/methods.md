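# Methods

This note documents the models, conventions and numerical choices behind
`partcurator`, and what the synthetic-data tests do and do not demonstrate.

## Data model and coordinates

GenBank 1-based inclusive locations are converted to 0-based half-open
intervals on ingest and converted back on output; `complement(...)` and
`join(...)` syntax is preserved. An origin-spanning feature on a circular
record is represented as the ordered two-part location `(a..L, 1..b)`; any
other multi-part location is treated as an intron/exon join. The feature
name is taken from the first `/note` qualifier and the description from the
second, with `/label`, `/gene`, `/product` as name fallbacks — annotation
exports differ in which qualifier they use. `source` features are skipped:
they describe the record, not a part. Expression-host metadata is not
standardized in GenBank, so hosts come from a sidecar TSV
(`record_id → host, application_domain`), normalized against a shipped
synonym table covering twelve canonical laboratory hosts plus
`Unspecified`; unknown host strings pass through with a warning rather than
being silently dropped.

## File-level deduplication

Two files are duplicates when their sequences are identical after
uppercasing, allowing reverse complement for all records and arbitrary
rotation for circular records; a linear record matching a rotation of a
circular record is a topological variant and collapses with it. Rotation
canonicalization uses Booth's least-rotation algorithm, so dedup is
O(total sequence length). The representative is the lexicographically
smallest record id — an arbitrary but deterministic choice. How
orientation variants of whole plasmids should be detected is not otherwise
constrained; reverse-complement matching is this package's definition.

## Curation

Sequence identity throughout curation is case-insensitive and
strand-sensitive: sequences are compared in reading orientation and
reverse-complement pairs are *not* merged, because orientation is resolved
at the plasmid level, not per feature. Step 3 (name merge) keys on
(sequence, description) and step 4 (description merge) on
(name, sequence), applied in that order; merge winners are chosen by summed
occurrence count with lexicographic tie-breaks. Homonym suffixes are
assigned in order of descending occurrence count, then lexicographically by
sequence, numbered from `-001`. Any historical numbering of a real curated
catalog is not recoverable from the data, so a deterministic convention is
used and documented. Manual judgments (e.g. collapsing positionally named
twins such as 5′/3′ long terminal repeats) are supported through an
optional user-supplied rename table applied before step 3, never
hard-coded. Nameless features receive `unnamed-NNNN` placeholders at
step 5 and are logged.

Provenance is conserved: after step 2, the sum of occurrence counts over
the library equals the number of surviving raw instances at every later
step, and step 5 never changes the feature count. Both properties are
asserted in tests.

## Variant comparison

Each variant is compared against its group consensus — defined as the
most-used variant (ties: longer sequence, then lexicographic), not a
column-majority artificial sequence — by pairwise alignment instead of a
multiple alignment: pairwise-vs-consensus is deterministic,
dependency-free, and sufficient for counting changes.

The alignment is a global alignment with free border runs: the columns
before the first and after the last aligned pair are border differences and
contribute neither score nor changes. Scoring is match +1, mismatch −2, gap
open −5 (first gap column), gap extend −1, implemented as a Gotoh
three-state dynamic program. The objective is lexicographic — maximize
score, then minimize counted bp changes, then minimize internal gap
columns — encoded in a single packed integer per cell, which makes the
reported counts well-defined even when several alignments tie on score.
Each internal mismatch counts one bp change and each internal gap column
counts one (a 3-bp indel is three changes). A consequence of free borders
on both sequences is that a substitution within two bases of a sequence end
ties with a border-shift interpretation and is then counted as a border
difference; synthetic edit plans keep planted edits in the interior, where
the optimum is unique. The implementation is checked against an exhaustive
alignment-path enumerator on short pairs and an independent recursive
oracle on 10 000 random pairs up to 12 bp.

`border_only` is true iff the internal region is change-free and the
sequences differ. A variant flagged border-only may in principle differ in
its flanks by more than annotation borders; for variants of a common
feature (the intended input) flanks are homologous and this reading matches
the "length-only variant" notion.

## Coding-change classification

Codons are read in the consensus frame (frame 0 of the full consensus
sequence); each internal mismatch is assigned to its consensus codon. A
codon pair translating identically is synonymous; otherwise the change is
conservative iff BLOSUM62(old, new) > 0 — the most common convention, and
configurable in principle since the matrix is loaded by name — else
non-conservative; substitutions creating or destroying a stop codon are
non-conservative. Internal indel columns in a CDS count as
non-conservative changes. Variants whose internal indels are not a
multiple of three break the frame; they are flagged `frameshift` and
classified at the DNA level only. `identical_protein` is true when the
variant has no internal indels and no non-synonymous changes (border trims
allowed), matching the "variants with no amino-acid changes" notion, which
counts border-trimmed variants as unchanged proteins.

## Table arithmetic and rounding

Derived ratio columns (changes/variant, changes/1000 bp, % length-only) are
printed to one decimal, rounded half-up (`decimal.ROUND_HALF_UP`), because
Python's banker's rounding would disagree with conventionally printed
tables. Percent-of-plasmids usage is rounded half-up to integers and counts
*distinct plasmids*, not instances. The three pooled change-type
percentages are a composition (they partition all counted bp changes), so
they are rounded with the largest-remainder method and always sum to
exactly 100; per-cell half-up rounding of a composition can sum to 99 or
101. The "variants with no amino-acid change" percentage is a plain share
and uses half-up rounding. Medians use the lower-median convention for
determinism on even counts.

## Part export and grammar

GenBank feature keys map to Sequence Ontology accessions through a shipped,
editable TSV covering the keys common in plasmid annotation; unmapped keys
fall back to the generic `SO:0000110` (sequence_feature) with a warning.
The START codon part is typed `SO:0000318` (an occasionally seen variant of
this accession with an extra zero is not a valid SO id). CDS parts have a
leading ATG and one trailing stop codon (default set TAA/TAG/TGA) stripped
unless stripping would leave less than one codon of ORF body; stripping is
recorded on the part and never applied twice, so it is idempotent even when
the ORF body itself begins with ATG. Parts identical after stripping (same
base name and sequence) are merged, and START/STOP are introduced as
standalone parts.

Part collections are versioned JSON documents (schema shipped in
`partcurator/data/part_collection.schema.json`): one per expression host
present (with `Unspecified` counting as a host), plus one combined — a
library with hosts {A, B} and unspecified parts yields four files. JSON
was chosen over an SBOL binding to keep the artifact dependency-light and
byte-exactly testable; the document carries the same fields (display id,
name, description, sequence, SO term) an SBOL DnaComponent would.

The grammar is a rewrite system: composition rules expand one category into
a sequence (e.g. a CDS is a START codon, an ORF and a STOP codon) and
subset rules substitute a category by a more specific one (a bacterial
terminator is a terminator). Categories without a corresponding SO term are
named with a leading `+`, user/project categories with `c-`. Construct
validation is memo-free recursive descent with split-point enumeration and
a cycle guard over unit derivations; it is exact for the small grammars this
package builds and is tested against an exhaustive rewriting enumerator.
Libraries are built per host, for all parts, and for "popular" parts used
in at least 17 plasmids (configurable threshold).

## Synthetic libraries

The generator's defaults define the study conditions: 8 plasmids (about
half circular, one forced circular to carry an origin-spanning feature),
20 base features over the common feature keys, 3 perfect-duplicate groups
of size 3, 2 ambiguous-base features and 1 intron-joined CDS, 2 name-synonym
groups of 3, 2 description-variant groups of 2, and 2 homonym families of 3
variants (one coding). Hosts cycle over *E. coli* and *S. cerevisiae* with
a quarter of plasmids unspecified — enough plasmids and structure for every
curation step and host-cardinality class to be exercised, while keeping a
library small enough that hundreds can be generated per test run. Feature
lengths are 90–240 bp (coding families ≥150 bp), backgrounds are uniform
random DNA.

Planted coding edits are selected at generation time by searching the codon
for a single-base change whose effect (synonymous / conservative /
non-conservative) is verified against the standard codon table and
BLOSUM62 — the same tables the analyzer uses — so the planted labels and
the analyzer's definitions cannot drift apart. Substitutions are spaced
and kept well inside feature bodies, and indels (deleted runs) are placed
away from substitutions, so the optimal alignment recovers the edit script
uniquely. All expected outputs — per-step curation counts, usage
histograms, host cardinalities, per-variant change counts — are computed
in closed form from the generation plan before any file is written.

What passing these tests shows: the pipeline implements its stated rules
exactly, end to end through real GenBank text. What it does not show:
behavior on real annotation noise the generator does not emulate —
biological sequence composition, near-identical (non-exact) duplicates,
inconsistent qualifier usage beyond the modeled fallbacks, or annotation
errors that require human judgment. Those remain the domain of the manual
rename table and downstream review.

## Problem sizes

Default test and acceptance runs use 200 generated libraries of ~50–90
feature instances each, alignment oracles on 10 000 random pairs ≤ 12 bp,
and exhaustive grammar enumeration to sentential forms of length 8. The
full suite runs in well under a minute on one CPU.
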