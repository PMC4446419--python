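# partcurator

Vendors and repositories distribute thousands of annotated plasmid files, but
their feature annotations are loosely organized: the same promoter appears
under several names, the same name covers several sequences, descriptions
disagree, and many features are duplicated verbatim across hundreds of
plasmids. `partcurator` turns a directory of annotated plasmid GenBank files
into a **non-redundant Standard Features Library** suitable for use as a
catalog of biological parts, and analyzes the variation structure of that
library.

It is aimed at synthetic biologists and curators of part registries who need
reproducible, scriptable curation of plasmid annotations rather than ad hoc
spreadsheet work.

## What it does

1. **File-level deduplication** — plasmids with identical sequence (up to
   rotation of circular molecules and reverse complement, including
   topological variants) are collapsed to one representative.
2. **Feature extraction** — every annotated feature is materialized in
   reading orientation, strand- and origin-aware; 5′ upstream windows
   (default 300 bp) of coding sequences can be extracted and grouped for
   promoter hunting.
3. **Five-step curation** to the Standard Features Library:
   1. collapse perfect duplicates — identical (sequence, name, description);
   2. remove inconsistent features — ambiguity codes (N, W, Y, …) or CDS with
      intron/exon `join` locations;
   3. merge name variants — same sequence under different names; the
      most-used name wins, the rest become synonyms;
   4. merge description variants — same (name, sequence), different
      descriptions; the most-used description wins;
   5. disambiguate homonyms — distinct sequences sharing a name get numeric
      suffixes (`MCS-001`, `MCS-002`, …); nameless features get placeholders.
   Steps 1–4 only merge (counts are non-increasing); step 5 only renames.
4. **Variant analysis** — features sharing a base name form a variant group;
   each variant is aligned against the group consensus (the most-used
   variant) with an ends-free pairwise alignment (match +1, mismatch −2, gap
   open −5, gap extend −1). Leading/trailing gap runs are *border
   differences* and are not counted; every internal mismatch or gap column is
   one bp change, so the per-group statistics

   - changes/variant = Σ changes ⁄ #variants,
   - changes/1000 bp = 1000 · Σ changes ⁄ Σ variant lengths,
   - % length-only variants (variants differing only in their borders)

   are fully determined by integer counts. For coding features each mismatch
   is assigned to its consensus codon and classified **synonymous**
   (identical translation), **conservative** (BLOSUM62 score > 0) or
   **non-conservative** (score ≤ 0; indel columns count here too).
5. **Statistics** — usage histograms and singleton counts, length
   distribution (lower median), GenBank feature-key distribution validated
   against the INSDC vocabulary, segmentation of features by expression host
   (12 canonical hosts + `Unspecified`), percent-of-plasmids usage per
   feature and per family.
6. **Part export** — features are mapped to Sequence Ontology terms via an
   editable GenBank-key→SO table, CDS parts have terminal START/STOP codons
   stripped (START and STOP become standalone parts; variants identical
   after stripping are merged), and per-host JSON part collections plus a
   rewrite grammar (categories + composition/subset rules, e.g.
   *CDS → START ORF STOP*, *bacterial terminator ⊂ terminator*) are written.
   `validate_construct` checks a sequence of part categories against the
   grammar and returns a derivation trace.
7. **Synthetic libraries** — a first-class generator plants duplicates,
   inconsistencies, synonym groups, description variants and homonym families
   with codon-verified edit plans, and derives every expected pipeline output
   in closed form before any file is written. This is how the pipeline is
   tested end to end with exact expectations.

## Worked example

Generate a synthetic library with known structure, curate it, and analyze
the variant groups:

```sh
partcurator simulate -o demo/gb --seed 5
partcurator curate   -i demo/gb -o demo/library
partcurator variants -l demo/library -o demo/variants
```

The `curate` step prints the per-step accounting:

```json
{
  "n_raw": 54,
  "n_after_perfect_dedup": 40,
  "n_after_inconsistent_removal": 37,
  "n_after_name_merge": 33,
  "n_after_description_merge": 31,
  "n_final": 31,
  "n_renamed": 6
}
```

54 feature instances on 8 plasmids collapse to 40 distinct
(sequence, name, description) triples; 3 inconsistent features are removed;
name merging saves 4 and description merging 2 more; the final library has
31 standard features, 6 of which (two homonym families of three variants)
received numeric suffixes. These numbers match the generator's closed-form
ground truth exactly (`demo/gb/ground_truth.json`).

`demo/variants/variant_groups.tsv` then contains one row per variant family:

```text
feature    coding  n_variants  n_occurrences  n_bp_changes  total_length_bp  changes_per_variant  changes_per_1000bp
family-00  True    3           7              3             450              1.0                  6.7
family-01  False   3           7              2             595              0.7                  3.4
Total              6           14             5             1045             0.8                  4.8
```

`family-00` is a coding family: its 3 bp changes are further classified in
`coding_changes.tsv` as synonymous/conservative/non-conservative, exactly
recovering the edits the generator planted.

`partcurator export -l demo/library -o demo/export` writes the SO-typed part
collections (one JSON document per expression host, one for unspecified
hosts, one combined) and `grammar.json`.

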