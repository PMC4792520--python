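# Methods

This note documents the model behind `metaforge`, the defaults that matter,
the numerical/tie-break choices, what the synthetic consortium does and
does not emulate, and the design decisions taken where the design was
genuinely open.

## The metadata model

Metadata are held as typed, linked records mirroring how sequencing assays
are actually performed: a **donor** (or model-organism strain) supplies one
or more **biosamples**; a **library** is nucleic acid extracted from one
biosample; a **replicate** is one performance of an assay, linking one
library (and, for immunoprecipitation assays, one **antibody lot**) into an
**experiment**; **files** carry format, output type, an md5 checksum of
their content and `derived_from` edges recording computational provenance;
**pipelines** and **software** records capture versions and download
checksums because outputs depend on both. Control experiments are modelled
as ordinary experiments carrying a `control_type`, referenced from
`possible_controls`.

Replicate relationships are derived, not declared: two replicates are
*technical* when their libraries come from the same biosample, *isogenic
biological* when their biosamples differ but share a donor, *anisogenic
biological* otherwise. Only the library-level definition of a technical
replicate is implemented; the classifier is a single function
(`MetadataStore.classify_replicates`) and is the extension point should a
different operational definition be needed.

## Schema language

The validator implements a deliberately closed keyword set: `kind` (text,
integer, number, boolean, list, link, document-ref), `enum`, `pattern`,
`link_to`, `items`, `required`, `dependencies`, `identifying_fields`,
`schema_version`. Anything else is a loud error — for a curated standard,
silently ignored keywords become silent policy. Choices within that:

- **Patterns are anchored full matches.** A partial match would accept
  `ENCSR000DVIgarbage` as an identifier.
- **Dependencies** come in presence-triggered and value-triggered forms,
  and may require or forbid fields. Internally a trigger field maps to a
  *list* of rules (the biosample type dispatches three different term-field
  requirements); a single rule is the common case.
- **Unknown record fields are violations** by default, downgradable to
  warnings (`strict_unknown=False`) for exploratory loading.
- **Status lifecycle** is the enumerated list `{in progress, released,
  replaced, deleted}`. This particular list is a project choice; the
  standard only requires that it be closed. Deletion is a status, never
  physical removal, because accession stability forbids re-use.
- Schema documents carry an integer `schema_version`; migration machinery
  is out of scope, the field is stored.

## Accessions

Grammar: `ENC` + type code (`SR` experiment, `BS` biosample, `DO` donor,
`AB` antibody lot, `LB` library, `FF` file) + 3 decimal digits + 3
uppercase letters: 10³ × 26³ = 17,576,000 serials per type. Decisions:

- **Seeded pseudo-random minting without replacement** (not sequential), so
  accession text leaks nothing about submission order. Minting is
  reproducible from (registry state, seed). Rejection sampling with a
  deterministic fallback to enumeration keeps minting O(1) while the space
  is sparse and exact near exhaustion.
- **Full A–Z alphabet, uppercase only.** No ambiguity-avoidance alphabet:
  the grammar says `[A-Z]`, and published examples freely use I and D.
- **Append-only plain-text ledger** (one accession per line, `#` comments)
  so stability survives restarts.
- File supersession is a map new → old; self-supersession, double
  supersession of the same file, and cycles are rejected; chains are
  walkable.
- The serial space is treated as flat — no per-lab or per-epoch blocks.

## Store semantics

- **Dangling links are tolerated during loading and rejected at
  `finalize()`**, mirroring partial submissions (one biological replicate
  may arrive before the second) while keeping released stores consistent.
- **`paired_with` symmetry is auto-completed at finalize** (if a names b,
  b gains the back-reference) rather than erroring. Auditing deliberately
  skips that repair (`finalize(complete_pairs=False)`) so one-sided pairs
  are visible as submitted.
- **Embedding depth defaults to 4**: the chain experiment → replicate →
  library → biosample → donor is four links, and donor fields should be
  reachable from an embedded experiment document. Depth is configurable;
  cycles terminate by embedding any revisited record as a bare id, making
  embedding a pure function of (store, id, depth).
- **Provenance order**: a file's ancestors are sorted by longest derivation
  distance from the file, ties by id. Longest-path layering is a valid
  topological order on a DAG, and it reads nearest-first (bam before the
  fastqs it came from). Cycles raise an error naming the cycle, both per
  query and at finalize.

## Audits

Rules are data (a registry of pure predicates), so projects can extend the
ruleset without touching the engine. Applicability keys off the
experiment's OBI assay term (`OBI:0000716` ChIP-seq, `OBI:0001271`
RNA-seq), never free text. Severities are a project choice: R1/R2
(ChIP-seq antibody/control omissions) are *not-compliant* — breaches of the
submission standard; R3 (missing spike-ins) is a *warning* — it degrades
calibration but the data stand; R4–R7 (broken pairing, inconsistent
technical replicates, unlinked files, library-less replicates) are
*errors* — structural defects. Experiments declaring a `control_type` are
exempt from R1/R2: an input-library control has no antibody and needs no
control of its own. Which assays beyond ChIP-seq require controls is left
configurable; the shipped rule applies to ChIP-seq only. Quality metrics
(read depth, concordance) are stored as fields but not audited numerically
— no thresholds are part of this standard.

## Ontologies and search

Toy slices of UBERON (tissues), CL (primary cells), EFO (cell lines), OBI
(assays) and ChEBI (treatments) — 28 terms — ship as OBO files; the loader
(built on `obonet`) accepts full-size ontologies but no test requires one.
Slices are merged into one bundle before integrity checks because
`part_of` edges legitimately cross namespaces (keratinocyte, a CL term, is
part of the UBERON skin epidermis). Both `is_a` and `part_of` are traversed
for ancestor closure and slimming — anatomical grouping is exactly why a
skin search should find keratinocytes — and the edge labels are preserved
so stricter traversal can be configured. Slimming is reflexive: a term in
its own slim set maps to itself. Synonyms are indexed for search but never
accepted as term identifiers in records.

Search indexes each record's depth-embedded document: lowercase tokens
split on non-alphanumerics, with accessions and CURIEs kept whole, no
stemming (stemming a curated vocabulary conflates terms). Queries use
intersection semantics; ranking is total match count with ties broken by
record id, which makes results independent of insertion order. Facet counts
are computed over the current result set, matching faceted-browsing
semantics. Because linked records embed each other, searching an accession
returns the record *and* the records that reference it; filtered to the
record's own type it returns exactly that record.

## Exporters and MINSEQE

ISA-TAB gets one study row per distinct biosample and one assay row per
(replicate, raw file); GEO SOFT one `^SERIES` per experiment and one
`^SAMPLE` per replicate. Exported file names are accession + "." + format
extension. Which ISA-TAB columns to populate beyond the structural mapping
is an implementation choice, documented in the column headers themselves.
MINSEQE is a guideline, so compliance is operationalized as five concrete
checks: assay described (OBI term present), samples described (every
replicate resolves library → biosample → donor), protocols present (≥ 1
document on a library or biosample), raw data present (≥ 1 fastq file),
processed data present (≥ 1 non-fastq file). Exports are pure functions of
the store; re-export is byte-identical. SRA-XML and GA4GH formats are out
of scope; the exporter surface is a plain function per format so they can
be added.

## The synthetic consortium

`FixtureSpec` defaults describe a small consortium sized for exhaustive
checking on a laptop: 6 donors (5 human, 1 mouse), 2 biosamples per donor,
12 ChIP-seq + 8 RNA-seq experiments (~20, plus 2 input controls), 2
replicates per experiment, one paired-end fastq pair per replicate with a
fastq → bam → bigWig chain. The layout guarantees the structures the rest
of the package exercises: one donor contributing both a liver and a brain
biosample, a keratinocyte pair (held out of the general term pool so the
"skin" search has an unambiguous expected set), three
technical-replicate experiments, one anisogenic experiment, antibody lots
with lot numbers, spike-ins on every RNA-seq library, and
pipeline/software records with versions and md5sums. All randomness flows
from one seeded generator and all accessions are minted through the
registry, so a spec maps to a byte-identical store.

`corrupt()` plants violations as minimal single edits chosen so each
induces exactly one audit flag: e.g. for a one-sided pair (R4) the
*partner* file loses its back-reference and is downgraded to single-ended,
leaving exactly one flag on the surviving paired-ended file. A reservation
set keeps edits from touching records other edits depend on (removing a
spike-in-less library's replicate link would otherwise erase the planted
R3 flag). Infeasible plans — more violations than eligible targets — raise
rather than silently under-plant.

What the generator does *not* emulate: realistic sequence content or
quality-metric distributions, submission errors other than the planted
rule violations, multi-lab contention, or ontology annotation mistakes.
Passing tests therefore demonstrate the correctness of the machinery —
validation, audit recall/precision, search expansion, export structure —
on well-formed and deliberately broken graphs, not robustness to the full
noise of real submission streams.

## Problem sizes

The shipped tests and `scripts/acceptance.py` run on the default
consortium (~305 records, 22 experiments), 50-node random provenance DAGs
(3 seeds), 40-node random ontology DAGs, the 260-element reduced accession
grammar enumerated exhaustively, and 10,000-accession mass minting. These
sizes make every brute-force oracle exact while keeping the whole suite
under a few seconds.

## Known limitations

- Single-writer, in-memory store; no transactions or relational backend.
- Fixed audit ruleset identifiers (R1–R7) with configurability by
  selection, not yet by external rule files.
- OBO subset only (`[Term]`, `id`, `name`, `is_a`, `relationship:
  part_of`, `synonym`); no OWL reasoning, obsolescence or cross-ontology
  axioms.
- Schema migration across `schema_version` values is not implemented.
- JSON-LD contexts and web-service layers are out of scope by design.
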