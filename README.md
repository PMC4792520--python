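# metaforge

A typed, accessioned, linked metadata object store for high-throughput
sequencing assays, in the style of a genomics data coordination center
(DCC). Consortium-scale projects describe every assay with structured
metadata — the donor and biosample the material came from, the library
prepared from it, the antibody lot used, the replicates performed, the data
files produced and the software that produced them. `metaforge` implements
that standard as a reusable Python library and CLI for data wranglers,
submission pipelines and anyone building a small LIMS around sequencing
metadata. No sequence data are ever read: only their descriptions.

## What it does

- **Schema validation.** Each record type (donor, biosample, library,
  antibody lot, experiment, replicate, file, pipeline, software, document,
  treatment, lab, award) is defined by a JSON schema document with typed
  properties, enumerated lists, anchored regex patterns, link targets and
  conditional dependencies (e.g. a file with `run_type = "paired-ended"`
  must name its `paired_with` partner). Unknown keywords are rejected
  loudly; partial submissions are legal.
- **Accessions.** Identifiers follow the grammar
  `ENC(SR|BS|DO|AB|LB|FF)[0-9]{3}[A-Z]{3}` — 10³ × 26³ = **17,576,000**
  serials per entity type. Accessions are stable and never re-issued, even
  for deleted records; replacement files get new accessions linked to the
  ones they supersede.
- **Linked object store.** Referential integrity over the graph
  donor ← biosample ← library ← replicate → experiment, with file
  provenance as a `derived_from` DAG. Replicate pairs classify as
  *technical* (same biosample), *isogenic biological* (same donor,
  different biosamples) or *anisogenic biological* (different donors).
- **Audits.** Declarative post-submission rules (R1–R7): ChIP-seq
  replicates need antibody lots, ChIP-seq experiments need controls,
  RNA-seq libraries should declare spike-ins, paired files must pair
  symmetrically, technical replicates must share a biosample, files must
  link replicates, replicates must link libraries.
- **Ontology-backed search.** Toy UBERON/CL/EFO/OBI/ChEBI slices validate
  controlled-vocabulary fields; ancestor closures over `is_a`/`part_of`
  drive slim annotation, so a search for `skin` finds keratinocyte assays
  even though no record contains that string. Facet counts support
  filter-driven browsing.
- **Export.** ISA-TAB (investigation/study/assay tables), GEO SOFT
  (`^SERIES`/`^SAMPLE` blocks) and a five-point MINSEQE compliance check.
- **Synthetic consortium fixtures.** A seeded generator emits a complete,
  clean submission stream — or one with planted, ground-truthed violations
  — so every layer is testable offline.

## Worked example

```sh
$ metaforge fixtures --seed 7 --out store.json
305 records -> store.json

$ metaforge search store.json "skin" --types experiment --facet assay_term_name
id	type	rank
ENCSR320VJR	experiment	1
ENCSR653ANW	experiment	2
# facet: assay_term_name
ChIP-seq	2
```

Neither experiment mentions "skin": both assay keratinocytes
(`CL:0000312`), whose ontology ancestors run keratinocyte → skin epidermis
→ *skin of body* (`UBERON:0002097`), a slim term the index attaches to the
records. The facet block shows both hits are ChIP-seq experiments.

```sh
$ metaforge check-accession ENCBS046RNA
ENCBS046RNA	BS	biosample

$ metaforge fixtures --seed 7 --out bad.json --violations R1:1,R4:1 --truth truth.tsv
305 records -> bad.json
2 planted violations -> truth.tsv

$ metaforge audit bad.json ; echo "exit=$?"
record_id	rule_id	severity	message
ENCFF124BGW	R4	error	one-sided pairing: ENCFF710PWZ does not name ENCFF124BGW back
rep-ENCSR320VJR-1-1	R1	not-compliant	ChIP-seq replicate in ENCSR320VJR has no antibody link
exit=1
```

The audit recovers exactly the two planted violations — a fastq whose
paired-end partner no longer names it back, and a ChIP-seq replicate
stripped of its antibody lot — and exits 1 so CI pipelines fail on dirty
metadata.

The same operations are available as library calls
(`metaforge.generate_consortium`, `metaforge.run_audits`,
`metaforge.build_index`, `metaforge.export_isatab`, ...); see the module
docstrings and `docs/methods.md`.

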