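"""Keyword search with ontology expansion, plus facet counts.

Records are indexed from their *embedded* form, so an experiment's tokens
include text from its replicates, libraries, biosamples and donors. On top
of the literal text, every ontology-annotated term contributes its synonyms
and its *slim* terms — the high-level ancestors chosen as browsing
categories. That is what lets a query for ``skin`` find assays on
keratinocytes: no record contains the string, but the keratinocyte term's
ancestor closure intersects the slim set at *skin of body*.

Tokenization is deliberately conservative: lowercase, split on
non-alphanumerics, but accessions and ontology CURIEs stay intact as single
tokens. No stemming — the vocabulary is curated, and stemming a controlled
term is how "liver" and "lively" become the same assay.

Multi-token queries use intersection semantics; ranking is by total match
count with ties broken by record id, so results are stable and reproducible.
Facet counts are computed over the current result set, matching
faceted-browsing behaviour.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional

from .errors import SearchError
from .ontology import OntologyBundle
from .store import DEFAULT_EMBED_DEPTH, MetadataStore

_TOKEN_RE = re.compile(
    r"ENC(?:SR|BS|DO|AB|LB|FF)[0-9]{3}[A-Z]{3}"  # accessions stay whole
    r"|[A-Za-z]+:[0-9A-Za-z_]+"                  # CURIEs stay whole
    r"|[A-Za-z0-9]+"
)

#: default browsing slim: high-level anatomical / assay categories
DEFAULT_SLIM_TERMS = (
    "UBERON:0002097",  # skin of body
    "UBERON:0002107",  # liver
    "UBERON:0000955",  # brain
    "UBERON:0000178",  # blood
)

_CURIE_RE = re.compile(r"[A-Z][A-Za-z]*:[0-9A-Za-z_]+")


def tokenize(text: str) -> list[str]:
    return [token.lower() for token in _TOKEN_RE.findall(text)]


@dataclass
class SearchIndex:
    """Inverted index: token -> {record id -> occurrence count}."""

    postings: dict[str, dict[str, int]] = field(default_factory=dict)
    facet_fields: tuple = ()
    #: record id -> values per facet field (from the embedded document)
    facet_values: dict[str, dict[str, tuple]] = field(default_factory=dict)
    #: record id -> names of slim terms its annotations roll up to
    slim_annotations: dict[str, set] = field(default_factory=dict)
    record_types: dict[str, str] = field(default_factory=dict)

    def _post(self, token: str, record_id: str, count: int = 1) -> None:
        bucket = self.postings.setdefault(token, {})
        bucket[record_id] = bucket.get(record_id, 0) + count


def _walk_strings(value: Any):
    if isinstance(value, str):
        yield value
    elif isinstance(value, Mapping):
        for v in value.values():
            yield from _walk_strings(v)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _walk_strings(v)
    elif value is not None:
        yield str(value)


def _path_values(doc: Any, path: list[str]):
    """Values at a dotted path in an embedded document; lists fan out."""
    if not path:
        if isinstance(doc, (str, int, float, bool)):
            yield doc
        return
    head, rest = path[0], path[1:]
    if isinstance(doc, Mapping) and head in doc:
        value = doc[head]
        values = value if isinstance(value, list) else [value]
        for one in values:
            yield from _path_values(one, rest)


def build_index(
    store: MetadataStore,
    embed_depth: int = DEFAULT_EMBED_DEPTH,
    facet_fields: Iterable[str] = (),
    ontology: Optional[OntologyBundle] = None,
    slim_terms: Iterable[str] = DEFAULT_SLIM_TERMS,
    record_types: Optional[Iterable[str]] = None,
) -> SearchIndex:
    """Index every (non-deleted) record from its depth-embedded document."""
    facet_fields = tuple(facet_fields)
    index = SearchIndex(facet_fields=facet_fields)
    slim_set = set(slim_terms) if ontology is not None else set()
    unknown_slims = slim_set - set(ontology.terms) if ontology is not None else set()
    if unknown_slims:
        raise SearchError(f"slim set contains unknown term(s) {sorted(unknown_slims)}")
    keep = set(record_types) if record_types is not None else None

    for record in store.records():
        if record.deleted or (keep is not None and record.type_name not in keep):
            continue
        doc = store.embed_object(record.id, embed_depth)
        index.record_types[record.id] = record.type_name

        strings = list(_walk_strings(doc))
        for text in strings:
            for token in tokenize(text):
                index._post(token, record.id)

        if ontology is not None:
            annotated = {
                s for s in strings if _CURIE_RE.fullmatch(s) and s in ontology
            }
            slim_names = set()
            for term_id in sorted(annotated):
                for synonym in ontology.get(term_id).synonyms:
                    for token in tokenize(synonym):
                        index._post(token, record.id)
                for slim_id in ontology.slim_terms(term_id, slim_set):
                    slim_names.add(ontology.name_of(slim_id))
            for name in sorted(slim_names):
                for token in tokenize(name):
                    index._post(token, record.id)
            index.slim_annotations[record.id] = slim_names

        values = {}
        for facet_field in facet_fields:
            found = tuple(sorted(str(v) for v in _path_values(doc, facet_field.split("."))))
            if found:
                values[facet_field] = found
        index.facet_values[record.id] = values
    return index


def keyword_search(
    index: SearchIndex,
    query_text: str,
    record_types: Optional[Iterable[str]] = None,
) -> list[str]:
    """Record ids matching *all* query tokens, ranked by match count.

    Empty queries return nothing. Ties rank by record id, so insertion
    order never shows through.
    """
    tokens = tokenize(query_text)
    if not tokens:
        return []
    result: Optional[set] = None
    for token in tokens:
        ids = set(index.postings.get(token, {}))
        result = ids if result is None else (result & ids)
        if not result:
            return []
    if record_types is not None:
        allowed = set(record_types)
        result = {rid for rid in result if index.record_types.get(rid) in allowed}

    def score(record_id: str) -> int:
        return sum(index.postings[token].get(record_id, 0) for token in tokens)

    return sorted(result, key=lambda rid: (-score(rid), rid))


def facet_counts(
    index: SearchIndex, result_ids: Iterable[str], facet_field: str
) -> dict[str, int]:
    """Value -> count over the result set for one registered facet field."""
    if facet_field not in index.facet_fields:
        raise SearchError(f"facet field {facet_field!r} is not registered on this index")
    counts: dict[str, int] = {}
    for record_id in result_ids:
        for value in index.facet_values.get(record_id, {}).get(facet_field, ()):
            counts[value] = counts.get(value, 0) + 1
    return dict(sorted(counts.items()))
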