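"""Ontology slices for controlled-vocabulary validation and search expansion.

Biosamples, assays and treatments are annotated with terms from community
ontologies rather than free text: UBERON for tissues, CL for primary cell
types, EFO for immortalized cell lines, OBI for assay names and ChEBI for
treatment agents. This module loads OBO-format slices of those ontologies
into one bundle, validates that each annotated field uses a term from the
allowed namespace, and computes ancestor closures over ``is_a`` and
``part_of`` edges.

Ancestor closures drive "slimming": a record annotated with *keratinocyte*
(CL:0000312, part_of skin epidermis, part_of skin of body) acquires the
high-level slim term *skin of body*, which is how a search for "skin" finds
keratinocyte assays even though no record contains that string.

Parsing is delegated to :mod:`obonet`; this module adds bundle-level
integrity checks (duplicate ids, dangling parents, cycles) and the closure
algebra.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet

from .errors import OntologyError

#: edge labels traversed by default when computing ancestors/slims
DEFAULT_RELATIONS = ("is_a", "part_of")

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass(frozen=True)
class OntologyTerm:
    """One controlled-vocabulary node."""

    term_id: str
    name: str
    #: (parent_id, edge_label) pairs; labels are "is_a" or "part_of"
    parents: tuple = ()
    synonyms: tuple = ()

    @property
    def namespace(self) -> str:
        return self.term_id.split(":", 1)[0]


class OntologyBundle:
    """A set of ontology slices loaded together.

    Cross-namespace ``part_of`` edges (e.g. a CL cell type located in an
    UBERON structure) are legal as long as the target is defined somewhere
    in the bundle, so integrity is checked after all slices are merged.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms = dict(terms)
        self._check()

    # -- loading ----------------------------------------------------------

    @classmethod
    def from_texts(cls, texts: Iterable[str]) -> "OntologyBundle":
        terms: dict[str, OntologyTerm] = {}
        for text in texts:
            for term in _parse_obo_text(text):
                if term.term_id in terms:
                    raise OntologyError(f"duplicate term id {term.term_id}")
                terms[term.term_id] = term
        return cls(terms)

    @classmethod
    def from_files(cls, paths: Iterable[str | Path]) -> "OntologyBundle":
        return cls.from_texts(Path(p).read_text(encoding="utf-8") for p in paths)

    @classmethod
    def from_dir(cls, path: str | Path) -> "OntologyBundle":
        return cls.from_files(sorted(Path(path).glob("*.obo")))

    @classmethod
    def builtin(cls) -> "OntologyBundle":
        """The toy UBERON/CL/EFO/OBI/ChEBI slices shipped with the package."""
        root = resources.files("metaforge").joinpath("data/ontology")
        texts = [
            entry.read_text(encoding="utf-8")
            for entry in sorted(root.iterdir(), key=lambda e: e.name)
            if entry.name.endswith(".obo")
        ]
        return cls.from_texts(texts)

    def _check(self) -> None:
        graph = nx.DiGraph()
        for term in self.terms.values():
            graph.add_node(term.term_id)
            for parent_id, _label in term.parents:
                if parent_id not in self.terms:
                    raise OntologyError(
                        f"{term.term_id}: parent {parent_id} not defined in bundle"
                    )
                graph.add_edge(term.term_id, parent_id)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"parent graph has a cycle: {cycle}")

    # -- queries ----------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def get(self, term_id: str) -> OntologyTerm:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term {term_id!r}")
        return self.terms[term_id]

    def name_of(self, term_id: str) -> str:
        return self.get(term_id).name

    def ancestors(
        self, term_id: str, relations: tuple = DEFAULT_RELATIONS
    ) -> set[str]:
        """Transitive closure of parents over the given edge labels.

        Reflexive-free: a term is not its own ancestor.
        """
        self.get(term_id)
        seen: set[str] = set()
        frontier = [term_id]
        while frontier:
            node = frontier.pop()
            for parent_id, label in self.terms[node].parents:
                if label in relations and parent_id not in seen:
                    seen.add(parent_id)
                    frontier.append(parent_id)
        return seen

    def slim_terms(
        self,
        term_id: str,
        slim_set: Iterable[str],
        relations: tuple = DEFAULT_RELATIONS,
    ) -> set[str]:
        """Slims matched by a term: ({term} ∪ ancestors) ∩ slim_set.

        Reflexive on purpose — a term in its own slim set maps to itself.
        """
        slims = set(slim_set)
        unknown = slims - set(self.terms)
        if unknown:
            raise OntologyError(f"slim set contains unknown term(s) {sorted(unknown)}")
        return ({term_id} | self.ancestors(term_id, relations)) & slims


def load_ontology(obo_text: str) -> OntologyBundle:
    """Load a single OBO document as a standalone bundle."""
    return OntologyBundle.from_texts([obo_text])


def _parse_obo_text(text: str) -> list[OntologyTerm]:
    # duplicate-id detection must precede obonet, which silently merges
    ids = re.findall(r"^\[Term\]\s*\nid: *(\S+)", text, flags=re.MULTILINE)
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise OntologyError(f"duplicate term id(s) within document: {sorted(dupes)}")
    try:
        graph = obonet.read_obo(io.StringIO(text))
    except Exception as exc:  # obonet raises assorted parse errors
        raise OntologyError(f"OBO parse failure: {exc}") from exc
    terms = []
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            # referenced but never defined in this document; the bundle-level
            # check decides whether another slice supplies it
            continue
        parents = [(p, "is_a") for p in data.get("is_a", [])]
        for rel in data.get("relationship", []):
            label, _, target = rel.partition(" ")
            if label == "part_of":
                parents.append((target.strip(), "part_of"))
        synonyms = []
        for raw in data.get("synonym", []):
            match = _SYNONYM_RE.match(raw)
            if match:
                synonyms.append(match.group(1))
        terms.append(
            OntologyTerm(
                term_id=node,
                name=data["name"],
                parents=tuple(parents),
                synonyms=tuple(synonyms),
            )
        )
    return terms


#: default controlled-vocabulary constraints: (type_name, field) -> namespaces
DEFAULT_TERM_CONSTRAINTS: dict[tuple, frozenset] = {
    ("biosample", "tissue_term"): frozenset({"UBERON"}),
    ("biosample", "cell_term"): frozenset({"CL"}),
    ("biosample", "cell_line_term"): frozenset({"EFO"}),
    ("experiment", "assay_term"): frozenset({"OBI"}),
    ("treatment", "treatment_term"): frozenset({"CHEBI"}),
}


@dataclass(frozen=True)
class TermViolation:
    type_name: str
    field: str
    term_id: str
    kind: str  # unknown-term | namespace
    message: str


def validate_term(
    bundle: OntologyBundle,
    type_name: str,
    field_name: str,
    term_id: str,
    constraints: Optional[Mapping[tuple, frozenset]] = None,
) -> Optional[TermViolation]:
    """Check one annotated term; returns None when the usage is valid."""
    constraints = DEFAULT_TERM_CONSTRAINTS if constraints is None else constraints
    allowed = constraints.get((type_name, field_name))
    if allowed is None:
        return None  # unconstrained field
    if term_id not in bundle:
        return TermViolation(
            type_name, field_name, term_id, "unknown-term",
            f"term {term_id!r} not found in the loaded ontology bundle",
        )
    namespace = bundle.get(term_id).namespace
    if namespace not in allowed:
        return TermViolation(
            type_name, field_name, term_id, "namespace",
            f"{field_name} requires {sorted(allowed)} terms, got {namespace}",
        )
    return None


def validate_store_terms(
    store,
    bundle: OntologyBundle,
    constraints: Optional[Mapping[tuple, frozenset]] = None,
) -> list[TermViolation]:
    """Validate every constrained term field across a store."""
    constraints = DEFAULT_TERM_CONSTRAINTS if constraints is None else constraints
    violations = []
    for record in store.records():
        for (type_name, field_name), _allowed in sorted(constraints.items()):
            if record.type_name != type_name:
                continue
            value = record.properties.get(field_name)
            if value is None:
                continue
            violation = validate_term(bundle, type_name, field_name, value, constraints)
            if violation is not None:
                violations.append(violation)
    return violations
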