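"""The linked metadata object store.

Records (donors, biosamples, libraries, replicates, experiments, files, ...)
form a graph: a biosample links its donor, a library its biosample, a
replicate its library and experiment, a file the files it derives from. The
store holds that graph, tolerating dangling links while a submission is in
flight and enforcing referential integrity at :meth:`MetadataStore.finalize`
— mirroring how partial submissions are accepted but released metadata must
be consistent.

Besides storage, the store owns the graph semantics the standard defines:

* replicate classification — two replicates are *technical* when their
  libraries come from the same biosample, *isogenic biological* when the
  biosamples differ but share a donor, *anisogenic biological* otherwise;
* file provenance — ``derived_from`` edges must form a DAG, and a file's
  ancestry is reported nearest-first in topological order;
* embedding — expanding link fields into nested documents to a given depth,
  with cycle-safe termination, used for search indexing and export.

Deletion is a status change, never removal: accessions are stable, and a
link to a deleted record is as dangling as a link to a missing one.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Optional

import networkx as nx

from .errors import IntegrityError, ProvenanceCycleError, StoreError
from .schemas import (
    ID_KEY,
    SchemaRegistry,
    ValidationReport,
    builtin_registry,
)

#: default link-expansion depth: experiment -> replicate -> library ->
#: biosample -> donor is four links, and donor fields should be reachable
#: from an embedded experiment
DEFAULT_EMBED_DEPTH = 4


@dataclass
class MetadataObject:
    """One record: identity, type, and schema-conforming properties."""

    id: str
    type_name: str
    properties: dict[str, Any] = field(default_factory=dict)

    @property
    def status(self) -> str:
        return self.properties.get("status", "in progress")

    @property
    def deleted(self) -> bool:
        return self.status == "deleted"

    def get(self, name: str, default=None):
        return self.properties.get(name, default)

    def to_json_dict(self) -> dict:
        return {ID_KEY: self.id, **self.properties}


@dataclass(frozen=True)
class IntegrityFinding:
    record_id: str
    field: str
    target_id: str
    problem: str  # dangling-link | mistyped-link
    message: str

    def __str__(self) -> str:
        return f"{self.record_id}.{self.field} -> {self.target_id}: {self.problem}"


# pairwise replicate relationships
TECHNICAL = "technical"
ISOGENIC = "isogenic-biological"
ANISOGENIC = "anisogenic-biological"


class MetadataStore:
    """Typed, linked object store validated against a schema registry."""

    def __init__(self, registry: Optional[SchemaRegistry] = None):
        self.registry = registry if registry is not None else builtin_registry()
        self._records: dict[str, MetadataObject] = {}
        self._identity: dict[tuple, str] = {}  # (type, field, value) -> id
        self.finalized = False

    # -- basic access -----------------------------------------------------

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def get(self, record_id: str) -> MetadataObject:
        if record_id not in self._records:
            raise StoreError(f"unknown record id {record_id!r}")
        return self._records[record_id]

    def get_type(self, record_id: str) -> Optional[str]:
        record = self._records.get(record_id)
        return None if record is None else record.type_name

    def records(self, type_name: Optional[str] = None) -> Iterator[MetadataObject]:
        for record_id in sorted(self._records):
            record = self._records[record_id]
            if type_name is None or record.type_name == type_name:
                yield record

    def ids(self, type_name: Optional[str] = None) -> list[str]:
        return [r.id for r in self.records(type_name)]

    # -- mutation ---------------------------------------------------------

    def add_object(
        self, record: MetadataObject, *, validate: bool = True, strict_unknown: bool = True
    ) -> MetadataObject:
        """Add a record. Dangling links are tolerated until finalize; duplicate
        ids and duplicate identifying-field values are rejected immediately."""
        if record.id in self._records:
            raise StoreError(f"duplicate record id {record.id!r}")
        schema = self.registry.get(record.type_name)
        if validate:
            report = self.registry.validate(
                record.type_name,
                record.properties,
                record_id=record.id,
                strict_unknown=strict_unknown,
            )
            if not report.valid:
                problems = "; ".join(v.message for v in report.violations)
                raise StoreError(f"record {record.id!r} fails validation: {problems}")
        for field_name in schema.identifying_fields:
            value = record.properties.get(field_name)
            if value is None:
                continue
            key = (record.type_name, field_name, value)
            if key in self._identity:
                raise StoreError(
                    f"{record.type_name}.{field_name}={value!r} already used "
                    f"by {self._identity[key]!r}"
                )
            self._identity[key] = record.id
        self._records[record.id] = record
        self.finalized = False
        return record

    def add(self, type_name: str, record_id: str, **properties) -> MetadataObject:
        return self.add_object(MetadataObject(record_id, type_name, properties))

    def delete(self, record_id: str) -> None:
        """Mark a record deleted. The record (and its accession) remains."""
        self.get(record_id).properties["status"] = "deleted"
        self.finalized = False

    # -- links ------------------------------------------------------------

    def _link_fields(self, record: MetadataObject) -> Iterator[tuple[str, str, str]]:
        """Yield (field, target_id, target_type) for every link value."""
        schema = self.registry.get(record.type_name)
        for field_name, target_type in sorted(schema.link_targets().items()):
            value = record.properties.get(field_name)
            if value is None:
                continue
            for target_id in value if isinstance(value, list) else [value]:
                yield field_name, target_id, target_type

    def check_referential_integrity(self) -> list[IntegrityFinding]:
        """Every link must resolve to a live record of the declared type."""
        findings = []
        for record in self.records():
            if record.deleted:
                continue
            for field_name, target_id, target_type in self._link_fields(record):
                target = self._records.get(target_id)
                if target is None or target.deleted:
                    reason = "deleted" if target is not None else "missing"
                    findings.append(
                        IntegrityFinding(
                            record.id, field_name, target_id, "dangling-link",
                            f"link target {target_id!r} is {reason}",
                        )
                    )
                elif target.type_name != target_type:
                    findings.append(
                        IntegrityFinding(
                            record.id, field_name, target_id, "mistyped-link",
                            f"expected {target_type}, found {target.type_name}",
                        )
                    )
        return findings

    def validate_all(self, strict_unknown: bool = True) -> list[ValidationReport]:
        """Schema-validate every record (with link-type checks); pure."""
        return [
            self.registry.validate(
                record.type_name,
                record.properties,
                record_id=record.id,
                store=self,
                strict_unknown=strict_unknown,
            )
            for record in self.records()
        ]

    def finalize(self, complete_pairs: bool = True) -> None:
        """Complete paired_with symmetry, then require full integrity.

        One-sided pairs gain the back-reference (a deliberate repair, since
        the pairing relation is symmetric by definition); dangling or
        mistyped links raise :class:`IntegrityError`. Pass
        ``complete_pairs=False`` to check integrity without that repair —
        auditing wants to see the submission exactly as it arrived.
        """
        for record in self.records("file") if complete_pairs else ():
            partner_id = record.get("paired_with")
            if partner_id is None or partner_id not in self._records:
                continue
            partner = self._records[partner_id]
            if partner.type_name == "file" and partner.get("paired_with") is None:
                partner.properties["paired_with"] = record.id
                partner.properties.setdefault("run_type", "paired-ended")
        findings = self.check_referential_integrity()
        if findings:
            raise IntegrityError(findings)
        cycle = self._find_provenance_cycle()
        if cycle is not None:
            raise ProvenanceCycleError(cycle)
        self.finalized = True

    # -- replicate semantics ----------------------------------------------

    def replicates_of(self, experiment_id: str) -> list[MetadataObject]:
        experiment = self.get(experiment_id)
        if experiment.type_name != "experiment":
            raise StoreError(f"{experiment_id!r} is a {experiment.type_name}, not an experiment")
        return [
            r for r in self.records("replicate")
            if r.get("experiment") == experiment_id and not r.deleted
        ]

    def _biosample_and_donor(self, replicate: MetadataObject) -> tuple[str, str]:
        library_id = replicate.get("library")
        if library_id is None:
            raise StoreError(f"replicate {replicate.id!r} has no library")
        biosample_id = self.get(library_id).get("biosample")
        if biosample_id is None:
            raise StoreError(f"library {library_id!r} has no biosample")
        donor_id = self.get(biosample_id).get("donor")
        if donor_id is None:
            raise StoreError(f"biosample {biosample_id!r} has no donor")
        self.get(donor_id)
        return biosample_id, donor_id

    def classify_replicates(self, experiment_id: str) -> dict[tuple, str]:
        """Pairwise replicate relationship for one experiment.

        Symmetric by construction: keys are id-sorted pairs.
        """
        replicates = sorted(self.replicates_of(experiment_id), key=lambda r: r.id)
        chains = {r.id: self._biosample_and_donor(r) for r in replicates}
        out: dict[tuple, str] = {}
        for i, first in enumerate(replicates):
            for second in replicates[i + 1 :]:
                bio1, donor1 = chains[first.id]
                bio2, donor2 = chains[second.id]
                if bio1 == bio2:
                    kind = TECHNICAL
                elif donor1 == donor2:
                    kind = ISOGENIC
                else:
                    kind = ANISOGENIC
                out[(first.id, second.id)] = kind
        return out

    # -- file provenance ---------------------------------------------------

    def _provenance_graph(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        for record in self.records("file"):
            graph.add_node(record.id)
            for parent_id in record.get("derived_from", []):
                graph.add_edge(record.id, parent_id)
        return graph

    def _find_provenance_cycle(self) -> Optional[list[str]]:
        graph = self._provenance_graph()
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            return None
        return [edge[0] for edge in cycle]

    def provenance_chain(self, file_id: str) -> list[str]:
        """All transitive ``derived_from`` ancestors, nearest first.

        Ordering is by longest derivation distance from the file (then id),
        which is a valid topological order on a DAG: an input always appears
        after every file computed from it. Raw files return ``[]``.
        """
        record = self.get(file_id)
        if record.type_name != "file":
            raise StoreError(f"{file_id!r} is a {record.type_name}, not a file")
        graph = self._provenance_graph()
        distance: dict[str, int] = {}
        on_path: set[str] = set()

        def longest(node: str, trail: list[str]) -> int:
            if node in on_path:
                cycle_start = trail.index(node)
                raise ProvenanceCycleError(trail[cycle_start:] + [node])
            if node in distance:
                return distance[node]
            on_path.add(node)
            best = 0
            for parent in graph.successors(node):
                best = max(best, 1 + longest(parent, trail + [node]))
            on_path.discard(node)
            distance[node] = best
            return best

        longest(file_id, [])
        ancestors = nx.descendants(graph, file_id)  # reachable along derived_from
        return sorted(ancestors, key=lambda n: (distance[file_id] - distance[n], n))

    # -- embedding ---------------------------------------------------------

    def embed_object(self, record_id: str, depth: int = DEFAULT_EMBED_DEPTH) -> dict:
        """Expand link fields into nested documents up to ``depth`` levels.

        Pure function of (store, id, depth). Links beyond the depth, to
        unknown ids, or back to any record already on the current embedding
        path remain bare ids, so cyclic references terminate.
        """

        def _embed(oid: str, remaining: int, path: frozenset) -> dict:
            record = self.get(oid)
            schema = self.registry.get(record.type_name)
            targets = schema.link_targets()
            doc: dict[str, Any] = {ID_KEY: oid, "type": record.type_name}
            for name in sorted(record.properties):
                value = record.properties[name]
                if name in targets and remaining > 0:
                    def expand(one):
                        if (
                            isinstance(one, str)
                            and one in self._records
                            and one not in path
                        ):
                            return _embed(one, remaining - 1, path | {oid})
                        return one
                    if isinstance(value, list):
                        doc[name] = [expand(v) for v in value]
                    else:
                        doc[name] = expand(value)
                else:
                    doc[name] = copy.deepcopy(value)
            return doc

        return _embed(record_id, depth, frozenset())

    # -- serialization -----------------------------------------------------

    def to_json_doc(self) -> dict:
        """Single-document dialect: type_name -> list of records."""
        doc: dict[str, list] = {}
        for record in self.records():
            doc.setdefault(record.type_name, []).append(record.to_json_dict())
        return {k: doc[k] for k in sorted(doc)}

    def save(self, path: str | Path) -> None:
        """Write either one JSON document (file path) or per-type files (dir)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(
                json.dumps(self.to_json_doc(), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
        else:
            path.mkdir(parents=True, exist_ok=True)
            for type_name, records in self.to_json_doc().items():
                (path / f"{type_name}.json").write_text(
                    json.dumps(records, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8",
                )

    @classmethod
    def from_json_doc(
        cls, doc: dict, registry: Optional[SchemaRegistry] = None, *, validate: bool = True
    ) -> "MetadataStore":
        store = cls(registry)
        for type_name in sorted(doc):
            for raw in doc[type_name]:
                raw = dict(raw)
                record_id = raw.pop(ID_KEY, None)
                if record_id is None:
                    raise StoreError(f"a {type_name} record lacks an {ID_KEY!r}")
                store.add_object(
                    MetadataObject(record_id, type_name, raw), validate=validate
                )
        return store

    @classmethod
    def load(
        cls,
        path: str | Path,
        registry: Optional[SchemaRegistry] = None,
        *,
        validate: bool = True,
        finalize: bool = False,
        complete_pairs: bool = True,
    ) -> "MetadataStore":
        """Read a store from a single JSON document or a per-type directory."""
        path = Path(path)
        if path.is_dir():
            doc = {}
            for type_file in sorted(path.glob("*.json")):
                doc[type_file.stem] = json.loads(type_file.read_text(encoding="utf-8"))
        else:
            doc = json.loads(path.read_text(encoding="utf-8"))
        store = cls.from_json_doc(doc, registry, validate=validate)
        if finalize:
            store.finalize(complete_pairs=complete_pairs)
        return store

    def copy(self) -> "MetadataStore":
        clone = MetadataStore(self.registry)
        for record in self.records():
            clone.add_object(
                MetadataObject(record.id, record.type_name, copy.deepcopy(record.properties)),
                validate=False,
            )
        clone.finalized = self.finalized
        return clone
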