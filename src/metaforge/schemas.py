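"""Schema documents and record validation.

Each record type (biosample, file, experiment, ...) is described by a schema
document: a JSON object declaring typed properties, required fields,
enumerated lists, regular-expression patterns, link targets and conditional
dependencies. The validator implements a deliberately small, closed set of
keywords and rejects anything it does not know — for a curated metadata
standard, silently ignoring an unknown keyword is how typos become policy.

Two dependency forms are supported, mirroring how submission rules are
written in practice:

* presence-triggered — "if ``paired_with`` is submitted, ``run_type`` must
  be too";
* value-triggered — "if ``run_type`` is ``paired-ended``, the paired file
  must be listed".

A rule may also forbid fields when it fires (e.g. a DNA library declaring
RNA spike-ins). Patterns are anchored full-matches: a partial match would
quietly accept malformed identifiers.

Validation is pure and reports *all* problems rather than raising on the
first; partial records are legal — only ``required`` and fired dependencies
force presence.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional

from .errors import SchemaError, TypeMismatchError

PROPERTY_KINDS = {"text", "integer", "number", "boolean", "list", "link", "document-ref"}

#: record-level lifecycle states (a project choice; the standard needs *a*
#: closed list, and deletion is a status, never physical removal)
STATUS_VALUES = ["in progress", "released", "replaced", "deleted"]

#: reserved key carrying record identity in serialized form; not a property
ID_KEY = "id"

_KNOWN_SCHEMA_KEYS = {
    "type_name",
    "schema_version",
    "properties",
    "required",
    "dependencies",
    "identifying_fields",
    "description",
}
_KNOWN_PROPERTY_KEYS = {"kind", "enum", "pattern", "link_to", "items", "description"}
_KNOWN_DEPENDENCY_KEYS = {"trigger_values", "required_fields", "forbidden_fields"}


@dataclass(frozen=True)
class PropertySpec:
    """Declaration of a single record field."""

    name: str
    kind: str
    enum: Optional[tuple] = None
    pattern: Optional[str] = None
    link_to: Optional[str] = None
    items: Optional["PropertySpec"] = None
    description: str = ""

    def __post_init__(self):
        if self.kind not in PROPERTY_KINDS:
            raise SchemaError(f"property {self.name!r}: unknown kind {self.kind!r}")
        if self.enum is not None:
            if self.kind != "text":
                raise SchemaError(f"property {self.name!r}: enum only valid for text kind")
            if len(self.enum) == 0:
                raise SchemaError(f"property {self.name!r}: enumerated list is empty")
            if len(set(self.enum)) != len(self.enum):
                raise SchemaError(f"property {self.name!r}: enumerated list has duplicates")
        if self.pattern is not None and self.kind != "text":
            raise SchemaError(f"property {self.name!r}: pattern only valid for text kind")
        if (self.link_to is not None) != (self.kind == "link"):
            raise SchemaError(f"property {self.name!r}: link_to present iff kind is link")
        if self.items is not None and self.kind != "list":
            raise SchemaError(f"property {self.name!r}: items only valid for list kind")


@dataclass(frozen=True)
class DependencyRule:
    """Conditional rule: when the trigger fires, some fields become required
    and others forbidden. Empty ``trigger_values`` means mere presence of the
    trigger field fires the rule."""

    trigger_field: str
    trigger_values: frozenset = frozenset()
    required_fields: tuple = ()
    forbidden_fields: tuple = ()

    def __post_init__(self):
        overlap = set(self.required_fields) & set(self.forbidden_fields)
        if overlap:
            raise SchemaError(
                f"dependency on {self.trigger_field!r}: fields {sorted(overlap)} "
                "both required and forbidden"
            )

    def fires(self, record: Mapping[str, Any]) -> bool:
        if self.trigger_field not in record:
            return False
        if not self.trigger_values:
            return True
        return record[self.trigger_field] in self.trigger_values


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str  # missing-required | enum | pattern | type | dependency-required
    #        | dependency-forbidden | bad-link-type | unknown-field
    message: str

    def as_tuple(self) -> tuple:
        return (self.field, self.rule, self.message)


@dataclass
class ValidationReport:
    record_id: str
    violations: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


@dataclass
class SchemaDoc:
    """Parsed schema for one record type."""

    type_name: str
    properties: dict[str, PropertySpec]
    required: tuple = ()
    dependencies: dict[str, tuple] = field(default_factory=dict)  # field -> rules
    identifying_fields: tuple = ()
    schema_version: int = 1
    description: str = ""

    def __post_init__(self):
        for name in self.required:
            if name not in self.properties:
                raise SchemaError(f"{self.type_name}: required field {name!r} not in properties")
        for name in self.identifying_fields:
            if name not in self.properties:
                raise SchemaError(
                    f"{self.type_name}: identifying field {name!r} not in properties"
                )
        for trigger, rules in self.dependencies.items():
            if trigger not in self.properties:
                raise SchemaError(
                    f"{self.type_name}: dependency trigger {trigger!r} not in properties"
                )
            for rule in rules:
                for name in (*rule.required_fields, *rule.forbidden_fields):
                    if name not in self.properties:
                        raise SchemaError(
                            f"{self.type_name}: dependency on {trigger!r} names "
                            f"unknown field {name!r}"
                        )

    def link_targets(self) -> dict[str, str]:
        """field -> target type for every link-valued field (incl. link lists)."""
        targets = {}
        for name, spec in self.properties.items():
            if spec.kind == "link":
                targets[name] = spec.link_to
            elif spec.kind == "list" and spec.items is not None and spec.items.kind == "link":
                targets[name] = spec.items.link_to
        return targets


def _parse_property(name: str, raw: Mapping[str, Any]) -> PropertySpec:
    unknown = set(raw) - _KNOWN_PROPERTY_KEYS
    if unknown:
        raise SchemaError(f"property {name!r}: unknown schema keyword(s) {sorted(unknown)}")
    if "kind" not in raw:
        raise SchemaError(f"property {name!r}: missing kind")
    items = None
    if "items" in raw:
        items = _parse_property(f"{name}[]", raw["items"])
    return PropertySpec(
        name=name,
        kind=raw["kind"],
        enum=tuple(raw["enum"]) if "enum" in raw else None,
        pattern=raw.get("pattern"),
        link_to=raw.get("link_to"),
        items=items,
        description=raw.get("description", ""),
    )


def load_schema(schema_text: str) -> SchemaDoc:
    """Parse one schema document from JSON text, enforcing all invariants."""
    try:
        raw = json.loads(schema_text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"schema does not parse as JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError("schema must be a JSON object")
    unknown = set(raw) - _KNOWN_SCHEMA_KEYS
    if unknown:
        raise SchemaError(f"unknown schema keyword(s) {sorted(unknown)}")
    if "type_name" not in raw:
        raise SchemaError("schema missing type_name")
    properties = {
        name: _parse_property(name, spec) for name, spec in raw.get("properties", {}).items()
    }
    dependencies: dict[str, tuple] = {}
    for trigger, rule_raw in raw.get("dependencies", {}).items():
        rule_list = rule_raw if isinstance(rule_raw, list) else [rule_raw]
        rules = []
        for one in rule_list:
            unknown = set(one) - _KNOWN_DEPENDENCY_KEYS
            if unknown:
                raise SchemaError(
                    f"dependency on {trigger!r}: unknown keyword(s) {sorted(unknown)}"
                )
            rules.append(
                DependencyRule(
                    trigger_field=trigger,
                    trigger_values=frozenset(one.get("trigger_values", [])),
                    required_fields=tuple(one.get("required_fields", [])),
                    forbidden_fields=tuple(one.get("forbidden_fields", [])),
                )
            )
        dependencies[trigger] = tuple(rules)
    return SchemaDoc(
        type_name=raw["type_name"],
        properties=properties,
        required=tuple(raw.get("required", [])),
        dependencies=dependencies,
        identifying_fields=tuple(raw.get("identifying_fields", [])),
        schema_version=int(raw.get("schema_version", 1)),
        description=raw.get("description", ""),
    )


def _check_scalar(spec: PropertySpec, value: Any, field_name: str) -> list[Violation]:
    out = []
    if spec.kind == "text":
        if not isinstance(value, str):
            out.append(Violation(field_name, "type", f"expected text, got {type(value).__name__}"))
            return out
        if spec.enum is not None and value not in spec.enum:
            out.append(
                Violation(
                    field_name,
                    "enum",
                    f"value {value!r} not in enumerated list {list(spec.enum)}",
                )
            )
        if spec.pattern is not None and not re.fullmatch(spec.pattern, value):
            out.append(
                Violation(field_name, "pattern", f"value {value!r} does not match /{spec.pattern}/")
            )
    elif spec.kind == "integer":
        if not isinstance(value, int) or isinstance(value, bool):
            out.append(Violation(field_name, "type", f"expected integer, got {value!r}"))
    elif spec.kind == "number":
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            out.append(Violation(field_name, "type", f"expected number, got {value!r}"))
    elif spec.kind == "boolean":
        if not isinstance(value, bool):
            out.append(Violation(field_name, "type", f"expected boolean, got {value!r}"))
    elif spec.kind in ("link", "document-ref"):
        if not isinstance(value, str) or not value:
            out.append(Violation(field_name, "type", f"expected an id, got {value!r}"))
    return out


def validate_record(
    schema: SchemaDoc,
    record: Mapping[str, Any],
    *,
    record_id: str = "",
    type_name: Optional[str] = None,
    store: Optional[Any] = None,
    strict_unknown: bool = True,
) -> ValidationReport:
    """Validate a record's property mapping against its schema.

    Pure: neither the record nor any store is mutated, and the report is a
    deterministic function of (schema, record). When ``store`` (anything with
    a ``get_type(id) -> type_name or None``) is supplied, link values resolving
    to a record of the wrong type are flagged as ``bad-link-type``; dangling
    links are a store-finalization concern, not a validation one. Unknown
    fields are violations in strict mode, warnings otherwise.
    """
    if type_name is not None and type_name != schema.type_name:
        raise TypeMismatchError(
            f"record of type {type_name!r} validated against schema {schema.type_name!r}"
        )
    report = ValidationReport(record_id=record_id or str(record.get(ID_KEY, "")))
    fields = {k: v for k, v in record.items() if k != ID_KEY}

    for name in schema.required:
        if name not in fields:
            report.violations.append(
                Violation(name, "missing-required", f"required field {name!r} is missing")
            )

    for name, value in sorted(fields.items()):
        spec = schema.properties.get(name)
        if spec is None:
            v = Violation(name, "unknown-field", f"field {name!r} not declared in schema")
            (report.violations if strict_unknown else report.warnings).append(v)
            continue
        if spec.kind == "list":
            if not isinstance(value, list):
                report.violations.append(
                    Violation(name, "type", f"expected list, got {type(value).__name__}")
                )
                continue
            if spec.items is not None:
                for i, item in enumerate(value):
                    report.violations.extend(_check_scalar(spec.items, item, f"{name}[{i}]"))
        else:
            report.violations.extend(_check_scalar(spec, value, name))

    for trigger in sorted(schema.dependencies):
        for rule in schema.dependencies[trigger]:
            if not rule.fires(fields):
                continue
            for name in rule.required_fields:
                if name not in fields:
                    report.violations.append(
                        Violation(
                            name,
                            "dependency-required",
                            f"{trigger!r}={fields.get(trigger)!r} requires {name!r}",
                        )
                    )
            for name in rule.forbidden_fields:
                if name in fields:
                    report.violations.append(
                        Violation(
                            name,
                            "dependency-forbidden",
                            f"{trigger!r}={fields.get(trigger)!r} forbids {name!r}",
                        )
                    )

    if store is not None:
        for name, target_type in sorted(schema.link_targets().items()):
            if name not in fields:
                continue
            values = fields[name] if isinstance(fields[name], list) else [fields[name]]
            for value in values:
                if not isinstance(value, str):
                    continue
                actual = store.get_type(value)
                if actual is not None and actual != target_type:
                    report.violations.append(
                        Violation(
                            name,
                            "bad-link-type",
                            f"{value!r} is a {actual}, expected {target_type}",
                        )
                    )
    return report


class SchemaRegistry:
    """All schemas of one metadata standard, keyed by type name.

    Duplicate registrations are rejected; link-target closure (every
    ``link_to`` naming a registered type) is checked once all schemas are in,
    via :meth:`check_links` — called implicitly by :func:`load_schema_dir`.
    """

    def __init__(self):
        self._schemas: dict[str, SchemaDoc] = {}

    def register(self, schema: SchemaDoc) -> None:
        if schema.type_name in self._schemas:
            raise SchemaError(f"duplicate schema for type {schema.type_name!r}")
        self._schemas[schema.type_name] = schema

    def get(self, type_name: str) -> SchemaDoc:
        if type_name not in self._schemas:
            raise SchemaError(f"no schema registered for type {type_name!r}")
        return self._schemas[type_name]

    def __contains__(self, type_name: str) -> bool:
        return type_name in self._schemas

    def type_names(self) -> list[str]:
        return sorted(self._schemas)

    def check_links(self) -> None:
        for schema in self._schemas.values():
            for fname, target in schema.link_targets().items():
                if target not in self._schemas:
                    raise SchemaError(
                        f"{schema.type_name}.{fname}: link target {target!r} "
                        "is not a registered type"
                    )

    def validate(self, type_name: str, record: Mapping[str, Any], **kwargs) -> ValidationReport:
        return validate_record(self.get(type_name), record, type_name=type_name, **kwargs)


def load_schema_dir(path: str | Path) -> SchemaRegistry:
    """Load every ``*.json`` schema in a directory into a checked registry."""
    registry = SchemaRegistry()
    for schema_file in sorted(Path(path).glob("*.json")):
        registry.register(load_schema(schema_file.read_text(encoding="utf-8")))
    registry.check_links()
    return registry


def builtin_registry() -> SchemaRegistry:
    """The schema set shipped with the package (13 record types)."""
    registry = SchemaRegistry()
    root = resources.files("metaforge").joinpath("data/schemas")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".json"):
            registry.register(load_schema(entry.read_text(encoding="utf-8")))
    registry.check_links()
    return registry


def iter_violation_rows(reports: Iterable[ValidationReport]):
    """Flatten reports to (record_id, field, rule, message) rows for TSV."""
    for report in reports:
        for violation in report.violations:
            yield (report.record_id, violation.field, violation.rule, violation.message)
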