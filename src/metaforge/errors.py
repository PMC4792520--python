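"""Exception hierarchy for metaforge.

Every error raised by the package derives from :class:`MetaforgeError`, so
callers (including the CLI) can distinguish metadata problems from bugs.
"""


class MetaforgeError(Exception):
    """Base class for all metaforge errors."""


class SchemaError(MetaforgeError):
    """A schema document violates the schema-language invariants."""


class TypeMismatchError(MetaforgeError):
    """Record type does not match the schema it was validated against."""


class MalformedAccessionError(MetaforgeError):
    """Accession text does not conform to the accession grammar."""

    def __init__(self, text: str, constraint: str, message: str):
        self.text = text
        #: first failing constraint, one of: length, case, prefix,
        #: type-code, digits, letters
        self.constraint = constraint
        super().__init__(f"{text!r}: {message} [{constraint}]")


class AccessionExhaustedError(MetaforgeError):
    """All serials of a type code have been issued."""


class SupersessionError(MetaforgeError):
    """Invalid file supersession (non-file, self-reference or cycle)."""


class StoreError(MetaforgeError):
    """Object-store level problem (duplicate id, unknown id, ...)."""


class IntegrityError(StoreError):
    """Finalize found dangling or mistyped links."""

    def __init__(self, findings):
        self.findings = list(findings)
        lines = "; ".join(str(f) for f in self.findings[:5])
        super().__init__(f"{len(self.findings)} referential-integrity finding(s): {lines}")


class ProvenanceCycleError(StoreError):
    """derived_from edges contain a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("provenance cycle: " + " -> ".join(self.cycle))


class OntologyError(MetaforgeError):
    """Problem loading or querying an ontology bundle."""


class AuditError(MetaforgeError):
    """Unknown audit rule or malformed ruleset selection."""


class ExportError(MetaforgeError):
    """Experiment cannot be exported (e.g. has no replicates)."""


class SearchError(MetaforgeError):
    """Unknown facet field or malformed search configuration."""


class InfeasiblePlanError(MetaforgeError):
    """A fixture violation plan cannot be realised on the given store."""
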