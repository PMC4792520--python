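"""Schema loading invariants and record validation semantics."""

import itertools
import json

import pytest
from hypothesis import given, settings, strategies as st

from metaforge.errors import SchemaError, TypeMismatchError
from metaforge.schemas import (
    DependencyRule,
    SchemaRegistry,
    builtin_registry,
    load_schema,
    validate_record,
)

REGISTRY = builtin_registry()
FILE_SCHEMA = REGISTRY.get("file")


def make_file_record(**overrides):
    record = {
        "file_format": "fastq",
        "output_type": "reads",
        "dataset": "ENCSR000AAA",
        "md5sum": "0" * 32,
        "run_type": "single-ended",
    }
    record.update(overrides)
    return {k: v for k, v in record.items() if v is not None}


class TestSchemaLoading:
    def test_builtin_set_covers_all_record_types(self):
        assert REGISTRY.type_names() == sorted(
            [
                "award", "lab", "document", "donor", "treatment", "biosample",
                "library", "antibody_lot", "experiment", "replicate", "file",
                "software", "pipeline",
            ]
        )

    def test_file_schema_declares_the_paired_end_dependency(self):
        rules = FILE_SCHEMA.dependencies["run_type"]
        assert any(
            "paired-ended" in rule.trigger_values
            and "paired_with" in rule.required_fields
            for rule in rules
        )

    def test_empty_enum_rejected(self):
        text = json.dumps(
            {"type_name": "t", "properties": {"x": {"kind": "text", "enum": []}}}
        )
        with pytest.raises(SchemaError, match="empty"):
            load_schema(text)

    def test_duplicate_enum_values_rejected(self):
        text = json.dumps(
            {"type_name": "t", "properties": {"x": {"kind": "text", "enum": ["a", "a"]}}}
        )
        with pytest.raises(SchemaError, match="duplicate"):
            load_schema(text)

    def test_dependency_on_unknown_field_rejected(self):
        text = json.dumps(
            {
                "type_name": "t",
                "properties": {"x": {"kind": "text"}},
                "dependencies": {"x": {"required_fields": ["ghost"]}},
            }
        )
        with pytest.raises(SchemaError, match="ghost"):
            load_schema(text)

    def test_unknown_schema_keyword_rejected_loudly(self):
        with pytest.raises(SchemaError, match="unknown"):
            load_schema(json.dumps({"type_name": "t", "additionalProperties": False}))
        with pytest.raises(SchemaError, match="unknown"):
            load_schema(
                json.dumps(
                    {"type_name": "t", "properties": {"x": {"kind": "text", "format": "uri"}}}
                )
            )

    def test_link_to_only_with_link_kind(self):
        with pytest.raises(SchemaError):
            load_schema(
                json.dumps(
                    {"type_name": "t", "properties": {"x": {"kind": "text", "link_to": "lab"}}}
                )
            )

    def test_duplicate_type_name_rejected_by_registry(self):
        registry = SchemaRegistry()
        schema = load_schema(json.dumps({"type_name": "t", "properties": {}}))
        registry.register(schema)
        with pytest.raises(SchemaError, match="duplicate"):
            registry.register(schema)

    def test_unregistered_link_target_rejected(self):
        registry = SchemaRegistry()
        registry.register(
            load_schema(
                json.dumps(
                    {"type_name": "t", "properties": {"x": {"kind": "link", "link_to": "ghost"}}}
                )
            )
        )
        with pytest.raises(SchemaError, match="ghost"):
            registry.check_links()

    def test_required_and_forbidden_must_be_disjoint(self):
        with pytest.raises(SchemaError):
            DependencyRule("x", frozenset(), ("y",), ("y",))


class TestRecordValidation:
    def test_paired_ended_without_pair_flags_dependency(self):
        report = validate_record(
            FILE_SCHEMA, make_file_record(run_type="paired-ended")
        )
        assert [(v.field, v.rule) for v in report.violations] == [
            ("paired_with", "dependency-required")
        ]

    def test_single_ended_without_pair_is_clean(self):
        report = validate_record(FILE_SCHEMA, make_file_record(run_type="single-ended"))
        assert report.valid

    def test_value_outside_enumerated_list_flags_enum(self):
        report = validate_record(
            FILE_SCHEMA, make_file_record(status="relesed")  # the typo enums prevent
        )
        assert [(v.field, v.rule) for v in report.violations] == [("status", "enum")]

    def test_missing_optional_field_is_allowed(self):
        # a partial record: no status, no replicate, no derived_from
        report = validate_record(FILE_SCHEMA, make_file_record())
        assert report.valid

    def test_missing_required_field_flagged(self):
        record = make_file_record()
        del record["md5sum"]
        report = validate_record(FILE_SCHEMA, record)
        assert ("md5sum", "missing-required") in [
            (v.field, v.rule) for v in report.violations
        ]

    def test_pattern_is_anchored_full_match(self):
        report = validate_record(
            FILE_SCHEMA, make_file_record(md5sum="deadbeef")  # too short
        )
        assert [(v.field, v.rule) for v in report.violations] == [("md5sum", "pattern")]
        report = validate_record(
            FILE_SCHEMA, make_file_record(md5sum="0" * 32 + "tail")
        )
        assert not report.valid

    def test_unknown_field_strict_vs_lenient(self):
        record = make_file_record(undeclared="x")
        strict = validate_record(FILE_SCHEMA, record)
        assert [(v.field, v.rule) for v in strict.violations] == [
            ("undeclared", "unknown-field")
        ]
        lenient = validate_record(FILE_SCHEMA, record, strict_unknown=False)
        assert lenient.valid
        assert [v.field for v in lenient.warnings] == ["undeclared"]

    def test_type_mismatch_between_schema_and_record_raises(self):
        with pytest.raises(TypeMismatchError):
            validate_record(FILE_SCHEMA, {}, type_name="biosample")

    def test_validation_is_order_independent(self):
        record = make_file_record(status="released", replicate="rep-1")
        reversed_record = dict(reversed(list(record.items())))
        first = validate_record(FILE_SCHEMA, record)
        second = validate_record(FILE_SCHEMA, reversed_record)
        assert [v.as_tuple() for v in first.violations] == [
            v.as_tuple() for v in second.violations
        ]

    def test_round_trip_stability_of_valid_records(self):
        record = make_file_record(status="released")
        assert validate_record(FILE_SCHEMA, record).valid
        reloaded = json.loads(json.dumps(record))
        assert validate_record(FILE_SCHEMA, reloaded).valid

    def test_list_items_validated(self):
        report = validate_record(
            REGISTRY.get("library"),
            {"biosample": "ENCBS000AAA", "nucleic_acid_term_name": "RNA",
             "spikeins_used": ["ERCC-mix1", 7]},
        )
        assert [(v.field, v.rule) for v in report.violations] == [
            ("spikeins_used[1]", "type")
        ]

    def test_dependency_forbidden_fires(self):
        report = validate_record(
            REGISTRY.get("library"),
            {"biosample": "ENCBS000AAA", "nucleic_acid_term_name": "DNA",
             "spikeins_used": ["ERCC-mix1"]},
        )
        assert [(v.field, v.rule) for v in report.violations] == [
            ("spikeins_used", "dependency-forbidden")
        ]


# --- exhaustive dependency semantics against a brute-force oracle ----------


def oracle_dependency_flags(rules, record):
    """Independent evaluation of dependency semantics on a plain dict."""
    flags = set()
    for rule in rules:
        fires = rule.trigger_field in record and (
            not rule.trigger_values or record[rule.trigger_field] in rule.trigger_values
        )
        if not fires:
            continue
        for name in rule.required_fields:
            if name not in record:
                flags.add((name, "dependency-required"))
        for name in rule.forbidden_fields:
            if name in record:
                flags.add((name, "dependency-forbidden"))
    return flags


DEP_SCHEMA = load_schema(
    json.dumps(
        {
            "type_name": "t",
            "properties": {name: {"kind": "text"} for name in "abcd"},
            "dependencies": {
                "a": {"trigger_values": ["on"], "required_fields": ["b"],
                      "forbidden_fields": ["c"]},
                "b": {"required_fields": ["d"]},
                "c": [{"trigger_values": ["x"], "required_fields": ["a"]},
                      {"trigger_values": ["y"], "forbidden_fields": ["d"]}],
            },
        }
    )
)


@pytest.mark.parametrize("values", list(itertools.product(["on", "off"], ["x", "y"])))
def test_dependency_flags_match_oracle_over_all_presence_patterns(values):
    a_value, c_value = values
    rules = [rule for rules in DEP_SCHEMA.dependencies.values() for rule in rules]
    for present in itertools.chain.from_iterable(
        itertools.combinations("abcd", k) for k in range(5)
    ):
        record = {}
        if "a" in present:
            record["a"] = a_value
        if "b" in present:
            record["b"] = "any"
        if "c" in present:
            record["c"] = c_value
        if "d" in present:
            record["d"] = "any"
        report = validate_record(DEP_SCHEMA, record)
        got = {
            (v.field, v.rule)
            for v in report.violations
            if v.rule.startswith("dependency")
        }
        assert got == oracle_dependency_flags(rules, record), record


@settings(max_examples=50, derandomize=True)
@given(
    run_type=st.sampled_from(["single-ended", "paired-ended", None]),
    paired=st.booleans(),
)
def test_paired_end_dependency_matches_oracle(run_type, paired):
    record = make_file_record(run_type=run_type)
    if paired:
        record["paired_with"] = "ENCFF000AAA"
    rules = [r for rs in FILE_SCHEMA.dependencies.values() for r in rs]
    got = {
        (v.field, v.rule)
        for v in validate_record(FILE_SCHEMA, record).violations
        if v.rule.startswith("dependency")
    }
    assert got == oracle_dependency_flags(rules, record)
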