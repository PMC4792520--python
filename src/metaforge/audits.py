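"""Post-submission consistency audits over a finalized store.

Schema validation catches per-record problems at submission time; audits
catch cross-record inconsistencies afterwards, before release. Each rule is
a pure predicate over the store, registered as data so downstream projects
can extend the ruleset without touching the engine.

Built-in rules
--------------

====  ============  ===========================================================
id    severity      inconsistency detected
====  ============  ===========================================================
R1    not-compliant ChIP-seq replicate lacking an antibody-lot link
R2    not-compliant ChIP-seq experiment lacking a control-experiment link
R3    warning       RNA-seq library lacking a spike-in declaration
R4    error         paired-ended file with missing or one-sided pairing
R5    error         technical replicates whose libraries disagree on biosample
R6    error         file not linked to a replicate of its experiment
R7    error         replicate lacking a library link
====  ============  ===========================================================

Assay applicability keys off the experiment's OBI assay term, not free text.
Experiments that declare a ``control_type`` are themselves controls: they
carry no antibody and need no control, so R1/R2 skip them. Severities are a
project choice: antibody and control omissions are submission-standard
breaches (not-compliant), missing spike-ins degrade calibration (warning),
and the structural rules R4–R7 are outright errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .errors import AuditError
from .store import MetadataStore

CHIP_SEQ_TERM = "OBI:0000716"
RNA_SEQ_TERM = "OBI:0001271"

SEVERITIES = ("error", "not-compliant", "warning", "internal")


@dataclass(frozen=True)
class AuditFlag:
    record_id: str
    rule_id: str
    severity: str
    message: str

    def as_tuple(self) -> tuple:
        return (self.record_id, self.rule_id, self.severity, self.message)


@dataclass(frozen=True)
class AuditRule:
    rule_id: str
    applies_to: str
    severity: str
    description: str
    #: pure function store -> iterable of (record_id, message)
    check: Callable[[MetadataStore], Iterable[tuple]]

    def run(self, store: MetadataStore) -> list[AuditFlag]:
        return [
            AuditFlag(record_id, self.rule_id, self.severity, message)
            for record_id, message in self.check(store)
        ]


def _experiments(store: MetadataStore, assay_term: Optional[str] = None, controls=False):
    for experiment in store.records("experiment"):
        if experiment.deleted:
            continue
        if assay_term is not None and experiment.get("assay_term") != assay_term:
            continue
        if not controls and experiment.get("control_type") is not None:
            continue
        yield experiment


def _check_chip_antibody(store: MetadataStore):
    for experiment in _experiments(store, CHIP_SEQ_TERM):
        for replicate in store.replicates_of(experiment.id):
            if replicate.get("antibody") is None:
                yield (
                    replicate.id,
                    f"ChIP-seq replicate in {experiment.id} has no antibody link",
                )


def _check_chip_control(store: MetadataStore):
    for experiment in _experiments(store, CHIP_SEQ_TERM):
        if not experiment.get("possible_controls"):
            yield (
                experiment.id,
                "ChIP-seq experiment lists no control experiment (possible_controls)",
            )


def _check_rnaseq_spikeins(store: MetadataStore):
    flagged = set()
    for experiment in _experiments(store, RNA_SEQ_TERM, controls=True):
        for replicate in store.replicates_of(experiment.id):
            library_id = replicate.get("library")
            if library_id is None or library_id not in store or library_id in flagged:
                continue
            if not store.get(library_id).get("spikeins_used"):
                flagged.add(library_id)
                yield (
                    library_id,
                    f"RNA-seq library (experiment {experiment.id}) declares no spike-ins",
                )


def _check_paired_files(store: MetadataStore):
    for record in store.records("file"):
        if record.deleted:
            continue
        partner_id = record.get("paired_with")
        if record.get("run_type") == "paired-ended" and partner_id is None:
            yield (record.id, "paired-ended file lists no paired_with file")
            continue
        if partner_id is None:
            continue
        if partner_id not in store:
            yield (record.id, f"paired_with target {partner_id!r} does not exist")
        elif store.get(partner_id).get("paired_with") != record.id:
            yield (
                record.id,
                f"one-sided pairing: {partner_id} does not name {record.id} back",
            )


def _check_technical_biosample(store: MetadataStore):
    for experiment in _experiments(store, controls=True):
        groups: dict[int, list] = {}
        for replicate in store.replicates_of(experiment.id):
            groups.setdefault(replicate.get("biological_replicate_number"), []).append(replicate)
        for bio_number, members in sorted(groups.items(), key=lambda kv: (kv[0] is None, kv[0])):
            if len(members) < 2:
                continue
            biosamples = set()
            for replicate in members:
                library_id = replicate.get("library")
                if library_id is None or library_id not in store:
                    continue  # R7's problem, not R5's
                biosamples.add(store.get(library_id).get("biosample"))
            if len(biosamples) > 1:
                yield (
                    experiment.id,
                    f"technical replicates (biological number {bio_number}) use "
                    f"different biosamples {sorted(map(str, biosamples))}",
                )


def _check_file_replicate(store: MetadataStore):
    for record in store.records("file"):
        if record.deleted:
            continue
        replicate_id = record.get("replicate")
        if replicate_id is None:
            yield (record.id, "file is linked to no replicate of its experiment")
        elif (
            replicate_id in store
            and store.get(replicate_id).get("experiment") != record.get("dataset")
        ):
            yield (
                record.id,
                f"file's replicate {replicate_id} belongs to a different experiment",
            )


def _check_replicate_library(store: MetadataStore):
    for replicate in store.records("replicate"):
        if not replicate.deleted and replicate.get("library") is None:
            yield (replicate.id, "replicate has no library link")


BUILTIN_RULES: dict[str, AuditRule] = {
    rule.rule_id: rule
    for rule in [
        AuditRule("R1", "replicate", "not-compliant",
                  "ChIP-seq replicates must link the antibody lot used",
                  _check_chip_antibody),
        AuditRule("R2", "experiment", "not-compliant",
                  "ChIP-seq experiments must list a control experiment",
                  _check_chip_control),
        AuditRule("R3", "library", "warning",
                  "RNA-seq libraries should declare their spike-ins",
                  _check_rnaseq_spikeins),
        AuditRule("R4", "file", "error",
                  "paired-ended files must name their pair, symmetrically",
                  _check_paired_files),
        AuditRule("R5", "experiment", "error",
                  "technical replicates must share a biosample",
                  _check_technical_biosample),
        AuditRule("R6", "file", "error",
                  "files must link a replicate of their experiment",
                  _check_file_replicate),
        AuditRule("R7", "replicate", "error",
                  "replicates must link a library",
                  _check_replicate_library),
    ]
}


def run_audits(
    store: MetadataStore,
    rules: Optional[Iterable[str]] = None,
    ruleset: Optional[dict] = None,
) -> list[AuditFlag]:
    """Run the (selected) ruleset; flags sorted by (record_id, rule_id)."""
    ruleset = BUILTIN_RULES if ruleset is None else ruleset
    if rules is None:
        selected = [ruleset[rule_id] for rule_id in sorted(ruleset)]
    else:
        selected = []
        for rule_id in rules:
            if rule_id not in ruleset:
                raise AuditError(f"unknown audit rule {rule_id!r}")
            selected.append(ruleset[rule_id])
    flags = [flag for rule in selected for flag in rule.run(store)]
    return sorted(flags, key=lambda f: (f.record_id, f.rule_id))


def render_report(flags: Iterable[AuditFlag], format: str = "tsv") -> str:
    """Render flags as TSV (one line per flag) or a severity-grouped text."""
    flags = sorted(flags, key=lambda f: (f.record_id, f.rule_id))
    if format == "tsv":
        lines = ["record_id\trule_id\tseverity\tmessage"]
        lines += ["\t".join(flag.as_tuple()) for flag in flags]
        return "\n".join(lines) + "\n"
    if format == "text":
        lines = []
        for severity in SEVERITIES:
            group = [f for f in flags if f.severity == severity]
            if not group:
                continue
            lines.append(f"{severity} ({len(group)}):")
            lines += [f"  {f.record_id}  {f.rule_id}  {f.message}" for f in group]
        if not lines:
            lines = ["no audit flags"]
        return "\n".join(lines) + "\n"
    raise AuditError(f"unknown report format {format!r}")


def parse_report_tsv(text: str) -> list[AuditFlag]:
    """Inverse of the TSV rendering (used for round-trips and tooling)."""
    lines = [line for line in text.splitlines() if line.strip()]
    flags = []
    for line in lines[1:]:
        record_id, rule_id, severity, message = line.split("\t", 3)
        flags.append(AuditFlag(record_id, rule_id, severity, message))
    return flags
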