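"""Standards-compliant export: ISA-TAB, GEO SOFT and MINSEQE checks.

The internal model is richer than either exchange format, so exporters
flatten the graph: ISA-TAB gets one study row per distinct biosample and
one assay row per (replicate, raw file); GEO SOFT gets one ``^SERIES`` block
per experiment and one ``^SAMPLE`` block per replicate. File names follow
the accession-as-filename convention: accession + "." + format extension.

MINSEQE (Minimum Information about a high-throughput SEQuencing Experiment)
is a guideline, not a schema; it is operationalized here as five concrete
checks — assay described, samples described, protocols attached, raw data
present, processed data present — whose conjunction is compliance.

All exports are pure functions of the store: re-exporting an unchanged
store is byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .errors import ExportError
from .store import MetadataStore

ORGANISM_NAMES = {"human": "Homo sapiens", "mouse": "Mus musculus"}


def _tsv(rows: Iterable[Iterable[str]]) -> str:
    return "\n".join("\t".join(row) for row in rows) + "\n"


def file_name(store: MetadataStore, file_id: str) -> str:
    """Accession-based file name: e.g. ENCFF123ABC.fastq."""
    return f"{file_id}.{store.get(file_id).get('file_format', 'dat')}"


def _biosample_of_replicate(store: MetadataStore, replicate) -> str | None:
    library_id = replicate.get("library")
    if library_id is None or library_id not in store:
        return None
    return store.get(library_id).get("biosample")


def _raw_files(store: MetadataStore, experiment_id: str, replicate_id: str | None = None):
    """fastq files of an experiment (optionally one replicate), id-sorted."""
    out = []
    for record in store.records("file"):
        if record.deleted or record.get("dataset") != experiment_id:
            continue
        if record.get("file_format") != "fastq":
            continue
        if replicate_id is not None and record.get("replicate") != replicate_id:
            continue
        out.append(record)
    return out


def _experiment_term_name(experiment) -> str:
    return experiment.get("assay_term_name", "")


# ---------------------------------------------------------------------------
# ISA-TAB


def export_isatab(store: MetadataStore, experiment_ids: Iterable[str]) -> dict[str, str]:
    """Export experiments as ISA-TAB investigation/study/assay tables.

    Returns ``{"i_investigation.txt": ..., "s_study.txt": ..., "a_assay.txt": ...}``.
    A biosample shared by several experiments appears once in the study table.
    """
    experiment_ids = sorted(experiment_ids)
    for experiment_id in experiment_ids:
        experiment = store.get(experiment_id)
        if experiment.type_name != "experiment":
            raise ExportError(f"{experiment_id!r} is not an experiment")
        if not store.replicates_of(experiment_id):
            raise ExportError(f"experiment {experiment_id} has no replicates; cannot export")

    study_rows = []
    seen_biosamples: set[str] = set()
    assay_rows = []
    for experiment_id in experiment_ids:
        experiment = store.get(experiment_id)
        replicates = sorted(
            store.replicates_of(experiment_id),
            key=lambda r: (
                r.get("biological_replicate_number", 0),
                r.get("technical_replicate_number", 0),
                r.id,
            ),
        )
        for replicate in replicates:
            biosample_id = _biosample_of_replicate(store, replicate)
            if biosample_id is not None and biosample_id not in seen_biosamples:
                seen_biosamples.add(biosample_id)
                biosample = store.get(biosample_id)
                donor_id = biosample.get("donor", "")
                organism = ""
                if donor_id and donor_id in store:
                    organism = ORGANISM_NAMES.get(
                        store.get(donor_id).get("organism", ""), ""
                    )
                study_rows.append(
                    (
                        biosample_id,
                        donor_id,
                        organism,
                        biosample.get("biosample_term_name", ""),
                        biosample.get("biosample_type", ""),
                    )
                )
            for raw in _raw_files(store, experiment_id, replicate.id):
                assay_rows.append(
                    (
                        biosample_id or "",
                        replicate.get("library", ""),
                        f"{experiment_id}"
                        f".{replicate.get('biological_replicate_number', 0)}"
                        f"_{replicate.get('technical_replicate_number', 0)}",
                        _experiment_term_name(experiment),
                        file_name(store, raw.id),
                    )
                )

    study_rows.sort()
    study_table = _tsv(
        [
            (
                "Sample Name",
                "Source Name",
                "Characteristics[organism]",
                "Characteristics[biosample term]",
                "Characteristics[biosample type]",
            ),
            *(
                (sample, source, organism, term, btype)
                for sample, source, organism, term, btype in study_rows
            ),
        ]
    )
    assay_table = _tsv(
        [
            (
                "Sample Name",
                "Extract Name",
                "Assay Name",
                "Parameter Value[assay term name]",
                "Raw Data File",
            ),
            *assay_rows,
        ]
    )
    investigation = _tsv(
        [
            ("ONTOLOGY SOURCE REFERENCE",),
            ("Term Source Name", "UBERON", "CL", "EFO", "OBI", "CHEBI"),
            ("INVESTIGATION",),
            ("Investigation Identifier", "metaforge-export"),
            ("STUDY",),
            ("Study Identifier", ";".join(experiment_ids)),
            ("Study File Name", "s_study.txt"),
            ("STUDY ASSAYS",),
            ("Study Assay File Name", "a_assay.txt"),
        ]
    )
    return {
        "i_investigation.txt": investigation,
        "s_study.txt": study_table,
        "a_assay.txt": assay_table,
    }


# ---------------------------------------------------------------------------
# GEO SOFT


def export_geo_soft(store: MetadataStore, experiment_id: str) -> str:
    """Export one experiment as a GEO SOFT series: ^SERIES + one ^SAMPLE per
    replicate. Replicates without raw files emit a placeholder supplementary
    line and a :class:`UserWarning`."""
    experiment = store.get(experiment_id)
    if experiment.type_name != "experiment":
        raise ExportError(f"{experiment_id!r} is not an experiment")
    replicates = sorted(
        store.replicates_of(experiment_id),
        key=lambda r: (
            r.get("biological_replicate_number", 0),
            r.get("technical_replicate_number", 0),
            r.id,
        ),
    )
    if not replicates:
        raise ExportError(f"experiment {experiment_id} has no replicates; cannot export")

    lines = [
        f"^SERIES = {experiment_id}",
        f"!Series_title = {_experiment_term_name(experiment)} "
        f"({experiment.get('biosample_term_name', experiment.get('description', ''))})".rstrip(),
        f"!Series_summary = {experiment.get('description', '')}",
        f"!Series_type = {_experiment_term_name(experiment)}",
    ]
    for replicate in replicates:
        bio = replicate.get("biological_replicate_number", 0)
        tech = replicate.get("technical_replicate_number", 0)
        lines.append(f"^SAMPLE = {experiment_id}_rep{bio}_{tech}")
        lines.append(f"!Sample_title = {_experiment_term_name(experiment)} replicate {bio}.{tech}")
        biosample_id = _biosample_of_replicate(store, replicate)
        if biosample_id is not None and biosample_id in store:
            biosample = store.get(biosample_id)
            donor_id = biosample.get("donor", "")
            organism = ""
            if donor_id and donor_id in store:
                organism = ORGANISM_NAMES.get(store.get(donor_id).get("organism", ""), "")
            lines.append(f"!Sample_organism_ch1 = {organism}")
            lines.append(
                f"!Sample_characteristics_ch1 = biosample: "
                f"{biosample.get('biosample_term_name', '')} ({biosample_id})"
            )
            lines.append(f"!Sample_characteristics_ch1 = donor: {donor_id}")
        lines.append(f"!Sample_library_strategy = {_experiment_term_name(experiment)}")
        raw_files = _raw_files(store, experiment_id, replicate.id)
        if raw_files:
            for raw in sorted(raw_files, key=lambda r: r.id):
                lines.append(f"!Sample_supplementary_file = {file_name(store, raw.id)}")
        else:
            warnings.warn(
                f"replicate {replicate.id} of {experiment_id} has no raw files",
                stacklevel=2,
            )
            lines.append("!Sample_supplementary_file = NONE")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# MINSEQE


@dataclass(frozen=True)
class MinseqeReport:
    """Five-point MINSEQE operationalization for one experiment."""

    experiment_id: str
    assay_described: bool
    samples_described: bool
    protocols_present: bool
    raw_data_present: bool
    processed_data_present: bool

    @property
    def compliant(self) -> bool:
        return (
            self.assay_described
            and self.samples_described
            and self.protocols_present
            and self.raw_data_present
            and self.processed_data_present
        )

    def checks(self) -> dict[str, bool]:
        return {
            "assay_described": self.assay_described,
            "samples_described": self.samples_described,
            "protocols_present": self.protocols_present,
            "raw_data_present": self.raw_data_present,
            "processed_data_present": self.processed_data_present,
        }


def check_minseqe(store: MetadataStore, experiment_id: str) -> MinseqeReport:
    """Evaluate the five MINSEQE checks for one experiment."""
    experiment = store.get(experiment_id)
    if experiment.type_name != "experiment":
        raise ExportError(f"{experiment_id!r} is not an experiment")
    replicates = store.replicates_of(experiment_id)

    assay_described = bool(experiment.get("assay_term"))

    samples_described = bool(replicates)
    protocols_present = False
    for replicate in replicates:
        library_id = replicate.get("library")
        if library_id is None or library_id not in store:
            samples_described = False
            continue
        library = store.get(library_id)
        if library.get("documents"):
            protocols_present = True
        biosample_id = library.get("biosample")
        if biosample_id is None or biosample_id not in store:
            samples_described = False
            continue
        biosample = store.get(biosample_id)
        if biosample.get("documents"):
            protocols_present = True
        donor_id = biosample.get("donor")
        if donor_id is None or donor_id not in store:
            samples_described = False

    files = [
        record
        for record in store.records("file")
        if not record.deleted and record.get("dataset") == experiment_id
    ]
    raw_data_present = any(f.get("file_format") == "fastq" for f in files)
    processed_data_present = any(f.get("file_format") != "fastq" for f in files)

    return MinseqeReport(
        experiment_id=experiment_id,
        assay_described=assay_described,
        samples_described=samples_described,
        protocols_present=protocols_present,
        raw_data_present=raw_data_present,
        processed_data_present=processed_data_present,
    )
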