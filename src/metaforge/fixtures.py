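"""Deterministic synthetic consortium stores for testing and demos.

:func:`generate_consortium` emits a small but structurally complete
submission stream: human and mouse donors (one donor contributing both a
liver and a brain biosample), ontology-annotated biosamples including a
keratinocyte pair, libraries, antibody lots, ChIP-seq experiments with
antibodies and input controls, RNA-seq experiments with spike-ins,
paired-end fastq pairs with fastq→bam→bigWig provenance chains, and
pipeline/software records with versions and md5sums. All identifiers are
minted through the accession registry, and every random choice flows from
one seeded generator, so the same spec always yields a byte-identical store.

A clean store passes schema validation, referential integrity, term
validation and the full audit ruleset with zero findings. :func:`corrupt`
then plants violations with minimal, locally scoped edits, emitting the
exact ground-truth flag list alongside — audits on the corrupted store must
equal that list, which is what makes audit recall and precision measurable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from typing import Iterable

from .accessions import AccessionRegistry
from .audits import CHIP_SEQ_TERM, RNA_SEQ_TERM, BUILTIN_RULES
from .errors import InfeasiblePlanError
from .store import MetadataStore

# (term field, term id, term name, biosample type); keratinocyte is kept out
# of the general pool so "skin" searches have an unambiguous expected set
KERATINOCYTE = ("cell_term", "CL:0000312", "keratinocyte", "primary cell")
TISSUE_TERMS = [
    ("tissue_term", "UBERON:0002107", "liver", "tissue"),
    ("tissue_term", "UBERON:0000955", "brain", "tissue"),
    ("tissue_term", "UBERON:0000948", "heart", "tissue"),
    ("tissue_term", "UBERON:0002048", "lung", "tissue"),
    ("tissue_term", "UBERON:0001264", "pancreas", "tissue"),
]
OTHER_CELL_TERMS = [
    ("cell_term", "CL:0000182", "hepatocyte", "primary cell"),
    ("cell_term", "CL:0000084", "T cell", "primary cell"),
    ("cell_line_term", "EFO:0001187", "HepG2", "immortalized cell line"),
    ("cell_line_term", "EFO:0002067", "K562", "immortalized cell line"),
]

CHIP_TARGETS = ["CTCF", "H3K27ac", "POLR2A"]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic consortium."""

    seed: int = 7
    n_donors: int = 6
    n_biosamples_per_donor: int = 2
    n_chipseq: int = 12
    n_rnaseq: int = 8
    replicates_per_experiment: int = 2
    files_per_replicate: int = 2  # raw fastq count; 2 = one paired-end pair
    violation_plan: list = dc_field(default_factory=list)

    def __post_init__(self):
        for name in (
            "n_donors",
            "n_biosamples_per_donor",
            "n_chipseq",
            "n_rnaseq",
            "replicates_per_experiment",
            "files_per_replicate",
        ):
            if getattr(self, name) < 0:
                raise InfeasiblePlanError(f"{name} must be non-negative")
        for rule_id, count in self.violation_plan:
            if rule_id not in BUILTIN_RULES:
                raise InfeasiblePlanError(f"violation plan names unknown rule {rule_id!r}")
            if count < 0:
                raise InfeasiblePlanError("violation counts must be non-negative")


@dataclass
class GroundTruth:
    """Planted (record_id, rule_id) pairs; empty for a clean store."""

    planted: list = dc_field(default_factory=list)

    def as_set(self) -> set[tuple]:
        return set(self.planted)

    def __len__(self) -> int:
        return len(self.planted)


def _md5(rng: random.Random) -> str:
    return f"{rng.getrandbits(128):032x}"


class _Builder:
    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.registry = AccessionRegistry()
        self.store = MetadataStore()

    def mint(self, code: str) -> str:
        return self.registry.mint(code, self.rng).text

    def build(self) -> MetadataStore:
        spec, rng, store = self.spec, self.rng, self.store
        if spec.n_donors < 4:
            raise InfeasiblePlanError(
                "the consortium layout needs at least 4 donors (liver/brain donor, "
                "keratinocyte donor, control donor, anisogenic partner)"
            )
        if spec.n_biosamples_per_donor < spec.replicates_per_experiment:
            raise InfeasiblePlanError(
                "isogenic experiments need one biosample per replicate from one donor"
            )

        store.add("lab", "lab-dcc-demo", name="dcc-demo-lab",
                  institute="Example University", status="released")
        store.add("award", "award-demo", name="U00HG000001",
                  project="demo consortium", status="released")
        doc_growth = store.add(
            "document", "doc-growth",
            document_type="growth protocol",
            description="standard growth and handling protocol",
            status="released",
        ).id
        doc_extract = store.add(
            "document", "doc-extract",
            document_type="extraction protocol",
            description="nucleic acid extraction and library preparation protocol",
            status="released",
        ).id
        store.add("treatment", "trt-tamoxifen",
                  treatment_term="CHEBI:41774", treatment_term_name="tamoxifen",
                  duration=4.0, duration_units="hour", status="released")

        # --- donors: last one is mouse, the rest human -------------------
        donors = []
        for i in range(spec.n_donors):
            donor_id = self.mint("DO")
            organism = "mouse" if i == spec.n_donors - 1 else "human"
            props = dict(
                organism=organism,
                sex=["female", "male"][i % 2],
                life_stage="adult",
                lab="lab-dcc-demo",
                status="released",
            )
            if organism == "mouse":
                props["strain_background"] = "C57BL/6"
            else:
                props["age"] = f"{30 + 3 * i} year"
            store.add("donor", donor_id, **props)
            donors.append((donor_id, organism))

        # --- biosample pools: donor 0 gets liver+brain, donor 1 the
        # keratinocyte pair, donor 2 the control cell lines ---------------
        pools: list[list[str]] = []
        human_cycle = TISSUE_TERMS[2:] + OTHER_CELL_TERMS  # skip liver/brain dupes
        for i, (donor_id, organism) in enumerate(donors):
            pool = []
            for j in range(spec.n_biosamples_per_donor):
                if i == 0 and j < 2:
                    term = TISSUE_TERMS[j]  # liver, then brain
                elif i == 1:
                    term = KERATINOCYTE
                elif i == 2 and j < 2:
                    term = OTHER_CELL_TERMS[2 + (j % 2)]  # HepG2, K562
                elif organism == "mouse":
                    term = TISSUE_TERMS[(i + j) % len(TISSUE_TERMS)]
                else:
                    term = human_cycle[(i + j) % len(human_cycle)]
                term_field, term_id, term_name, biosample_type = term
                biosample_id = self.mint("BS")
                props = dict(
                    biosample_term_name=term_name,
                    biosample_type=biosample_type,
                    donor=donor_id,
                    source="demo tissue bank",
                    date_obtained=f"2015-{(i % 12) + 1:02d}-{(j % 28) + 1:02d}",
                    documents=[doc_growth],
                    lab="lab-dcc-demo",
                    status="released",
                )
                props[term_field] = term_id
                if i == 0 and j == 1:  # the brain biosample carries a treatment
                    props["treatments"] = ["trt-tamoxifen"]
                store.add("biosample", biosample_id, **props)
                pool.append(biosample_id)
            pools.append(pool)
        self._pools = pools

        # --- antibody lots ------------------------------------------------
        antibody_by_target = {}
        for k, target in enumerate(CHIP_TARGETS):
            antibody_id = self.mint("AB")
            store.add(
                "antibody_lot", antibody_id,
                source="demo antibodies inc", product_id=f"ab-{100 + k}",
                lot_id=f"lot-{rng.randrange(1000, 9999)}", targets=[target],
                status="released",
            )
            antibody_by_target[target] = antibody_id

        # --- software / pipelines ----------------------------------------
        for name, version in [("bwa", "0.7.17"), ("samtools", "1.9"), ("star", "2.7.0a")]:
            store.add("software", f"sw-{name}", name=name, version=version,
                      md5sum=_md5(rng), status="released")
        store.add("pipeline", "pl-chip-align", title="ChIP-seq read mapping",
                  software_used=["sw-bwa", "sw-samtools"], status="released")
        store.add("pipeline", "pl-rna-align", title="RNA-seq quantification",
                  software_used=["sw-star", "sw-samtools"], status="released")

        # --- control experiments (input libraries; no antibody, no control)
        controls = []
        for c in range(2):
            experiment_id = self.mint("SR")
            store.add(
                "experiment", experiment_id,
                assay_term=CHIP_SEQ_TERM, assay_term_name="ChIP-seq",
                target="Control", control_type="input library",
                description="input chromatin control",
                lab="lab-dcc-demo", award="award-demo",
                replicates=[], status="released",
            )
            biosample_id = pools[2][c % len(pools[2])]
            self._add_replicates(
                experiment_id, [(1, 1, biosample_id)], assay="chip-control",
                antibody=None, doc_extract=doc_extract,
            )
            controls.append(experiment_id)

        # --- ChIP-seq experiments ----------------------------------------
        donor_cycle = [i for i in range(spec.n_donors)]
        for e in range(spec.n_chipseq):
            experiment_id = self.mint("SR")
            target = CHIP_TARGETS[e % len(CHIP_TARGETS)]
            if e in (0, 1):
                donor_index = 1  # keratinocyte experiments
            elif e in (2, 7):
                donor_index = 0  # technical replicates on donor 0
            else:
                donor_index = donor_cycle[(3 + e) % spec.n_donors]
                if donor_index in (1,):  # keep keratinocytes exclusive
                    donor_index = 0
            layout = self._replicate_layout(e, donor_index, technical=(e in (2, 7)))
            store.add(
                "experiment", experiment_id,
                assay_term=CHIP_SEQ_TERM, assay_term_name="ChIP-seq",
                target=target,
                description=f"{target} ChIP-seq on "
                f"{store.get(layout[0][2]).get('biosample_term_name')}",
                possible_controls=[controls[e % len(controls)]],
                lab="lab-dcc-demo", award="award-demo",
                replicates=[], status="released",
            )
            self._add_replicates(
                experiment_id, layout, assay="chip",
                antibody=antibody_by_target[target], doc_extract=doc_extract,
            )

        # --- RNA-seq experiments -----------------------------------------
        for e in range(spec.n_rnaseq):
            experiment_id = self.mint("SR")
            donor_index = donor_cycle[(3 + e) % spec.n_donors]
            if donor_index == 1:
                donor_index = 0
            technical = e == 0 and spec.replicates_per_experiment >= 2
            layout = self._replicate_layout(
                1000 + e, donor_index, technical=technical
            )
            store.add(
                "experiment", experiment_id,
                assay_term=RNA_SEQ_TERM, assay_term_name="RNA-seq",
                description=f"RNA-seq on "
                f"{store.get(layout[0][2]).get('biosample_term_name')}",
                lab="lab-dcc-demo", award="award-demo",
                replicates=[], status="released",
            )
            self._add_replicates(
                experiment_id, layout, assay="rna",
                antibody=None, doc_extract=doc_extract,
            )

        store.finalize()
        return store

    def _replicate_layout(self, e: int, donor_index: int, technical: bool):
        """List of (bio_number, tech_number, biosample_id) per replicate."""
        spec = self.spec
        pool = self._pool(donor_index)
        if technical:
            biosample_id = pool[0]
            return [
                (1, t + 1, biosample_id)
                for t in range(max(2, spec.replicates_per_experiment))
            ][: max(2, spec.replicates_per_experiment)]
        if e == 3:  # one anisogenic ChIP experiment: distinct donors
            partner = 3 if donor_index != 3 else 0
            layout = [(1, 1, pool[0]), (2, 1, self._pool(partner)[0])]
            return layout[: max(2, spec.replicates_per_experiment)]
        return [
            (b + 1, 1, pool[b % len(pool)])
            for b in range(spec.replicates_per_experiment)
        ]

    def _pool(self, donor_index: int) -> list[str]:
        return self._pools[donor_index]

    def _add_replicates(self, experiment_id, layout, assay, antibody, doc_extract):
        spec, rng, store = self.spec, self.rng, self.store
        replicate_ids = []
        for bio_number, tech_number, biosample_id in layout:
            library_id = self.mint("LB")
            props = dict(
                biosample=biosample_id,
                nucleic_acid_term_name="DNA" if assay.startswith("chip") else "polyadenylated mRNA",
                fragmentation_method="sonication" if assay.startswith("chip") else "chemical",
                documents=[doc_extract],
                status="released",
            )
            if not assay.startswith("chip"):
                props["spikeins_used"] = ["ERCC-mix1"]
            store.add("library", library_id, **props)

            replicate_id = f"rep-{experiment_id}-{bio_number}-{tech_number}"
            rep_props = dict(
                experiment=experiment_id,
                biological_replicate_number=bio_number,
                technical_replicate_number=tech_number,
                library=library_id,
                status="released",
            )
            if antibody is not None:
                rep_props["antibody"] = antibody
            store.add("replicate", replicate_id, **rep_props)
            replicate_ids.append(replicate_id)
            self._add_files(experiment_id, replicate_id)
        store.get(experiment_id).properties["replicates"] = replicate_ids

    def _add_files(self, experiment_id, replicate_id):
        spec, rng, store = self.spec, self.rng, self.store
        fastq_ids = []
        pairs, singles = divmod(spec.files_per_replicate, 2)
        for _ in range(pairs):
            first, second = self.mint("FF"), self.mint("FF")
            for this, other in ((first, second), (second, first)):
                store.add(
                    "file", this,
                    file_format="fastq", output_type="reads",
                    dataset=experiment_id, replicate=replicate_id,
                    run_type="paired-ended", paired_with=other,
                    md5sum=_md5(rng), status="released",
                )
            fastq_ids += [first, second]
        for _ in range(singles):
            file_id = self.mint("FF")
            store.add(
                "file", file_id,
                file_format="fastq", output_type="reads",
                dataset=experiment_id, replicate=replicate_id,
                run_type="single-ended",
                md5sum=_md5(rng), status="released",
            )
            fastq_ids.append(file_id)
        if not fastq_ids:
            return
        bam_id = self.mint("FF")
        store.add(
            "file", bam_id,
            file_format="bam", output_type="alignments",
            dataset=experiment_id, replicate=replicate_id,
            derived_from=sorted(fastq_ids), md5sum=_md5(rng), status="released",
        )
        bigwig_id = self.mint("FF")
        store.add(
            "file", bigwig_id,
            file_format="bigWig", output_type="signal",
            dataset=experiment_id, replicate=replicate_id,
            derived_from=[bam_id], md5sum=_md5(rng), status="released",
        )


def generate_consortium(spec: FixtureSpec) -> tuple[MetadataStore, GroundTruth]:
    """Build a consortium store per ``spec``; plant violations if planned."""
    store = _Builder(spec).build()
    if spec.violation_plan:
        return corrupt(store, spec.violation_plan, spec.seed)
    return store, GroundTruth([])


# ---------------------------------------------------------------------------
# planted violations


def _chip_experiments(store: MetadataStore):
    return [
        e for e in store.records("experiment")
        if e.get("assay_term") == CHIP_SEQ_TERM and e.get("control_type") is None
    ]


def _rna_experiments(store: MetadataStore):
    return [
        e for e in store.records("experiment") if e.get("assay_term") == RNA_SEQ_TERM
    ]


def _pick(rng: random.Random, candidates: list, count: int, rule_id: str) -> list:
    if len(candidates) < count:
        raise InfeasiblePlanError(
            f"rule {rule_id}: plan needs {count} target(s), only "
            f"{len(candidates)} available"
        )
    return rng.sample(sorted(candidates, key=str), count)


def corrupt(
    store: MetadataStore, violation_plan: Iterable[tuple], seed: int
) -> tuple[MetadataStore, GroundTruth]:
    """Plant violations into a copy of a clean store.

    Each planted violation is one minimal edit chosen so it induces exactly
    one audit flag and no others; edits never touch (or depend on) a record
    another edit uses, so the audit result equals the ground truth exactly.
    """
    rng = random.Random(seed)
    store = store.copy()
    truth: list[tuple] = []
    used: set[str] = set()  # record ids no later edit may touch or rely on

    plan = list(violation_plan)
    for rule_id, count in plan:
        if rule_id not in BUILTIN_RULES:
            raise InfeasiblePlanError(f"unknown rule {rule_id!r} in violation plan")
        if count < 0:
            raise InfeasiblePlanError("violation counts must be non-negative")

    for rule_id, count in plan:
        if count == 0:
            continue
        if rule_id == "R1":
            candidates = [
                r.id
                for e in _chip_experiments(store)
                for r in store.replicates_of(e.id)
                if r.get("antibody") is not None and r.id not in used and e.id not in used
            ]
            for replicate_id in _pick(rng, candidates, count, rule_id):
                del store.get(replicate_id).properties["antibody"]
                used.update({replicate_id, store.get(replicate_id).get("experiment")})
                truth.append((replicate_id, "R1"))
        elif rule_id == "R2":
            candidates = [
                e.id for e in _chip_experiments(store)
                if e.get("possible_controls") and e.id not in used
            ]
            for experiment_id in _pick(rng, candidates, count, rule_id):
                del store.get(experiment_id).properties["possible_controls"]
                used.add(experiment_id)
                truth.append((experiment_id, "R2"))
        elif rule_id == "R3":
            candidates = []
            for experiment in _rna_experiments(store):
                for replicate in store.replicates_of(experiment.id):
                    library_id = replicate.get("library")
                    if (
                        library_id
                        and library_id not in used
                        and experiment.id not in used
                        and store.get(library_id).get("spikeins_used")
                    ):
                        candidates.append(library_id)
            for library_id in _pick(rng, sorted(set(candidates)), count, rule_id):
                del store.get(library_id).properties["spikeins_used"]
                used.add(library_id)
                # reserve the linking replicates so no later edit repoints
                # them away (which would orphan the planted violation)
                used.update(
                    r.id for r in store.records("replicate")
                    if r.get("library") == library_id
                )
                truth.append((library_id, "R3"))
        elif rule_id == "R4":
            pairs = []
            for record in store.records("file"):
                partner_id = record.get("paired_with")
                if (
                    partner_id
                    and record.id < partner_id
                    and record.id not in used
                    and partner_id not in used
                ):
                    pairs.append((record.id, partner_id))
            for keep_id, partner_id in _pick(rng, pairs, count, rule_id):
                partner = store.get(partner_id)
                del partner.properties["paired_with"]
                partner.properties["run_type"] = "single-ended"
                used.update({keep_id, partner_id})
                truth.append((keep_id, "R4"))
        elif rule_id == "R5":
            candidates = []
            for experiment in store.records("experiment"):
                if experiment.id in used:
                    continue
                groups: dict[int, list] = {}
                for replicate in store.replicates_of(experiment.id):
                    groups.setdefault(
                        replicate.get("biological_replicate_number"), []
                    ).append(replicate)
                for members in groups.values():
                    if len(members) >= 2 and all(
                        m.get("library") and m.id not in used for m in members
                    ):
                        candidates.append((experiment.id, members[1].id))
                        break
            for experiment_id, replicate_id in _pick(rng, candidates, count, rule_id):
                replicate = store.get(replicate_id)
                own_library = store.get(replicate.get("library"))
                own_biosample = own_library.get("biosample")
                is_rna = store.get(experiment_id).get("assay_term") == RNA_SEQ_TERM
                donors = [
                    lib.id
                    for lib in store.records("library")
                    if lib.get("biosample") != own_biosample
                    and lib.id not in used
                    and (not is_rna or lib.get("spikeins_used"))
                ]
                if not donors:
                    raise InfeasiblePlanError(
                        f"rule R5: no replacement library with a different biosample"
                    )
                replacement = _pick(rng, donors, 1, rule_id)[0]
                replicate.properties["library"] = replacement
                used.update(
                    {experiment_id, replicate_id, replacement}
                    | {m.id for m in store.replicates_of(experiment_id)}
                )
                truth.append((experiment_id, "R5"))
        elif rule_id == "R6":
            candidates = [
                f.id
                for f in store.records("file")
                if f.get("file_format") == "bigWig"
                and f.get("replicate")
                and f.id not in used
            ]
            for file_id in _pick(rng, candidates, count, rule_id):
                del store.get(file_id).properties["replicate"]
                used.add(file_id)
                truth.append((file_id, "R6"))
        elif rule_id == "R7":
            candidates = []
            for replicate in store.records("replicate"):
                if replicate.id in used or not replicate.get("library"):
                    continue
                experiment_id = replicate.get("experiment")
                if experiment_id in used:
                    continue
                siblings = store.replicates_of(experiment_id)
                same_bio = [
                    s for s in siblings
                    if s.get("biological_replicate_number")
                    == replicate.get("biological_replicate_number")
                ]
                if len(same_bio) == 1:  # keep clear of technical groups (R5 scope)
                    candidates.append(replicate.id)
            for replicate_id in _pick(rng, candidates, count, rule_id):
                replicate = store.get(replicate_id)
                del replicate.properties["library"]
                used.update({replicate_id, replicate.get("experiment")})
                truth.append((replicate_id, "R7"))
        else:  # pragma: no cover - plan validation keeps us in R1..R7
            raise InfeasiblePlanError(f"rule {rule_id!r} cannot be planted")

    truth.sort()
    return store, GroundTruth(truth)
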