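"""Object store: linking, integrity, replicates, provenance, embedding."""

import random

import pytest

from metaforge.errors import IntegrityError, ProvenanceCycleError, StoreError
from metaforge.store import (
    ANISOGENIC,
    ISOGENIC,
    TECHNICAL,
    MetadataObject,
    MetadataStore,
)


def minimal_store():
    """donor -> two biosamples, plus scaffolding for replicate chains."""
    store = MetadataStore()
    store.add("lab", "lab-1", name="lab one", status="released")
    store.add("donor", "ENCDO000AAA", organism="human", status="released")
    for accession, term_name, term in [
        ("ENCBS000LIV", "liver", "UBERON:0002107"),
        ("ENCBS000BRN", "brain", "UBERON:0000955"),
    ]:
        store.add(
            "biosample", accession,
            biosample_term_name=term_name, biosample_type="tissue",
            tissue_term=term, donor="ENCDO000AAA", source="bank",
            status="released",
        )
    return store


def add_experiment_chain(store, experiment_id, replicate_specs):
    """replicate_specs: list of (bio, tech, biosample_id, donor_id|None)."""
    store.add(
        "experiment", experiment_id,
        assay_term="OBI:0000716", assay_term_name="ChIP-seq", status="released",
    )
    for bio, tech, biosample_id, donor_id in replicate_specs:
        if donor_id is not None and donor_id not in store:
            store.add("donor", donor_id, organism="human", status="released")
        if biosample_id not in store:
            store.add(
                "biosample", biosample_id,
                biosample_term_name="liver", biosample_type="tissue",
                tissue_term="UBERON:0002107", donor=donor_id, source="bank",
                status="released",
            )
        library_id = f"lib-{experiment_id}-{bio}-{tech}"
        store.add(
            "library", library_id,
            biosample=biosample_id, nucleic_acid_term_name="DNA",
            status="released",
        )
        store.add(
            "replicate", f"rep-{experiment_id}-{bio}-{tech}",
            experiment=experiment_id, biological_replicate_number=bio,
            technical_replicate_number=tech, library=library_id,
            status="released",
        )


class TestAddAndIntegrity:
    def test_shared_donor_resolves_from_both_biosamples(self):
        store = minimal_store()
        donors = {
            store.get(b.id).get("donor") for b in store.records("biosample")
        }
        assert donors == {"ENCDO000AAA"}
        assert store.check_referential_integrity() == []

    def test_duplicate_id_rejected(self):
        store = minimal_store()
        with pytest.raises(StoreError, match="duplicate"):
            store.add("donor", "ENCDO000AAA", organism="human")

    def test_duplicate_identifying_field_rejected(self):
        store = minimal_store()
        with pytest.raises(StoreError, match="already used"):
            store.add("lab", "lab-2", name="lab one")

    def test_dangling_link_tolerated_until_finalize(self):
        store = MetadataStore()
        store.add(
            "biosample", "ENCBS000AAA",
            biosample_term_name="liver", biosample_type="tissue",
            tissue_term="UBERON:0002107", donor="ENCDO404NOP", source="bank",
        )
        findings = store.check_referential_integrity()
        assert [(f.field, f.problem) for f in findings] == [("donor", "dangling-link")]
        with pytest.raises(IntegrityError):
            store.finalize()
        store.add("donor", "ENCDO404NOP", organism="human")
        store.finalize()
        assert store.finalized

    def test_deleting_a_referenced_record_dangles_the_link(self):
        store = minimal_store()
        store.finalize()
        store.delete("ENCDO000AAA")
        findings = store.check_referential_integrity()
        assert {(f.record_id, f.problem) for f in findings} == {
            ("ENCBS000BRN", "dangling-link"),
            ("ENCBS000LIV", "dangling-link"),
        }

    def test_mistyped_link_reported(self):
        store = minimal_store()
        store.add(
            "library", "lib-1",
            biosample="ENCDO000AAA",  # a donor, not a biosample
            nucleic_acid_term_name="DNA",
        )
        findings = store.check_referential_integrity()
        assert [(f.record_id, f.problem) for f in findings] == [
            ("lib-1", "mistyped-link")
        ]


class TestReplicateClassification:
    def test_same_biosample_is_technical(self):
        store = minimal_store()
        add_experiment_chain(
            store, "ENCSR000AAA",
            [(1, 1, "ENCBS000LIV", None), (1, 2, "ENCBS000LIV", None)],
        )
        (classification,) = store.classify_replicates("ENCSR000AAA").values()
        assert classification == TECHNICAL

    def test_same_donor_different_biosamples_is_isogenic(self):
        store = minimal_store()
        add_experiment_chain(
            store, "ENCSR000AAA",
            [(1, 1, "ENCBS000LIV", None), (2, 1, "ENCBS000BRN", None)],
        )
        (classification,) = store.classify_replicates("ENCSR000AAA").values()
        assert classification == ISOGENIC

    def test_different_donors_is_anisogenic(self):
        store = minimal_store()
        add_experiment_chain(
            store, "ENCSR000AAA",
            [(1, 1, "ENCBS000LIV", None), (2, 1, "ENCBS999OTH", "ENCDO999OTH")],
        )
        (classification,) = store.classify_replicates("ENCSR000AAA").values()
        assert classification == ANISOGENIC

    def test_classification_is_symmetric_and_order_invariant(self, clean_store):
        for experiment in clean_store.records("experiment"):
            pairs = clean_store.classify_replicates(experiment.id)
            for (first, second) in pairs:
                assert first < second  # canonical orientation covers both

    def test_unresolvable_chain_raises(self):
        store = minimal_store()
        store.add(
            "experiment", "ENCSR000AAA",
            assay_term="OBI:0000716", assay_term_name="ChIP-seq",
        )
        store.add(
            "replicate", "rep-1", experiment="ENCSR000AAA",
            biological_replicate_number=1, technical_replicate_number=1,
        )
        store.add(
            "replicate", "rep-2", experiment="ENCSR000AAA",
            biological_replicate_number=2, technical_replicate_number=1,
        )
        with pytest.raises(StoreError, match="no library"):
            store.classify_replicates("ENCSR000AAA")


def file_store(edges, n):
    """Build a store of bare file nodes with the given derived_from edges."""
    store = MetadataStore()
    for i in range(n):
        parents = sorted(dst for src, dst in edges if src == i)
        store.add_object(
            MetadataObject(
                f"F{i:03d}", "file",
                {"derived_from": [f"F{j:03d}" for j in parents]},
            ),
            validate=False,
        )
    return store


def brute_force_ancestors(edges, node):
    """Reflexive-free transitive closure by repeated edge expansion."""
    ancestors = set()
    frontier = {node}
    while frontier:
        step = {dst for src, dst in edges if src in frontier}
        frontier = step - ancestors
        ancestors |= step
    ancestors.discard(node)
    return ancestors


class TestProvenance:
    def test_three_node_chain_orders_nearest_first(self):
        store = file_store({(2, 1), (1, 0)}, 3)  # bigWig(2) <- bam(1) <- fastq(0)
        assert store.provenance_chain("F002") == ["F001", "F000"]

    def test_raw_file_has_empty_chain(self):
        store = file_store(set(), 1)
        assert store.provenance_chain("F000") == []

    def test_cycle_detected_and_named(self):
        store = file_store({(0, 1), (1, 0)}, 2)
        with pytest.raises(ProvenanceCycleError) as err:
            store.provenance_chain("F000")
        assert set(err.value.cycle) >= {"F000", "F001"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_dag_matches_brute_force_closure(self, seed):
        rng = random.Random(seed)
        n = 50
        edges = {
            (i, j)
            for i in range(n)
            for j in range(i)  # j < i guarantees acyclicity
            if rng.random() < 0.08
        }
        store = file_store(edges, n)
        for i in range(n):
            chain = store.provenance_chain(f"F{i:03d}")
            expected = {f"F{j:03d}" for j in brute_force_ancestors(edges, i)}
            assert set(chain) == expected
            # topological: every file precedes all of its own ancestors
            for pos, file_id in enumerate(chain):
                node = int(file_id[1:])
                for ancestor in brute_force_ancestors(edges, node):
                    assert chain.index(f"F{ancestor:03d}") > pos

    def test_finalize_rejects_provenance_cycles(self):
        store = file_store({(0, 1), (1, 0)}, 2)
        with pytest.raises(ProvenanceCycleError):
            store.finalize()


class TestEmbedding:
    def test_depth_zero_leaves_links_as_ids(self):
        store = minimal_store()
        doc = store.embed_object("ENCBS000LIV", depth=0)
        assert doc["donor"] == "ENCDO000AAA"

    def test_default_depth_reaches_donor_from_experiment(self, clean_store):
        experiment = next(
            e for e in clean_store.records("experiment") if e.get("replicates")
        )
        doc = clean_store.embed_object(experiment.id)
        replicate = doc["replicates"][0]
        donor = replicate["library"]["biosample"]["donor"]
        assert isinstance(donor, dict) and donor["organism"] in ("human", "mouse")

    def test_mutually_linked_records_terminate(self):
        store = MetadataStore()
        store.add_object(
            MetadataObject("F000", "file", {"paired_with": "F001"}), validate=False
        )
        store.add_object(
            MetadataObject("F001", "file", {"paired_with": "F000"}), validate=False
        )
        doc = store.embed_object("F000", depth=10)
        # the revisit embeds as a bare id, bounding the nesting
        assert doc["paired_with"]["paired_with"] == "F000"

    def test_embedding_is_pure(self, clean_store):
        experiment_id = clean_store.ids("experiment")[0]
        assert clean_store.embed_object(experiment_id) == clean_store.embed_object(
            experiment_id
        )


class TestSerialization:
    def test_single_document_round_trip(self, tmp_path, clean_store):
        path = tmp_path / "store.json"
        clean_store.save(path)
        reloaded = MetadataStore.load(path, finalize=True)
        assert reloaded.to_json_doc() == clean_store.to_json_doc()

    def test_directory_dialect_round_trip(self, tmp_path, clean_store):
        path = tmp_path / "store"
        clean_store.save(path)
        assert (path / "experiment.json").exists()
        reloaded = MetadataStore.load(path, finalize=True)
        assert reloaded.to_json_doc() == clean_store.to_json_doc()

    def test_paired_with_symmetry_completed_on_finalize(self):
        store = MetadataStore()
        base = dict(
            file_format="fastq", output_type="reads", dataset="ENCSR000AAA",
            md5sum="0" * 32,
        )
        store.add(
            "experiment", "ENCSR000AAA",
            assay_term="OBI:0000716", assay_term_name="ChIP-seq",
        )
        store.add("file", "ENCFF000AAA", run_type="paired-ended",
                  paired_with="ENCFF000BBB", **base)
        # the one-sided partner bypasses submission validation, as a
        # half-loaded submission would
        store.add_object(
            MetadataObject("ENCFF000BBB", "file", dict(base, run_type="paired-ended")),
            validate=False,
        )
        store.finalize()
        assert store.get("ENCFF000BBB").get("paired_with") == "ENCFF000AAA"
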