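"""Apply engine: per-type semantics, strict atomicity, lenient mode, and
provisional (deferred) changes."""

import pytest

from kgclite import (ApplyConfig, ChangeSet, ClassCreation, EdgeCreation,
                     EdgeDeletion, EdgeRecord, FixtureSpec, NewSynonym,
                     NewTextDefinition, NodeDeletion, NodeMove, NodeObsoletion,
                     NodeRef, NodeRename, NodeTextDefinitionChange,
                     PredicateChange, RemoveSynonym, RemoveTextDefinition,
                     Synonym, SynonymReplacement, apply, apply_pending,
                     dumps_graph, generate_graph, graph_equal, invert,
                     loads_graph, random_changeset, store_provisional)
from kgclite.errors import (PreconditionFailed, UnknownPendingId,
                            UnresolvableReference)
from kgclite.vocab import IS_A, PART_OF, PENDING_CHANGE_PRED

from conftest import make_graph

HAND = NodeRef(curie="UBERON:0002398")


def apply_one(change, graph, **kw):
    new, _ = apply(ChangeSet([change.with_id("kgcl:000001")]), graph, **kw)
    return new


class TestNodeChanges:
    def test_rename_by_label(self, anatomy):
        g = apply_one(NodeRename(about_node=NodeRef(label="hand"),
                                 old_value="hand", new_value="manus"), anatomy)
        assert g.nodes["UBERON:0002398"].label == "manus"
        # the input graph is untouched
        assert anatomy.nodes["UBERON:0002398"].label == "hand"

    def test_rename_wrong_old_value_fails_strict(self, anatomy):
        with pytest.raises(PreconditionFailed, match="label"):
            apply_one(NodeRename(about_node=HAND, old_value="paw",
                                 new_value="manus"), anatomy)

    def test_obsoletion_deprecates_and_drops_out_edges(self, anatomy):
        g = apply_one(NodeObsoletion(
            about_node=NodeRef(label="liver"),
            has_direct_replacement=NodeRef(curie="UBERON:0000948")), anatomy)
        node = g.nodes["UBERON:0002107"]
        assert node.deprecated and node.replaced_by == "UBERON:0000948"
        # out-edge liver is_a abdomen is consumed; incoming part_of edge stays
        assert not g.out_edges("UBERON:0002107")
        assert EdgeRecord("UBERON:0000062", PART_OF, "UBERON:0002107") in g.edges

    def test_obsoleting_twice_fails(self, anatomy):
        g = apply_one(NodeObsoletion(about_node=HAND), anatomy)
        with pytest.raises(PreconditionFailed, match="already"):
            apply_one(NodeObsoletion(about_node=HAND), g)

    def test_deletion_removes_node_and_incident_edges(self, anatomy):
        g = apply_one(NodeDeletion(about_node=NodeRef(label="liver")), anatomy)
        assert "UBERON:0002107" not in g.nodes
        assert not any("UBERON:0002107" in (e.subject, e.object)
                       for e in g.edges)

    def test_class_creation_mints_an_id(self, anatomy):
        g = apply_one(ClassCreation(name="digestive system"), anatomy,
                      config=ApplyConfig(id_namespace="UBERONX"))
        (new_id,) = set(g.nodes) - set(anatomy.nodes)
        assert new_id.startswith("UBERONX:")
        assert g.nodes[new_id].label == "digestive system"

    def test_class_creation_with_explicit_curie(self, anatomy):
        change = ClassCreation(about_node=NodeRef(curie="UBERON:0001007"),
                               name="digestive system")
        g = apply_one(change, anatomy)
        assert g.nodes["UBERON:0001007"].label == "digestive system"
        with pytest.raises(PreconditionFailed, match="exists"):
            apply_one(change, g)

    def test_created_class_is_addressable_later_in_the_set(self, anatomy):
        cs = ChangeSet([
            ClassCreation(name="digestive system", id="kgcl:000001"),
            NodeMove(about_node=NodeRef(label="liver"),
                     new_object=NodeRef(label="digestive system"),
                     old_object=NodeRef(label="abdomen"), id="kgcl:000002"),
        ])
        g, report = apply(cs, anatomy)
        assert len(report.applied) == 2
        (new_id,) = set(g.nodes) - set(anatomy.nodes)
        assert EdgeRecord("UBERON:0002107", IS_A, new_id) in g.edges


class TestTextChanges:
    def test_synonym_lifecycle(self, anatomy):
        g = apply_one(NewSynonym(about_node=NodeRef(label="femur"),
                                 new_value="thigh bone", qualifier="exact"),
                      anatomy)
        assert Synonym("thigh bone", "exact") in g.nodes["UBERON:0000981"].synonyms
        g = apply_one(SynonymReplacement(about_node=NodeRef(label="femur"),
                                         old_value="thighbone",
                                         new_value="os femoris"), g)
        syns = g.nodes["UBERON:0000981"].synonyms
        # replacement keeps the original related scope
        assert Synonym("os femoris", "related") in syns
        assert not any(s.value == "thighbone" for s in syns)
        g = apply_one(RemoveSynonym(about_node=NodeRef(label="femur"),
                                    old_value="os femoris"), g)
        assert g.nodes["UBERON:0000981"].synonyms == {Synonym("thigh bone", "exact")}

    def test_duplicate_synonym_fails(self, anatomy):
        with pytest.raises(PreconditionFailed, match="synonym"):
            apply_one(NewSynonym(about_node=NodeRef(label="humerus"),
                                 new_value="arm bone", qualifier="exact"),
                      anatomy)
        # the same value under a different scope is a distinct assertion
        g = apply_one(NewSynonym(about_node=NodeRef(label="humerus"),
                                 new_value="arm bone", qualifier="broad"),
                      anatomy)
        assert len(g.nodes["UBERON:0000976"].synonyms) == 2

    def test_definition_lifecycle(self, anatomy):
        g = apply_one(NewTextDefinition(about_node=NodeRef(label="trachea"),
                                        new_value="The windpipe."), anatomy)
        assert g.nodes["UBERON:0003126"].definition == "The windpipe."
        g = apply_one(NodeTextDefinitionChange(
            about_node=NodeRef(label="trachea"), old_value="The windpipe.",
            new_value="An airway."), g)
        assert g.nodes["UBERON:0003126"].definition == "An airway."
        g = apply_one(RemoveTextDefinition(about_node=NodeRef(label="trachea")), g)
        assert g.nodes["UBERON:0003126"].definition is None

    def test_adding_a_second_definition_fails(self, anatomy):
        with pytest.raises(PreconditionFailed, match="definition"):
            apply_one(NewTextDefinition(about_node=NodeRef(label="liver"),
                                        new_value="Another."), anatomy)

    def test_definition_change_verifies_old_value(self, anatomy):
        with pytest.raises(PreconditionFailed):
            apply_one(NodeTextDefinitionChange(
                about_node=NodeRef(label="liver"), old_value="Wrong.",
                new_value="New."), anatomy)


class TestEdgeChanges:
    def test_edge_creation_and_duplicate(self, anatomy):
        change = EdgeCreation(subject=NodeRef(label="femur"),
                              predicate=PART_OF,
                              object=NodeRef(label="abdomen"))
        g = apply_one(change, anatomy)
        assert EdgeRecord("UBERON:0000981", PART_OF, "UBERON:0000916") in g.edges
        with pytest.raises(PreconditionFailed, match="exists"):
            apply_one(change, g)

    def test_deleting_a_missing_edge_fails(self, anatomy):
        with pytest.raises(PreconditionFailed, match="absent"):
            apply_one(EdgeDeletion(subject=NodeRef(label="femur"),
                                   predicate=IS_A,
                                   object=NodeRef(label="abdomen")), anatomy)

    def test_short_move_infers_the_unique_parent(self, anatomy):
        g = apply_one(NodeMove(about_node=NodeRef(label="liver"),
                               new_object=NodeRef(label="heart")), anatomy)
        assert EdgeRecord("UBERON:0002107", IS_A, "UBERON:0000948") in g.edges
        assert EdgeRecord("UBERON:0002107", IS_A, "UBERON:0000916") not in g.edges

    def test_short_move_with_ambiguous_parent_fails(self, anatomy):
        anatomy.edges.add(EdgeRecord("UBERON:0002107", IS_A, "UBERON:0000948"))
        with pytest.raises(PreconditionFailed, match="parent"):
            apply_one(NodeMove(about_node=NodeRef(label="liver"),
                               new_object=NodeRef(label="trachea")), anatomy)

    def test_predicate_change(self, anatomy):
        g = apply_one(PredicateChange(subject=NodeRef(label="liver"),
                                      object=NodeRef(label="abdomen"),
                                      old_predicate=IS_A,
                                      new_predicate=PART_OF), anatomy)
        assert EdgeRecord("UBERON:0002107", PART_OF, "UBERON:0000916") in g.edges
        assert EdgeRecord("UBERON:0002107", IS_A, "UBERON:0000916") not in g.edges


class TestModes:
    def test_strict_failure_is_atomic(self, anatomy):
        cs = ChangeSet([
            NodeRename(about_node=HAND, old_value="hand", new_value="manus",
                       id="kgcl:000001"),
            NodeDeletion(about_node=NodeRef(label="gallbladder"),
                         id="kgcl:000002"),
        ])
        with pytest.raises(UnresolvableReference):
            apply(cs, anatomy)
        assert anatomy.nodes["UBERON:0002398"].label == "hand"

    def test_lenient_skips_failures_and_keeps_going(self, anatomy):
        cs = ChangeSet([
            NodeDeletion(about_node=NodeRef(label="gallbladder"),
                         id="kgcl:000001"),
            NodeRename(about_node=HAND, old_value="hand", new_value="manus",
                       id="kgcl:000002"),
        ])
        g, report = apply(cs, anatomy, mode="lenient")
        assert g.nodes["UBERON:0002398"].label == "manus"
        assert report.applied == ["kgcl:000002"]
        assert report.skipped and report.skipped[0][0] == "kgcl:000001"

    def test_lenient_applies_despite_stale_old_value(self, anatomy):
        g, report = apply(ChangeSet([NodeRename(
            about_node=HAND, old_value="paw", new_value="manus",
            id="kgcl:000001")]), anatomy, mode="lenient")
        assert g.nodes["UBERON:0002398"].label == "manus"
        assert report.warnings

    def test_apply_then_inverse_restores_the_graph(self, anatomy):
        graph = generate_graph(FixtureSpec(n_nodes=30, n_edges=35, seed=11))
        invertible = ("NodeRename", "SynonymReplacement", "NewSynonym",
                      "NewTextDefinition", "EdgeCreation", "EdgeDeletion",
                      "NodeMove", "PredicateChange")
        cs = random_changeset(graph, 25, seed=12,
                              type_weights={t: 1.0 for t in invertible})
        forward, _ = apply(cs, graph)
        inverse = ChangeSet([invert(c) for c in reversed(list(cs))])
        restored, _ = apply(inverse, forward)
        cmp = graph_equal(restored, graph)
        assert cmp.equal, cmp.differences


class TestProvisional:
    def changeset(self):
        return ChangeSet([
            NodeRename(about_node=HAND, old_value="hand", new_value="manus",
                       id="kgcl:000001"),
            NewSynonym(about_node=NodeRef(label="femur"),
                       new_value="thigh bone", qualifier="exact",
                       id="kgcl:000002"),
        ])

    def test_store_does_not_enact(self, anatomy):
        g = store_provisional(self.changeset(), anatomy)
        assert g.nodes["UBERON:0002398"].label == "hand"
        assert len(g.provisional) == 2
        assert g.provisional[0][0] == "UBERON:0002398"

    def test_deferred_equals_direct(self, anatomy):
        cs = self.changeset()
        direct, _ = apply(cs, anatomy)
        deferred, _ = apply_pending(store_provisional(cs, anatomy), "all")
        cmp = graph_equal(deferred, direct, ignore_provisional=True)
        assert cmp.equal, cmp.differences
        assert not deferred.provisional

    def test_selective_pending_application(self, anatomy):
        stored = store_provisional(self.changeset(), anatomy)
        g, report = apply_pending(stored, ["kgcl:000002"])
        assert report.applied == ["kgcl:000002"]
        assert g.nodes["UBERON:0002398"].label == "hand"  # still pending
        assert [pid for pid, _ in
                [(t, p) for t, p in g.provisional]] == ["UBERON:0002398"]
        with pytest.raises(UnknownPendingId):
            apply_pending(g, ["kgcl:000404"])

    def test_pending_annotations_survive_save_and_load(self, anatomy):
        stored = store_provisional(self.changeset(), anatomy)
        text = dumps_graph(stored)
        assert PENDING_CHANGE_PRED in text
        reloaded = loads_graph(text)
        # storage order survives the round trip
        assert [t for t, _ in reloaded.provisional] == \
               [t for t, _ in stored.provisional]
        g, report = apply_pending(reloaded, "all")
        assert len(report.applied) == 2
        assert g.nodes["UBERON:0002398"].label == "manus"

    def test_class_creation_is_stored_at_graph_level(self):
        g = make_graph([("EX:1", "thing")])
        stored = store_provisional(
            ChangeSet([ClassCreation(name="new thing", id="kgcl:000001")]), g)
        assert stored.provisional[0][0] is None

    @pytest.mark.parametrize("seed", range(10))
    def test_deferred_equals_direct_on_random_changesets(self, seed):
        graph = generate_graph(FixtureSpec(n_nodes=25, n_edges=30, seed=seed))
        cs = random_changeset(graph, 20, seed=seed + 900)
        direct, _ = apply(cs, graph)
        stored = loads_graph(dumps_graph(store_provisional(cs, graph)))
        deferred, _ = apply_pending(stored, "all")
        cmp = graph_equal(deferred, direct, ignore_provisional=True)
        assert cmp.equal, cmp.differences
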