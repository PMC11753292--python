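"""Diff engine: the raw delta, the lift rules, parsimony, and the
apply∘diff soundness property."""

import pytest

from kgclite import (ChangeSet, EdgeRecord, FixtureSpec, NodeMove, NodeRecord,
                     NodeRef, Synonym, apply, diff, generate_graph,
                     graph_equal, lift, random_changeset, raw_diff)
from kgclite.errors import UnliftableDelta
from kgclite.vocab import IS_A, PART_OF

from conftest import make_graph


def five_node_pair():
    """The motivating five-node scenario: E is re-parented from C to B."""
    nodes = [("EX:A", "A"), ("EX:B", "B"), ("EX:C", "C"),
             ("EX:D", "D"), ("EX:E", "E")]
    shared = [("EX:B", IS_A, "EX:A"), ("EX:C", IS_A, "EX:A"),
              ("EX:D", IS_A, "EX:B")]
    o1 = make_graph(nodes, shared + [("EX:E", IS_A, "EX:C")])
    o2 = make_graph(nodes, shared + [("EX:E", IS_A, "EX:B")])
    return o1, o2


class TestRawDiff:
    def test_identical_graphs_give_an_empty_delta(self, anatomy):
        delta = raw_diff(anatomy, anatomy)
        assert not (delta.nodes_added or delta.nodes_removed
                    or delta.field_changed or delta.edges_added
                    or delta.edges_removed)

    def test_every_low_level_difference_is_recorded(self, anatomy):
        other = anatomy.copy()
        other.nodes["UBERON:0002398"].label = "manus"
        other.nodes["UBERON:0000981"].synonyms.add(Synonym("os femoris", "exact"))
        del other.nodes["UBERON:0003126"]
        delta = raw_diff(anatomy, other)
        assert delta.nodes_removed == {"UBERON:0003126"}
        assert ("UBERON:0002398", "label", "hand", "manus") in delta.field_changed
        assert any(f[1] == "synonym_added" for f in delta.field_changed)

    def test_raw_diff_matches_a_brute_force_field_walk(self):
        a = generate_graph(FixtureSpec(n_nodes=20, n_edges=24, seed=21))
        b = generate_graph(FixtureSpec(n_nodes=20, n_edges=24, seed=22))
        delta = raw_diff(a, b)
        assert set(delta.nodes_added) == set(b.nodes) - set(a.nodes)
        assert set(delta.nodes_removed) == set(a.nodes) - set(b.nodes)
        assert set(delta.edges_added) == b.edges - a.edges
        assert set(delta.edges_removed) == a.edges - b.edges


class TestFiveNodeScenario:
    def test_reparenting_lifts_to_exactly_one_node_move(self):
        o1, o2 = five_node_pair()
        cs = diff(o1, o2)
        assert len(cs) == 1
        (change,) = cs
        assert change == NodeMove(about_node=NodeRef(curie="EX:E"),
                                  old_object=NodeRef(curie="EX:C"),
                                  new_object=NodeRef(curie="EX:B"),
                                  predicate=IS_A).with_id(change.id)

    def test_the_recovered_move_reproduces_o2(self):
        o1, o2 = five_node_pair()
        patched, _ = apply(diff(o1, o2), o1)
        cmp = graph_equal(patched, o2)
        assert cmp.equal, cmp.differences


class TestLiftRules:
    def test_rename_not_delete_plus_create(self, anatomy):
        other = anatomy.copy()
        other.nodes["UBERON:0002398"].label = "manus"
        cs = diff(anatomy, other)
        assert [c.type_name for c in cs] == ["NodeRename"]

    def test_same_scope_synonym_pair_becomes_a_replacement(self, anatomy):
        other = anatomy.copy()
        syns = other.nodes["UBERON:0000981"].synonyms
        syns.clear()
        syns.add(Synonym("os femoris", "related"))
        cs = diff(anatomy, other)
        assert [c.type_name for c in cs] == ["SynonymReplacement"]

    def test_cross_scope_synonym_swap_stays_two_changes(self, anatomy):
        other = anatomy.copy()
        syns = other.nodes["UBERON:0000981"].synonyms
        syns.clear()
        syns.add(Synonym("os femoris", "exact"))
        assert sorted(c.type_name for c in diff(anatomy, other)) == \
            ["NewSynonym", "RemoveSynonym"]

    def test_deprecation_with_pointer_becomes_an_obsoletion(self, anatomy):
        other = anatomy.copy()
        node = other.nodes["UBERON:0002107"]
        node.deprecated = True
        node.replaced_by = "UBERON:0000948"
        for e in list(other.out_edges("UBERON:0002107")):
            other.edges.discard(e)
        cs = diff(anatomy, other)
        assert [c.type_name for c in cs] == ["NodeObsoletion"]
        assert cs[0].has_direct_replacement == NodeRef(curie="UBERON:0000948")

    def test_obsoletion_that_keeps_an_out_edge_adds_it_back(self, anatomy):
        other = anatomy.copy()
        other.nodes["UBERON:0002107"].deprecated = True
        # the is_a out-edge of the obsoleted liver is retained in the target
        cs = diff(anatomy, other)
        assert sorted(c.type_name for c in cs) == \
            ["EdgeCreation", "NodeObsoletion"]
        patched, _ = apply(cs, anatomy)
        assert graph_equal(patched, other).equal

    def test_new_node_becomes_class_creation_with_followups(self, anatomy):
        other = anatomy.copy()
        other.add_node(NodeRecord(id="UBERON:0001007",
                                  label="digestive system",
                                  definition="The organs of digestion.",
                                  node_kind="class"))
        cs = diff(anatomy, other)
        assert [c.type_name for c in cs] == \
            ["ClassCreation", "NewTextDefinition"]
        assert cs[0].about_node == NodeRef(curie="UBERON:0001007")

    def test_predicate_flip_is_one_change(self, anatomy):
        other = anatomy.copy()
        other.edges.discard(EdgeRecord("UBERON:0000062", PART_OF,
                                       "UBERON:0002107"))
        other.edges.add(EdgeRecord("UBERON:0000062", IS_A, "UBERON:0002107"))
        cs = diff(anatomy, other)
        assert [c.type_name for c in cs] == ["PredicateChange"]

    def test_unrelated_edge_churn_stays_creation_plus_deletion(self, anatomy):
        other = anatomy.copy()
        other.edges.discard(EdgeRecord("UBERON:0002398", IS_A,
                                       "UBERON:0000916"))
        other.edges.add(EdgeRecord("UBERON:0000981", IS_A, "UBERON:0000916"))
        assert sorted(c.type_name for c in diff(anatomy, other)) == \
            ["EdgeCreation", "EdgeDeletion"]


class TestUnliftable:
    def test_undeprecation_is_not_expressible(self, anatomy):
        anatomy.nodes["UBERON:0002398"].deprecated = True
        other = anatomy.copy()
        other.nodes["UBERON:0002398"].deprecated = False
        with pytest.raises(UnliftableDelta):
            diff(anatomy, other)

    def test_replacement_rewrite_without_flip_is_not_expressible(self, anatomy):
        anatomy.nodes["UBERON:0002398"].deprecated = True
        anatomy.nodes["UBERON:0002398"].replaced_by = "UBERON:0000948"
        other = anatomy.copy()
        other.nodes["UBERON:0002398"].replaced_by = "UBERON:0002107"
        with pytest.raises(UnliftableDelta):
            diff(anatomy, other)

    def test_new_unlabeled_node_is_not_expressible(self, anatomy):
        other = anatomy.copy()
        other.add_node(NodeRecord(id="UBERON:0001007", label=None,
                                  node_kind="class"))
        with pytest.raises(UnliftableDelta):
            diff(anatomy, other)


class TestSoundnessProperty:
    @pytest.mark.parametrize("seed", range(25))
    def test_apply_diff_identity_on_random_pairs(self, seed):
        a = generate_graph(FixtureSpec(n_nodes=30, n_edges=36, seed=seed))
        cs = random_changeset(a, 25, seed=seed + 300)
        b, _ = apply(cs, a)
        recovered = diff(a, b)
        patched, _ = apply(recovered, a)
        cmp = graph_equal(patched, b)
        assert cmp.equal, cmp.differences

    @pytest.mark.parametrize("seed", range(5))
    def test_diff_of_identical_graphs_is_empty(self, seed):
        g = generate_graph(FixtureSpec(n_nodes=20, n_edges=24, seed=seed))
        assert len(diff(g, g.copy())) == 0

    def test_diff_output_is_deterministic(self):
        a = generate_graph(FixtureSpec(n_nodes=30, n_edges=36, seed=41))
        b, _ = apply(random_changeset(a, 30, seed=42), a)
        assert diff(a, b) == diff(a, b)
        assert [c.id for c in diff(a, b)] == [c.id for c in diff(a, b)]

    @pytest.mark.parametrize("seed", range(10))
    def test_parsimony_no_liftable_pair_remains(self, seed):
        a = generate_graph(FixtureSpec(n_nodes=25, n_edges=30, seed=seed))
        b, _ = apply(random_changeset(a, 20, seed=seed + 700), a)
        cs = diff(a, b)
        # a residual EdgeDeletion+EdgeCreation pair sharing (subject,
        # predicate) should have been lifted to a NodeMove; sharing
        # (subject, object) to a PredicateChange
        deleted = {(c.subject.curie, c.predicate, c.object.curie)
                   for c in cs if c.type_name == "EdgeDeletion"}
        created = {(c.subject.curie, c.predicate, c.object.curie)
                   for c in cs if c.type_name == "EdgeCreation"}
        consumed = {t[0] for t in deleted} & {
            c.about_node.curie for c in cs
            if c.type_name in ("NodeDeletion", "NodeObsoletion")}
        for s, p, o in deleted:
            if s in consumed:
                continue
            assert not any(cs_ == s and cp == p for cs_, cp, _ in created), \
                f"unlifted NodeMove candidate on ({s}, {p})"
            assert not any(cs_ == s and co == o for cs_, _, co in created), \
                f"unlifted PredicateChange candidate on ({s}, {o})"
        # rename beats delete+create: no node id may be both removed and added
        removed_nodes = {c.about_node.curie for c in cs
                         if c.type_name == "NodeDeletion"}
        added_nodes = {c.about_node.curie for c in cs
                       if c.type_name == "ClassCreation" and c.about_node}
        assert not removed_nodes & added_nodes


def test_lift_is_exposed_separately(anatomy):
    other = anatomy.copy()
    other.nodes["UBERON:0002398"].label = "manus"
    cs = lift(raw_diff(anatomy, other), anatomy, other)
    assert isinstance(cs, ChangeSet) and len(cs) == 1
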