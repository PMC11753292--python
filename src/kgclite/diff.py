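"""The diff engine: recover a parsimonious high-level change set between two
graph versions.

Axiom-wise set diffs describe change at a lower level than curators think:
re-parenting a term shows up as one edge deleted plus one edge inserted. This
engine works in two stages. :func:`raw_diff` computes exactly those low-level
deltas (node additions/removals, field changes, edge additions/removals).
:func:`lift` then explains every delta element by exactly one high-level
change, pairing low-level fragments into the single operation a curator would
name:

1. a label change → NodeRename;
2. a definition appearing / disappearing / changing → NewTextDefinition /
   RemoveTextDefinition / NodeTextDefinitionChange;
3. a synonym removed and one added on the same node with the same scope →
   SynonymReplacement (otherwise RemoveSynonym / NewSynonym);
4. the deprecation flag flipping on → NodeObsoletion (with replacement when
   a replaced-by pointer appears alongside);
5. a node only in the new graph → ClassCreation (plus follow-up changes for
   its definition/synonyms, since creation carries only the name); a node
   only in the old graph → NodeDeletion;
6. a removed and an added edge sharing subject and predicate → one NodeMove;
7. a removed and an added edge sharing subject and object → one
   PredicateChange;
8. whatever edges remain → plain EdgeDeletion / EdgeCreation.

Edges that the apply semantics of a node change already accounts for are
consumed by that change: a deleted node takes its incident edges with it, and
an obsoleted node takes its out-edges (any out-edge the new version retains or
gains on an obsoleted node is re-asserted by an explicit EdgeCreation).

The guiding invariant is soundness: ``apply(diff(a, b), a)`` is always
graph-equal to ``b``. Deltas the change vocabulary cannot express (a node
un-deprecating, changing kind, or a non-class node appearing) raise
:class:`~kgclite.errors.UnliftableDelta` rather than being dropped silently.

Output order is deterministic: node-level changes (creation first, deletion
and obsoletion last per node), then edge-level changes, lexicographic by
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnliftableDelta
from .graph import EdgeRecord, NodeRecord, OntologyGraph, Synonym
from .model import (Change, ChangeIdGenerator, ChangeSet, ClassCreation,
                    EdgeCreation, EdgeDeletion, NewSynonym, NewTextDefinition,
                    NodeDeletion, NodeMove, NodeObsoletion, NodeRef,
                    NodeRename, NodeTextDefinitionChange, PredicateChange,
                    RemoveSynonym, RemoveTextDefinition, SynonymReplacement)

__all__ = ["RawDelta", "raw_diff", "lift", "diff"]


@dataclass
class RawDelta:
    """The low-level set difference between two graphs."""

    nodes_added: set[str] = field(default_factory=set)
    nodes_removed: set[str] = field(default_factory=set)
    field_changed: list[tuple[str, str, object, object]] = field(default_factory=list)
    edges_added: set[EdgeRecord] = field(default_factory=set)
    edges_removed: set[EdgeRecord] = field(default_factory=set)

    def is_empty(self) -> bool:
        return not (self.nodes_added or self.nodes_removed or self.field_changed
                    or self.edges_added or self.edges_removed)


_SCALAR_FIELDS = ("label", "definition", "deprecated", "replaced_by", "node_kind")


def raw_diff(a: OntologyGraph, b: OntologyGraph) -> RawDelta:
    """Element-wise set difference keyed on node id and edge triple."""
    delta = RawDelta()
    delta.nodes_added = set(b.nodes) - set(a.nodes)
    delta.nodes_removed = set(a.nodes) - set(b.nodes)
    for nid in sorted(set(a.nodes) & set(b.nodes)):
        na, nb = a.nodes[nid], b.nodes[nid]
        for fname in _SCALAR_FIELDS:
            va, vb = getattr(na, fname), getattr(nb, fname)
            if va != vb:
                delta.field_changed.append((nid, fname, va, vb))
        for syn in na.synonyms - nb.synonyms:
            delta.field_changed.append((nid, "synonym_removed", syn, None))
        for syn in nb.synonyms - na.synonyms:
            delta.field_changed.append((nid, "synonym_added", None, syn))
    delta.edges_added = b.edges - a.edges
    delta.edges_removed = a.edges - b.edges
    return delta


def _curie(nid: str) -> NodeRef:
    return NodeRef(curie=nid)


_EMPTY = object()


def _lift_node_fields(nid: str, old: NodeRecord, new: NodeRecord,
                      created: bool) -> list[Change]:
    """Changes explaining how *old* became *new* for one surviving node
    (or, when ``created``, how a freshly created bare node acquires the rest
    of its content)."""
    changes: list[Change] = []
    ref = _curie(nid)

    if created:
        changes.append(ClassCreation(about_node=ref, name=new.label or ""))
        if new.node_kind != "class":
            raise UnliftableDelta(
                f"new node {nid} has kind {new.node_kind!r}; only class "
                "creation is expressible")
        if new.label is None:
            raise UnliftableDelta(f"new node {nid} has no label; class creation "
                                  "requires a name")
    elif old.label != new.label:
        if old.label is None or new.label is None:
            raise UnliftableDelta(f"node {nid}: a label cannot appear or vanish, "
                                  "only change")
        changes.append(NodeRename(about_node=ref, old_value=old.label,
                                  new_value=new.label))
    if not created and old.node_kind != new.node_kind:
        raise UnliftableDelta(f"node {nid}: node kind changed "
                              f"({old.node_kind!r} → {new.node_kind!r})")

    old_def = None if created else old.definition
    if old_def != new.definition:
        if old_def is None:
            changes.append(NewTextDefinition(about_node=ref,
                                             new_value=new.definition))
        elif new.definition is None:
            changes.append(RemoveTextDefinition(about_node=ref))
        else:
            changes.append(NodeTextDefinitionChange(about_node=ref,
                                                    new_value=new.definition,
                                                    old_value=old_def))

    old_syns = set() if created else set(old.synonyms)
    removed = sorted(old_syns - new.synonyms, key=Synonym.sort_key)
    added = sorted(new.synonyms - old_syns, key=Synonym.sort_key)
    # pair removed+added of equal scope into replacements, greedily in
    # lexicographic order — deterministic, and sound under any pairing
    by_scope_added: dict[str, list[Synonym]] = {}
    for syn in added:
        by_scope_added.setdefault(syn.scope, []).append(syn)
    for syn in removed:
        pool = by_scope_added.get(syn.scope)
        if pool:
            partner = pool.pop(0)
            changes.append(SynonymReplacement(about_node=ref,
                                              old_value=syn.value,
                                              new_value=partner.value))
        else:
            changes.append(RemoveSynonym(about_node=ref, old_value=syn.value))
    for scope in sorted(by_scope_added):
        for syn in by_scope_added[scope]:
            changes.append(NewSynonym(about_node=ref, new_value=syn.value,
                                      qualifier=syn.scope))

    old_dep = False if created else old.deprecated
    old_rep = None if created else old.replaced_by
    if old_dep != new.deprecated:
        if not new.deprecated:
            raise UnliftableDelta(f"node {nid}: un-deprecation is not expressible")
        replacement = None
        if new.replaced_by is not None and new.replaced_by != old_rep:
            replacement = _curie(new.replaced_by)
        changes.append(NodeObsoletion(about_node=ref,
                                      has_direct_replacement=replacement))
    elif old_rep != new.replaced_by:
        raise UnliftableDelta(
            f"node {nid}: replaced_by changed without a deprecation flip")
    return changes


# per-node ordering of lifted changes: creation first, then content edits,
# obsoletion after everything else the node keeps
_TYPE_RANK = {
    "ClassCreation": 0,
    "NodeRename": 1,
    "NewTextDefinition": 2,
    "NodeTextDefinitionChange": 2,
    "RemoveTextDefinition": 2,
    "SynonymReplacement": 3,
    "RemoveSynonym": 3,
    "NewSynonym": 3,
    "NodeObsoletion": 8,
    "NodeDeletion": 9,
}


def lift(delta: RawDelta, a: OntologyGraph, b: OntologyGraph) -> ChangeSet:
    """Lift a raw delta (computed from *a* and *b*) to high-level changes.

    Every raw delta element is consumed by exactly one emitted change, and the
    emitted set strict-applies to *a* yielding *b*.
    """
    node_changes: list[Change] = []

    for nid in sorted(delta.nodes_removed):
        node_changes.append(NodeDeletion(about_node=_curie(nid)))
    for nid in sorted(delta.nodes_added):
        node_changes.extend(
            _lift_node_fields(nid, NodeRecord(id=nid), b.nodes[nid], created=True))
    for nid in sorted({nid for nid, *_ in delta.field_changed}):
        node_changes.extend(
            _lift_node_fields(nid, a.nodes[nid], b.nodes[nid], created=False))

    node_changes.sort(key=lambda c: (
        (c.about_node.curie if getattr(c, "about_node", None) else ""),
        _TYPE_RANK.get(c.type_name, 5),
    ))

    # --- edges ----------------------------------------------------------
    # Simulate the edge side effects of the node changes: a deletion takes
    # incident edges, an obsoletion takes out-edges. Those removals are
    # consumed; only the residual difference needs explicit edge changes.
    deleted = delta.nodes_removed
    obsoleted = {c.about_node.curie for c in node_changes
                 if isinstance(c, NodeObsoletion)}
    after_node_ops = {
        e for e in a.edges
        if e.subject not in deleted and e.object not in deleted
        and e.subject not in obsoleted
    }
    removed = sorted(after_node_ops - b.edges,
                     key=lambda e: (e.subject, e.predicate, e.object))
    added = sorted(b.edges - after_node_ops,
                   key=lambda e: (e.subject, e.predicate, e.object))

    edge_changes: list[Change] = []
    added_pool = list(added)

    # rule 6: shared (subject, predicate) → NodeMove
    residual_removed: list[EdgeRecord] = []
    for edge in removed:
        partner = next((x for x in added_pool
                        if x.subject == edge.subject
                        and x.predicate == edge.predicate), None)
        if partner is not None and partner.subject not in obsoleted:
            added_pool.remove(partner)
            edge_changes.append(NodeMove(about_node=_curie(edge.subject),
                                         old_object=_curie(edge.object),
                                         new_object=_curie(partner.object),
                                         predicate=edge.predicate))
        else:
            residual_removed.append(edge)

    # rule 7: shared (subject, object) → PredicateChange
    still_removed: list[EdgeRecord] = []
    for edge in residual_removed:
        partner = next((x for x in added_pool
                        if x.subject == edge.subject
                        and x.object == edge.object), None)
        if partner is not None and partner.subject not in obsoleted:
            added_pool.remove(partner)
            edge_changes.append(PredicateChange(subject=_curie(edge.subject),
                                                object=_curie(edge.object),
                                                old_predicate=edge.predicate,
                                                new_predicate=partner.predicate))
        else:
            still_removed.append(edge)

    # rule 8: residuals
    for edge in still_removed:
        edge_changes.append(EdgeDeletion(subject=_curie(edge.subject),
                                         predicate=edge.predicate,
                                         object=_curie(edge.object)))
    for edge in added_pool:
        edge_changes.append(EdgeCreation(subject=_curie(edge.subject),
                                         predicate=edge.predicate,
                                         object=_curie(edge.object)))

    def _edge_key(c: Change):
        subject = getattr(c, "about_node", None) or getattr(c, "subject", None)
        order = {"NodeMove": 0, "PredicateChange": 1,
                 "EdgeDeletion": 2, "EdgeCreation": 3}[c.type_name]
        return (subject.curie, order)

    edge_changes.sort(key=_edge_key)
    return ChangeSet(node_changes + edge_changes)


def diff(a: OntologyGraph, b: OntologyGraph,
         id_generator: ChangeIdGenerator | None = None) -> ChangeSet:
    """The parsimonious change set transforming *a* into *b*.

    ``apply(diff(a, b), a)`` is graph-equal to *b* (provisional storage
    aside). Output is deterministic across runs and platforms.
    """
    cs = lift(raw_diff(a, b), a, b)
    return cs.with_ids(id_generator or ChangeIdGenerator())
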