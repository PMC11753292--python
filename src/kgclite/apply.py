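"""The apply engine: enact a change set on an ontology graph.

Changes are applied in order against the *evolving* graph, so a label used by
change *i* may have been introduced by an earlier change. Two modes:

* **strict** (default): every precondition is verified (current label equals
  the stated old value, an edge to delete exists, ...). The first failure
  raises and the input graph is returned untouched — application is atomic.
* **lenient**: old-value verification is skipped with a warning, and changes
  whose preconditions still fail are skipped and recorded in the report.

Obsoletion deprecates a node without deleting it, removes the node's own
out-edges (an obsolete term should assert nothing), and records a replacement
pointer when given. Incoming edges are left in place as dangling-reference
lint for downstream curation. Labels are not rewritten.

Provisional mode defers changes instead of enacting them: each change is
serialized to JSON and stored inside the graph as an annotation on the entity
it targets (under the :data:`~kgclite.vocab.PENDING_CHANGE_PRED` property),
until :func:`apply_pending` enacts and removes it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .errors import (AmbiguousLabel, PreconditionFailed, UnknownCurie,
                     UnknownLabel, UnknownPendingId, UnresolvableReference)
from .graph import EdgeRecord, NodeRecord, OntologyGraph, Synonym, resolve
from .model import (Change, ChangeSet, ClassCreation, EdgeCreation,
                    EdgeDeletion, NewSynonym, NewTextDefinition, NodeDeletion,
                    NodeMove, NodeObsoletion, NodeRef, NodeRename,
                    NodeTextDefinitionChange, PredicateChange, RemoveSynonym,
                    RemoveTextDefinition, SynonymReplacement)
from .serialize import change_from_dict, change_to_dict
from .vocab import DEFAULT_SYNONYM_SCOPE

__all__ = ["ApplyReport", "ApplyConfig", "apply", "store_provisional",
           "apply_pending"]


@dataclass
class ApplyConfig:
    """Knobs for the apply engine.

    ``id_namespace``/``id_start`` control CURIEs minted for class creations
    that do not supply one.
    """

    id_namespace: str = "EX"
    id_start: int = 1


@dataclass
class ApplyReport:
    """What happened: applied change ids, and (in lenient mode) skips with reasons."""

    applied: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    mode: str = "strict"


def _resolve(ref: NodeRef, graph: OntologyGraph, change: Change,
             require_present: bool = True) -> str:
    try:
        return resolve(ref, graph, strict=require_present)
    except (UnknownLabel, AmbiguousLabel, UnknownCurie) as exc:
        raise UnresolvableReference(f"change {change.id or '<unassigned>'}: {exc}") from exc


def _node(graph: OntologyGraph, ref: NodeRef, change: Change) -> NodeRecord:
    nid = _resolve(ref, graph, change)
    return graph.nodes[nid]


def apply(cs: ChangeSet, graph: OntologyGraph, mode: str = "strict",
          config: ApplyConfig | None = None) -> tuple[OntologyGraph, ApplyReport]:
    """Apply *cs* to a copy of *graph*; the input graph is never mutated.

    Returns the new graph and a report. In strict mode any failure raises
    (:class:`~kgclite.errors.PreconditionFailed` or
    :class:`~kgclite.errors.UnresolvableReference`) before a result exists,
    so the caller's graph is always consistent.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or ApplyConfig()
    out = graph.copy()
    report = ApplyReport(mode=mode)
    counter = config.id_start
    for change in cs:
        try:
            counter = _apply_one(change, out, mode, config, counter, report)
        except (PreconditionFailed, UnresolvableReference) as exc:
            if mode == "strict":
                raise
            report.skipped.append((change.id or "<unassigned>", str(exc)))
            continue
        report.applied.append(change.id or "<unassigned>")
    return out, report


def _fail(change: Change, detail: str) -> PreconditionFailed:
    return PreconditionFailed(change.id, detail)


def _verify(condition: bool, change: Change, detail: str, mode: str,
            report: ApplyReport) -> None:
    """Old-value checks: hard in strict mode, a warning in lenient mode."""
    if condition:
        return
    if mode == "strict":
        raise _fail(change, detail)
    report.warnings.append(f"change {change.id or '<unassigned>'}: {detail}")


def _apply_one(change: Change, g: OntologyGraph, mode: str, config: ApplyConfig,
               counter: int, report: ApplyReport) -> int:
    if isinstance(change, NodeRename):
        node = _node(g, change.about_node, change)
        _verify(node.label == change.old_value, change,
                f"label is {node.label!r}, expected {change.old_value!r}",
                mode, report)
        node.label = change.new_value

    elif isinstance(change, NodeObsoletion):
        node = _node(g, change.about_node, change)
        if node.deprecated:
            raise _fail(change, f"{node.id} is already deprecated")
        if change.has_direct_replacement is not None:
            # the replacement may live outside this graph (or be created by a
            # later change); a CURIE reference is taken at face value
            replacement = _resolve(change.has_direct_replacement, g, change,
                                   require_present=False)
            if replacement == node.id:
                raise _fail(change, "replacement equals the obsoleted node")
            node.replaced_by = replacement
        node.deprecated = True
        # an obsolete term should not assert anything of its own
        for edge in g.out_edges(node.id):
            g.edges.discard(edge)

    elif isinstance(change, NodeDeletion):
        nid = _resolve(change.about_node, g, change)
        for edge in g.incident_edges(nid):
            g.edges.discard(edge)
        del g.nodes[nid]

    elif isinstance(change, ClassCreation):
        if change.about_node is not None and change.about_node.curie is not None:
            nid = change.about_node.curie
        else:
            while f"{config.id_namespace}:{counter:07d}" in g.nodes:
                counter += 1
            nid = f"{config.id_namespace}:{counter:07d}"
            counter += 1
        if nid in g.nodes:
            raise _fail(change, f"node {nid} already exists")
        g.nodes[nid] = NodeRecord(id=nid, label=change.name, node_kind="class")

    elif isinstance(change, SynonymReplacement):
        node = _node(g, change.about_node, change)
        matches = [s for s in node.synonyms if s.value == change.old_value]
        if not matches:
            _verify(False, change,
                    f"{node.id} has no synonym {change.old_value!r}", mode, report)
            node.synonyms.add(Synonym(change.new_value, DEFAULT_SYNONYM_SCOPE))
        else:
            for syn in matches:
                node.synonyms.discard(syn)
                node.synonyms.add(Synonym(change.new_value, syn.scope))

    elif isinstance(change, NewSynonym):
        node = _node(g, change.about_node, change)
        scope = change.qualifier or DEFAULT_SYNONYM_SCOPE
        new = Synonym(change.new_value, scope)
        if new in node.synonyms:
            raise _fail(change, f"{node.id} already has {scope} synonym "
                                f"{change.new_value!r}")
        node.synonyms.add(new)

    elif isinstance(change, RemoveSynonym):
        node = _node(g, change.about_node, change)
        matches = [s for s in node.synonyms if s.value == change.old_value]
        if not matches:
            raise _fail(change, f"{node.id} has no synonym {change.old_value!r}")
        for syn in matches:
            node.synonyms.discard(syn)

    elif isinstance(change, NewTextDefinition):
        node = _node(g, change.about_node, change)
        if node.definition is not None:
            raise _fail(change, f"{node.id} already has a definition")
        node.definition = change.new_value

    elif isinstance(change, RemoveTextDefinition):
        node = _node(g, change.about_node, change)
        if node.definition is None:
            raise _fail(change, f"{node.id} has no definition")
        node.definition = None

    elif isinstance(change, NodeTextDefinitionChange):
        node = _node(g, change.about_node, change)
        if node.definition is None:
            raise _fail(change, f"{node.id} has no definition to change")
        if change.old_value is not None:
            _verify(node.definition == change.old_value, change,
                    f"definition of {node.id} does not match stated old value",
                    mode, report)
        node.definition = change.new_value

    elif isinstance(change, EdgeCreation):
        subject = _resolve(change.subject, g, change, require_present=False)
        obj = _resolve(change.object, g, change, require_present=False)
        edge = EdgeRecord(subject, change.predicate, obj)
        if edge in g.edges:
            if mode == "strict":
                raise _fail(change, f"edge ({subject} {change.predicate} {obj}) "
                                    "already exists")
            report.warnings.append(
                f"change {change.id or '<unassigned>'}: edge already exists (no-op)")
        g.edges.add(edge)

    elif isinstance(change, EdgeDeletion):
        subject = _resolve(change.subject, g, change, require_present=False)
        obj = _resolve(change.object, g, change, require_present=False)
        edge = EdgeRecord(subject, change.predicate, obj)
        if edge not in g.edges:
            raise _fail(change, f"edge ({subject} {change.predicate} {obj}) "
                                "is absent")
        g.edges.discard(edge)

    elif isinstance(change, NodeMove):
        nid = _resolve(change.about_node, g, change)
        new_obj = _resolve(change.new_object, g, change, require_present=False)
        if change.old_object is not None:
            old_obj = _resolve(change.old_object, g, change, require_present=False)
        else:
            parents = sorted(e.object for e in g.out_edges(nid)
                             if e.predicate == change.predicate)
            if len(parents) != 1:
                raise _fail(change, f"cannot infer source parent of {nid}: "
                                    f"{len(parents)} {change.predicate} parents")
            old_obj = parents[0]
        old_edge = EdgeRecord(nid, change.predicate, old_obj)
        new_edge = EdgeRecord(nid, change.predicate, new_obj)
        if old_edge not in g.edges:
            raise _fail(change, f"edge ({nid} {change.predicate} {old_obj}) "
                                "is absent")
        if new_edge in g.edges:
            raise _fail(change, f"edge ({nid} {change.predicate} {new_obj}) "
                                "already exists")
        g.edges.discard(old_edge)
        g.edges.add(new_edge)

    elif isinstance(change, PredicateChange):
        subject = _resolve(change.subject, g, change, require_present=False)
        obj = _resolve(change.object, g, change, require_present=False)
        old_edge = EdgeRecord(subject, change.old_predicate, obj)
        new_edge = EdgeRecord(subject, change.new_predicate, obj)
        if old_edge not in g.edges:
            raise _fail(change, f"edge ({subject} {change.old_predicate} {obj}) "
                                "is absent")
        if new_edge in g.edges:
            raise _fail(change, f"edge ({subject} {change.new_predicate} {obj}) "
                                "already exists")
        g.edges.discard(old_edge)
        g.edges.add(new_edge)

    else:
        raise _fail(change, f"unsupported change type {change.type_name}")
    return counter


# ---------------------------------------------------------------------------
# Provisional (deferred) changes


def _provisional_target(change: Change, graph: OntologyGraph) -> str | None:
    """The node a deferred change is annotated onto: its about-node, or the
    edge's subject; None (graph-level) when the target is not in the graph."""
    ref = getattr(change, "about_node", None) or getattr(change, "subject", None)
    if ref is None:
        return None
    if isinstance(change, ClassCreation):
        return None  # target does not exist yet
    try:
        return resolve(ref, graph, strict=True)
    except (UnknownLabel, AmbiguousLabel) as exc:
        raise UnresolvableReference(str(exc)) from exc
    except UnknownCurie:
        # the target may be created by an earlier pending change; keep the
        # annotation at graph level until it can be applied
        return None


def store_provisional(cs: ChangeSet, graph: OntologyGraph) -> OntologyGraph:
    """Store *cs* inside the graph as pending annotations; enact nothing.

    Each change is serialized to JSON and attached to the entity it targets,
    in changeset order. A ``seq`` field in the payload records the change's
    position so the order survives a save/load cycle (entries are regrouped
    per node on disk). The graph's content is otherwise untouched.
    """
    out = graph.copy()
    for change in cs:
        target = _provisional_target(change, out)
        payload = json.dumps({"seq": len(out.provisional),
                              **change_to_dict(change)},
                             ensure_ascii=False, sort_keys=False)
        out.provisional.append((target, payload))
    return out


def apply_pending(graph: OntologyGraph, selector="all", mode: str = "strict",
                  config: ApplyConfig | None = None
                  ) -> tuple[OntologyGraph, ApplyReport]:
    """Enact stored pending changes and remove them from storage.

    ``selector`` is ``"all"`` or an iterable of change ids. Pending entries
    are applied in storage order, which is the original changeset order even
    after a save/load cycle (each payload records its position).
    """
    entries = list(graph.provisional)
    changes = []
    for _nid, payload in entries:
        doc = json.loads(payload)
        doc.pop("seq", None)
        changes.append(change_from_dict(doc))
    if selector == "all":
        picked = list(range(len(entries)))
    else:
        wanted = list(selector)
        by_id: dict[str, int] = {}
        for i, change in enumerate(changes):
            if change.id is not None and change.id not in by_id:
                by_id[change.id] = i
        missing = [cid for cid in wanted if cid not in by_id]
        if missing:
            raise UnknownPendingId(f"no pending change(s) with id(s) {missing}")
        picked = sorted(by_id[cid] for cid in wanted)
    out, report = apply(ChangeSet(changes[i] for i in picked), graph,
                        mode=mode, config=config)
    remaining = [entries[i] for i in range(len(entries)) if i not in set(picked)]
    if mode == "lenient" and report.skipped:
        # keep entries whose application was skipped
        skipped_ids = {cid for cid, _ in report.skipped}
        for i in picked:
            if (changes[i].id or "<unassigned>") in skipped_ids:
                remaining.append(entries[i])
        warnings.warn(f"{len(report.skipped)} pending change(s) kept in storage "
                      "after failing to apply")
    out.provisional = remaining
    return out, report
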