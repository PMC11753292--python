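"""A minimal ontology/knowledge-graph container and its OBO Graphs JSON I/O.

The container is intentionally small: nodes with label / definition / scoped
synonyms / deprecation metadata, a set of subject–predicate–object edges, a
prefix map, and a slot for provisional (stored-but-not-applied) changes.
That is exactly the surface the change vocabulary touches; logical axioms
beyond plain edges are out of scope.

Interchange is OBO Graphs JSON: one document holds ``graphs``, each with
``nodes`` (id / lbl / type / meta) and ``edges`` (sub / pred / obj).
Definitions live at ``meta.definition.val``, synonyms at ``meta.synonyms``
(with the four oboInOwl scope predicates), deprecation at ``meta.deprecated``,
and the replacement pointer as a ``basicPropertyValues`` entry with predicate
IAO:0100001. Provisional changes are ``basicPropertyValues`` entries under
the dedicated :data:`~kgclite.vocab.PENDING_CHANGE_PRED` key.

Saving is deterministic (sorted nodes, edges and synonyms; fixed key order)
so that text diffs between saved documents are stable.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

from .errors import (AmbiguousLabel, DuplicateNodeId, ParseFailure,
                     UnknownCurie, UnknownLabel)
from .model import NodeRef
from .vocab import (PENDING_CHANGE_PRED, REPLACED_BY, SCOPE_TO_SYNONYM_PRED,
                    SYNONYM_PRED_TO_SCOPE, is_curie, normalize_predicate)

__all__ = [
    "Synonym",
    "NodeRecord",
    "EdgeRecord",
    "OntologyGraph",
    "GraphComparison",
    "load_graph",
    "loads_graph",
    "save_graph",
    "dumps_graph",
    "resolve",
    "graph_equal",
    "lint",
    "DEFAULT_PREFIX_MAP",
]

# IRIs compressed on load; CURIEs are kept verbatim internally.
DEFAULT_PREFIX_MAP: dict[str, str] = {
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "oboInOwl": "http://www.geneontology.org/formats/oboInOwl#",
    "IAO": "http://purl.obolibrary.org/obo/IAO_",
    "BFO": "http://purl.obolibrary.org/obo/BFO_",
    "RO": "http://purl.obolibrary.org/obo/RO_",
}

_OBO_BASE = "http://purl.obolibrary.org/obo/"


@dataclass(frozen=True)
class Synonym:
    """A synonym string with its scope relative to the primary label."""

    value: str
    scope: str = "related"

    def sort_key(self):
        return (self.value, self.scope)


@dataclass(frozen=True)
class EdgeRecord:
    """One subject–predicate–object triple; the triple is its own identity."""

    subject: str
    predicate: str
    object: str


@dataclass
class NodeRecord:
    """One term: identifier plus its curation-relevant metadata.

    Deprecated nodes stay in the graph — obsoletion marks, it never deletes.
    ``extras`` preserves document metadata this model does not interpret, so
    a load→save cycle is lossless on recognized content.
    """

    id: str
    label: Optional[str] = None
    definition: Optional[str] = None
    synonyms: set[Synonym] = field(default_factory=set)
    deprecated: bool = False
    replaced_by: Optional[str] = None
    node_kind: str = "class"  # class | relation | other
    extras: dict[str, Any] = field(default_factory=dict)

    def copy(self) -> "NodeRecord":
        return NodeRecord(
            id=self.id, label=self.label, definition=self.definition,
            synonyms=set(self.synonyms), deprecated=self.deprecated,
            replaced_by=self.replaced_by, node_kind=self.node_kind,
            extras=copy.deepcopy(self.extras),
        )


@dataclass
class OntologyGraph:
    """Nodes + edges + prefix map + provisional change storage.

    ``provisional`` is an ordered list of ``(node_id_or_None, json_text)``
    pairs: each entry is one serialized change annotated onto the node it
    targets (or onto the graph itself when the target node does not yet
    exist). List order is the order in which changes were stored.
    """

    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    edges: set[EdgeRecord] = field(default_factory=set)
    prefix_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PREFIX_MAP))
    provisional: list[tuple[Optional[str], str]] = field(default_factory=list)
    graph_id: Optional[str] = None
    extras: dict[str, Any] = field(default_factory=dict)

    def copy(self) -> "OntologyGraph":
        return OntologyGraph(
            nodes={i: n.copy() for i, n in self.nodes.items()},
            edges=set(self.edges),
            prefix_map=dict(self.prefix_map),
            provisional=list(self.provisional),
            graph_id=self.graph_id,
            extras=copy.deepcopy(self.extras),
        )

    def add_node(self, node: NodeRecord) -> None:
        if node.id in self.nodes:
            raise DuplicateNodeId(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def out_edges(self, node_id: str) -> list[EdgeRecord]:
        return [e for e in self.edges if e.subject == node_id]

    def incident_edges(self, node_id: str) -> list[EdgeRecord]:
        return [e for e in self.edges if node_id in (e.subject, e.object)]


# ---------------------------------------------------------------------------
# CURIE compression


def _compress_iri(iri: str, prefix_map: dict[str, str]) -> str:
    """Compress a full IRI to a CURIE via the prefix map; CURIEs pass through."""
    if "://" not in iri:
        return iri
    for prefix, base in prefix_map.items():
        if iri.startswith(base):
            return f"{prefix}:{iri[len(base):]}"
    if iri.startswith(_OBO_BASE):
        local = iri[len(_OBO_BASE):]
        if "_" in local:
            pfx, loc = local.split("_", 1)
            return f"{pfx}:{loc}"
    warnings.warn(f"no prefix for IRI {iri!r}; kept verbatim", stacklevel=3)
    return iri


def _norm_pred(pred: str, prefix_map: dict[str, str]) -> str:
    # "is_a" is the obographs shorthand for the subclass predicate
    return normalize_predicate(_compress_iri(pred, prefix_map))


# ---------------------------------------------------------------------------
# Loading


def loads_graph(text: str, prefix_map: dict[str, str] | None = None) -> OntologyGraph:
    """Parse one OBO Graphs JSON document into an :class:`OntologyGraph`.

    The document must hold exactly one graph; a multi-graph document is
    rejected rather than silently truncated.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseFailure(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "graphs" not in doc:
        raise ParseFailure("document has no 'graphs' key")
    graphs = doc["graphs"]
    if not isinstance(graphs, list) or not graphs:
        raise ParseFailure("'graphs' must be a non-empty list")
    if len(graphs) > 1:
        raise ParseFailure(f"expected one graph per document, found {len(graphs)}")
    gdoc = graphs[0]

    pmap = dict(DEFAULT_PREFIX_MAP)
    if prefix_map:
        pmap.update(prefix_map)
    pmap.update(doc.get("prefixes", {}))

    graph = OntologyGraph(prefix_map=pmap, graph_id=gdoc.get("id"))

    for ndoc in gdoc.get("nodes", []):
        if "id" not in ndoc:
            raise ParseFailure(f"node record without id: {ndoc!r}")
        node = _node_from_doc(ndoc, pmap, graph)
        if node.id in graph.nodes:
            raise DuplicateNodeId(f"duplicate node id {node.id!r}")
        graph.nodes[node.id] = node

    for edoc in gdoc.get("edges", []):
        for k in ("sub", "pred", "obj"):
            if k not in edoc:
                raise ParseFailure(f"edge record missing {k!r}: {edoc!r}")
        graph.edges.add(EdgeRecord(
            subject=_compress_iri(edoc["sub"], pmap),
            predicate=_norm_pred(edoc["pred"], pmap),
            object=_compress_iri(edoc["obj"], pmap),
        ))

    for key, value in gdoc.items():
        if key not in ("id", "nodes", "edges", "meta"):
            graph.extras[key] = value
    gmeta = gdoc.get("meta", {})
    for bpv in gmeta.get("basicPropertyValues", []):
        if _compress_iri(bpv.get("pred", ""), pmap) == PENDING_CHANGE_PRED:
            graph.provisional.append((None, bpv["val"]))
        else:
            graph.extras.setdefault("meta_basicPropertyValues", []).append(bpv)
    for key, value in gmeta.items():
        if key != "basicPropertyValues":
            graph.extras.setdefault("meta", {})[key] = value

    # Per-node pending entries collected after all nodes, sorted by node id so
    # the global order is deterministic (within-node order is preserved).
    for nid in sorted(graph.nodes):
        for val in graph.nodes[nid].extras.pop("_pending", []):
            graph.provisional.append((nid, val))
    # Payloads carry their original position in the deferred change set;
    # restore that order (entries without one keep their collection order).
    graph.provisional = [entry for _key, entry in sorted(
        (_pending_seq(payload, idx), (target, payload))
        for idx, (target, payload) in enumerate(graph.provisional))]
    return graph


def _pending_seq(payload: str, fallback: int) -> tuple[int, int]:
    try:
        seq = json.loads(payload).get("seq")
    except (ValueError, AttributeError):
        seq = None
    if isinstance(seq, int):
        return (0, seq)
    return (1, fallback)


def _node_from_doc(ndoc: dict, pmap: dict[str, str],
                   graph: OntologyGraph) -> NodeRecord:
    nid = _compress_iri(ndoc["id"], pmap)
    ntype = ndoc.get("type", "CLASS")
    kind = {"CLASS": "class", "PROPERTY": "relation"}.get(ntype, "other")
    node = NodeRecord(id=nid, label=ndoc.get("lbl"), node_kind=kind)
    meta = ndoc.get("meta", {})
    if "definition" in meta:
        node.definition = meta["definition"].get("val")
        defn_extras = {k: v for k, v in meta["definition"].items() if k != "val"}
        if defn_extras:
            node.extras["definition_extras"] = defn_extras
    for syn in meta.get("synonyms", []):
        pred = syn.get("pred", "hasRelatedSynonym")
        short = pred.rsplit("#", 1)[-1].rsplit(":", 1)[-1]
        scope = SYNONYM_PRED_TO_SCOPE.get(short)
        if scope is None:
            node.extras.setdefault("unrecognized_synonyms", []).append(syn)
            continue
        node.synonyms.add(Synonym(value=syn["val"], scope=scope))
    node.deprecated = bool(meta.get("deprecated", False))
    pending: list[str] = []
    for bpv in meta.get("basicPropertyValues", []):
        pred = _compress_iri(bpv.get("pred", ""), pmap)
        if pred == REPLACED_BY:
            node.replaced_by = _compress_iri(bpv["val"], pmap)
        elif pred == PENDING_CHANGE_PRED:
            pending.append(bpv["val"])
        else:
            node.extras.setdefault("basicPropertyValues", []).append(bpv)
    if pending:
        node.extras["_pending"] = pending
    for key, value in meta.items():
        if key not in ("definition", "synonyms", "deprecated", "basicPropertyValues"):
            node.extras.setdefault("meta", {})[key] = value
    for key, value in ndoc.items():
        if key not in ("id", "lbl", "type", "meta"):
            node.extras.setdefault("node", {})[key] = value
    return node


def load_graph(path) -> OntologyGraph:
    """Read one OBO Graphs JSON file."""
    with open(path, encoding="utf-8") as fh:
        return loads_graph(fh.read())


# ---------------------------------------------------------------------------
# Saving


def _node_to_doc(node: NodeRecord, pending: list[str]) -> dict:
    ndoc: dict[str, Any] = {"id": node.id}
    if node.label is not None:
        ndoc["lbl"] = node.label
    ndoc["type"] = {"class": "CLASS", "relation": "PROPERTY"}.get(node.node_kind, "OTHER")
    meta: dict[str, Any] = {}
    if node.definition is not None:
        meta["definition"] = {"val": node.definition}
        meta["definition"].update(node.extras.get("definition_extras", {}))
    syns = sorted(node.synonyms, key=Synonym.sort_key)
    syn_docs = [{"pred": SCOPE_TO_SYNONYM_PRED[s.scope], "val": s.value} for s in syns]
    syn_docs.extend(node.extras.get("unrecognized_synonyms", []))
    if syn_docs:
        meta["synonyms"] = syn_docs
    if node.deprecated:
        meta["deprecated"] = True
    bpvs: list[dict] = []
    if node.replaced_by is not None:
        bpvs.append({"pred": REPLACED_BY, "val": node.replaced_by})
    bpvs.extend(node.extras.get("basicPropertyValues", []))
    bpvs.extend({"pred": PENDING_CHANGE_PRED, "val": v} for v in pending)
    if bpvs:
        meta["basicPropertyValues"] = bpvs
    meta.update(node.extras.get("meta", {}))
    if meta:
        ndoc["meta"] = meta
    ndoc.update(node.extras.get("node", {}))
    return ndoc


def dumps_graph(graph: OntologyGraph) -> str:
    """Serialize to OBO Graphs JSON text; deterministic, ends with a newline."""
    pending_by_node: dict[Optional[str], list[str]] = {}
    for nid, val in graph.provisional:
        key = nid if nid in graph.nodes else None
        pending_by_node.setdefault(key, []).append(val)

    nodes = [_node_to_doc(graph.nodes[nid], pending_by_node.get(nid, []))
             for nid in sorted(graph.nodes)]
    edges = [{"sub": e.subject, "pred": _save_pred(e.predicate), "obj": e.object}
             for e in sorted(graph.edges,
                             key=lambda e: (e.subject, e.predicate, e.object))]
    gdoc: dict[str, Any] = {}
    if graph.graph_id is not None:
        gdoc["id"] = graph.graph_id
    gdoc["nodes"] = nodes
    gdoc["edges"] = edges
    gmeta: dict[str, Any] = {}
    bpvs = list(graph.extras.get("meta_basicPropertyValues", []))
    bpvs.extend({"pred": PENDING_CHANGE_PRED, "val": v}
                for v in pending_by_node.get(None, []))
    if bpvs:
        gmeta["basicPropertyValues"] = bpvs
    gmeta.update(graph.extras.get("meta", {}))
    if gmeta:
        gdoc["meta"] = gmeta
    for key, value in graph.extras.items():
        if key not in ("meta", "meta_basicPropertyValues"):
            gdoc[key] = value
    doc: dict[str, Any] = {"graphs": [gdoc]}
    if graph.prefix_map and graph.prefix_map != DEFAULT_PREFIX_MAP:
        doc["prefixes"] = dict(sorted(graph.prefix_map.items()))
    return json.dumps(doc, indent=2, ensure_ascii=False, sort_keys=False) + "\n"


def _save_pred(pred: str) -> str:
    # write the subclass predicate in the dialect's customary shorthand
    return "is_a" if pred == "rdfs:subClassOf" else pred


def save_graph(graph: OntologyGraph, path) -> None:
    """Write one OBO Graphs JSON file (atomically via a temp file + rename)."""
    import os
    import tempfile

    text = dumps_graph(graph)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Reference resolution


def resolve(ref: NodeRef, graph: OntologyGraph, strict: bool = False) -> str:
    """Resolve a node reference to a CURIE.

    A CURIE reference is returned unchanged (its presence in the graph is
    checked only in strict mode). A label reference must match exactly one
    node label, case-sensitively — ambiguity is an error, never a guess.
    """
    if ref.curie is not None:
        if strict and ref.curie not in graph.nodes:
            raise UnknownCurie(f"no node with id {ref.curie!r}")
        return ref.curie
    matches = [nid for nid, node in graph.nodes.items() if node.label == ref.label]
    if not matches:
        raise UnknownLabel(f"no node labeled {ref.label!r}")
    if len(matches) > 1:
        raise AmbiguousLabel(
            f"label {ref.label!r} matches {len(matches)} nodes: {sorted(matches)}")
    return matches[0]


# ---------------------------------------------------------------------------
# Equality and lint


@dataclass
class GraphComparison:
    """Result of :func:`graph_equal`: a verdict plus human-readable differences."""

    equal: bool
    differences: list[str] = field(default_factory=list)
    prefix_differences: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.equal


_NODE_FIELDS = ("label", "definition", "deprecated", "replaced_by", "node_kind")


def graph_equal(a: OntologyGraph, b: OntologyGraph,
                ignore_provisional: bool = False) -> GraphComparison:
    """Structural equality of node maps and edge sets, with a difference summary.

    Prefix maps are compared separately and reported, but never make two
    otherwise-equal graphs unequal.
    """
    diffs: list[str] = []
    only_a = sorted(set(a.nodes) - set(b.nodes))
    only_b = sorted(set(b.nodes) - set(a.nodes))
    diffs.extend(f"node {nid} only in first graph" for nid in only_a)
    diffs.extend(f"node {nid} only in second graph" for nid in only_b)
    for nid in sorted(set(a.nodes) & set(b.nodes)):
        na, nb = a.nodes[nid], b.nodes[nid]
        for fname in _NODE_FIELDS:
            va, vb = getattr(na, fname), getattr(nb, fname)
            if va != vb:
                diffs.append(f"node {nid}: {fname} {va!r} != {vb!r}")
        for syn in sorted(na.synonyms - nb.synonyms, key=Synonym.sort_key):
            diffs.append(f"node {nid}: synonym {syn.value!r} ({syn.scope}) "
                         "only in first graph")
        for syn in sorted(nb.synonyms - na.synonyms, key=Synonym.sort_key):
            diffs.append(f"node {nid}: synonym {syn.value!r} ({syn.scope}) "
                         "only in second graph")
        if na.extras != nb.extras:
            diffs.append(f"node {nid}: extras differ")
    for e in sorted(a.edges - b.edges, key=lambda e: (e.subject, e.predicate, e.object)):
        diffs.append(f"edge ({e.subject} {e.predicate} {e.object}) only in first graph")
    for e in sorted(b.edges - a.edges, key=lambda e: (e.subject, e.predicate, e.object)):
        diffs.append(f"edge ({e.subject} {e.predicate} {e.object}) only in second graph")
    if not ignore_provisional:
        pa = sorted(a.provisional, key=lambda t: (t[0] or "", t[1]))
        pb = sorted(b.provisional, key=lambda t: (t[0] or "", t[1]))
        if pa != pb:
            diffs.append("provisional change annotations differ")
    prefix_diffs = []
    for pfx in sorted(set(a.prefix_map) ^ set(b.prefix_map)):
        prefix_diffs.append(f"prefix {pfx!r} present in only one graph")
    for pfx in sorted(set(a.prefix_map) & set(b.prefix_map)):
        if a.prefix_map[pfx] != b.prefix_map[pfx]:
            prefix_diffs.append(f"prefix {pfx!r} expands differently")
    return GraphComparison(equal=not diffs, differences=diffs,
                           prefix_differences=prefix_diffs)


def lint(graph: OntologyGraph) -> list[str]:
    """Report structural oddities that are allowed but worth flagging."""
    warnings_: list[str] = []
    for e in sorted(graph.edges, key=lambda e: (e.subject, e.predicate, e.object)):
        for endpoint in (e.subject, e.object):
            if endpoint not in graph.nodes:
                warnings_.append(
                    f"edge ({e.subject} {e.predicate} {e.object}) references "
                    f"missing node {endpoint}")
    for nid, node in sorted(graph.nodes.items()):
        if node.replaced_by is not None and not node.deprecated:
            warnings_.append(f"node {nid} has replaced_by but is not deprecated")
        if not is_curie(nid):
            warnings_.append(f"node id {nid!r} is not a CURIE")
    return warnings_
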