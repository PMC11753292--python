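"""Programmatic test fixtures: synthetic ontology graphs and change sets.

Everything here is generated, seeded, and deterministic — no downloads, no
stored data files. :func:`generate_graph` builds a DAG-shaped hierarchy
(mostly is_a, a minority of part_of edges) with synthetic labels and optional
definitions/synonyms. :func:`random_changeset` samples changes of every type
that are *guaranteed to strict-apply*: it maintains a working copy of the
graph and applies each candidate as it is sampled, so the emitted sequence is
feasible by construction — the guarantee that makes apply∘diff property
suites meaningful.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .apply import ApplyConfig, apply
from .errors import InfeasibleChangeType
from .graph import EdgeRecord, NodeRecord, OntologyGraph, Synonym
from .model import (Change, ChangeIdGenerator, ChangeSet, ClassCreation,
                    EdgeCreation, EdgeDeletion, NewSynonym, NewTextDefinition,
                    NodeDeletion, NodeMove, NodeObsoletion, NodeRef,
                    NodeRename, NodeTextDefinitionChange, PredicateChange,
                    RemoveSynonym, RemoveTextDefinition, SynonymReplacement)
from .vocab import IS_A, PART_OF, SYNONYM_SCOPES

__all__ = ["FixtureSpec", "generate_graph", "random_changeset"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic ontology graph."""

    n_nodes: int = 20
    n_edges: int = 25
    p_definition: float = 0.5
    p_synonym: float = 0.5
    seed: int = 0
    namespace: str = "EX"

    def validate(self) -> None:
        if self.n_nodes < 0 or self.n_edges < 0:
            raise ValueError("n_nodes and n_edges must be non-negative")
        if not (0 <= self.p_definition <= 1 and 0 <= self.p_synonym <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError("n_edges exceeds the number of possible edges")


def generate_graph(spec: FixtureSpec) -> OntologyGraph:
    """Build a deterministic synthetic ontology graph from *spec*.

    Nodes get unique ids and labels; edges form a DAG (child → earlier node),
    ~80% is_a and the rest part_of.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    graph = OntologyGraph(graph_id=f"{spec.namespace.lower()}-fixture-{spec.seed}")
    ids = [f"{spec.namespace}:{i + 1:07d}" for i in range(spec.n_nodes)]
    for i, nid in enumerate(ids):
        node = NodeRecord(id=nid, label=f"term {i + 1}")
        if rng.random() < spec.p_definition:
            node.definition = f"A synthetic concept number {i + 1}."
        if rng.random() < spec.p_synonym:
            for k in range(rng.randint(1, 2)):
                node.synonyms.add(Synonym(value=f"synonym {k + 1} of term {i + 1}",
                                          scope=rng.choice(SYNONYM_SCOPES)))
        graph.nodes[nid] = node

    # candidate DAG edges: subject strictly later in creation order
    possible = [(i, j) for i in range(1, spec.n_nodes) for j in range(i)]
    rng.shuffle(possible)
    count = 0
    for i, j in possible:
        if count >= spec.n_edges:
            break
        pred = IS_A if rng.random() < 0.8 else PART_OF
        edge = EdgeRecord(ids[i], pred, ids[j])
        if edge in graph.edges:
            continue
        # avoid a duplicate pair with the other predicate to keep diffs crisp
        other = EdgeRecord(ids[i], PART_OF if pred == IS_A else IS_A, ids[j])
        if other in graph.edges:
            continue
        graph.edges.add(edge)
        count += 1
    if count < spec.n_edges:
        # dense spec: fill remaining slots with reverse-direction pairs
        for i, j in possible:
            if count >= spec.n_edges:
                break
            for pred in (IS_A, PART_OF):
                edge = EdgeRecord(ids[j], pred, ids[i])
                if count < spec.n_edges and edge not in graph.edges:
                    graph.edges.add(edge)
                    count += 1
    return graph


_ALL_TYPES = ("NodeRename", "NodeObsoletion", "NodeDeletion", "ClassCreation",
              "SynonymReplacement", "NewSynonym", "RemoveSynonym",
              "NewTextDefinition", "RemoveTextDefinition",
              "NodeTextDefinitionChange", "EdgeCreation", "EdgeDeletion",
              "NodeMove", "PredicateChange")


class _Sampler:
    """Draws one feasible change of a requested type from the working graph."""

    def __init__(self, graph: OntologyGraph, rng: random.Random, namespace: str):
        self.g = graph
        self.rng = rng
        self.namespace = namespace
        self._fresh = 0

    def _fresh_text(self, stem: str) -> str:
        self._fresh += 1
        return f"{stem} {self._fresh}"

    def _node_ids(self, predicate=None) -> list[str]:
        ids = sorted(self.g.nodes)
        if predicate is not None:
            ids = [i for i in ids if predicate(self.g.nodes[i])]
        return ids

    def _pick(self, ids: list[str]) -> str | None:
        return self.rng.choice(ids) if ids else None

    def sample(self, type_name: str) -> Change | None:
        return getattr(self, f"_s_{type_name}")()

    def _s_NodeRename(self):
        nid = self._pick(self._node_ids(lambda n: n.label is not None))
        if nid is None:
            return None
        return NodeRename(about_node=NodeRef(curie=nid),
                          old_value=self.g.nodes[nid].label,
                          new_value=self._fresh_text("renamed term"))

    def _s_NodeObsoletion(self):
        nid = self._pick(self._node_ids(lambda n: not n.deprecated))
        if nid is None:
            return None
        replacement = None
        others = [i for i in self._node_ids(lambda n: not n.deprecated) if i != nid]
        if others and self.rng.random() < 0.5:
            replacement = NodeRef(curie=self.rng.choice(others))
        return NodeObsoletion(about_node=NodeRef(curie=nid),
                              has_direct_replacement=replacement)

    def _s_NodeDeletion(self):
        nid = self._pick(self._node_ids())
        if nid is None:
            return None
        return NodeDeletion(about_node=NodeRef(curie=nid))

    def _s_ClassCreation(self):
        self._fresh += 1
        nid = f"{self.namespace}:{9000000 + self._fresh:07d}"
        while nid in self.g.nodes:
            self._fresh += 1
            nid = f"{self.namespace}:{9000000 + self._fresh:07d}"
        return ClassCreation(about_node=NodeRef(curie=nid),
                             name=self._fresh_text("created term"))

    def _syn_node(self):
        return self._pick(self._node_ids(lambda n: bool(n.synonyms)))

    def _s_SynonymReplacement(self):
        nid = self._syn_node()
        if nid is None:
            return None
        syn = sorted(self.g.nodes[nid].synonyms, key=Synonym.sort_key)[0]
        return SynonymReplacement(about_node=NodeRef(curie=nid),
                                  old_value=syn.value,
                                  new_value=self._fresh_text("replacement synonym"))

    def _s_NewSynonym(self):
        nid = self._pick(self._node_ids())
        if nid is None:
            return None
        qualifier = self.rng.choice(SYNONYM_SCOPES + (None,))
        return NewSynonym(about_node=NodeRef(curie=nid),
                          new_value=self._fresh_text("new synonym"),
                          qualifier=qualifier)

    def _s_RemoveSynonym(self):
        nid = self._syn_node()
        if nid is None:
            return None
        syn = sorted(self.g.nodes[nid].synonyms, key=Synonym.sort_key)[0]
        return RemoveSynonym(about_node=NodeRef(curie=nid), old_value=syn.value)

    def _s_NewTextDefinition(self):
        nid = self._pick(self._node_ids(lambda n: n.definition is None))
        if nid is None:
            return None
        return NewTextDefinition(about_node=NodeRef(curie=nid),
                                 new_value=self._fresh_text("A new definition"))

    def _s_RemoveTextDefinition(self):
        nid = self._pick(self._node_ids(lambda n: n.definition is not None))
        if nid is None:
            return None
        return RemoveTextDefinition(about_node=NodeRef(curie=nid))

    def _s_NodeTextDefinitionChange(self):
        nid = self._pick(self._node_ids(lambda n: n.definition is not None))
        if nid is None:
            return None
        old = self.g.nodes[nid].definition
        include_old = self.rng.random() < 0.5
        return NodeTextDefinitionChange(about_node=NodeRef(curie=nid),
                                        new_value=self._fresh_text("A changed definition"),
                                        old_value=old if include_old else None)

    def _s_EdgeCreation(self):
        ids = self._node_ids()
        if len(ids) < 2:
            return None
        for _ in range(30):
            s, o = self.rng.sample(ids, 2)
            pred = self.rng.choice((IS_A, PART_OF))
            if (EdgeRecord(s, pred, o) not in self.g.edges
                    and not self.g.nodes[s].deprecated):
                return EdgeCreation(subject=NodeRef(curie=s), predicate=pred,
                                    object=NodeRef(curie=o))
        return None

    def _existing_edge(self):
        edges = sorted(self.g.edges, key=lambda e: (e.subject, e.predicate, e.object))
        return self.rng.choice(edges) if edges else None

    def _s_EdgeDeletion(self):
        edge = self._existing_edge()
        if edge is None:
            return None
        return EdgeDeletion(subject=NodeRef(curie=edge.subject),
                            predicate=edge.predicate,
                            object=NodeRef(curie=edge.object))

    def _s_NodeMove(self):
        edges = sorted(self.g.edges, key=lambda e: (e.subject, e.predicate, e.object))
        self.rng.shuffle(edges)
        ids = self._node_ids()
        for edge in edges:
            candidates = [o for o in ids
                          if o not in (edge.subject, edge.object)
                          and EdgeRecord(edge.subject, edge.predicate, o)
                          not in self.g.edges]
            if candidates:
                new_obj = self.rng.choice(candidates)
                return NodeMove(about_node=NodeRef(curie=edge.subject),
                                old_object=NodeRef(curie=edge.object),
                                new_object=NodeRef(curie=new_obj),
                                predicate=edge.predicate)
        return None

    def _s_PredicateChange(self):
        edges = sorted(self.g.edges, key=lambda e: (e.subject, e.predicate, e.object))
        self.rng.shuffle(edges)
        for edge in edges:
            new_pred = PART_OF if edge.predicate == IS_A else IS_A
            if EdgeRecord(edge.subject, new_pred, edge.object) not in self.g.edges:
                return PredicateChange(subject=NodeRef(curie=edge.subject),
                                       object=NodeRef(curie=edge.object),
                                       old_predicate=edge.predicate,
                                       new_predicate=new_pred)
        return None


def random_changeset(graph: OntologyGraph, n_changes: int, seed: int = 0,
                     type_weights: dict[str, float] | None = None,
                     namespace: str = "EX") -> ChangeSet:
    """Sample *n_changes* changes that strict-apply, in order, to *graph*.

    The sampler simulates application while drawing, so the result is feasible
    by construction. ``type_weights`` biases the draw (types absent from the
    dict get weight 0 when the dict is given; default is uniform over all 14
    types). Raises :class:`~kgclite.errors.InfeasibleChangeType` when no
    requested type can be hosted by the evolving graph.
    """
    if type_weights is None:
        weights = {t: 1.0 for t in _ALL_TYPES}
    else:
        unknown = set(type_weights) - set(_ALL_TYPES)
        if unknown:
            raise ValueError(f"unknown change type(s) in weights: {sorted(unknown)}")
        weights = {t: w for t, w in type_weights.items() if w > 0}
    rng = random.Random(seed)
    working = graph.copy()
    sampler = _Sampler(working, rng, namespace)
    gen = ChangeIdGenerator()
    changes: list[Change] = []
    for _ in range(n_changes):
        available = dict(weights)
        change = None
        while available:
            names = sorted(available)
            type_name = rng.choices(names,
                                    weights=[available[t] for t in names])[0]
            change = sampler.sample(type_name)
            if change is not None:
                break
            del available[type_name]
        if change is None:
            raise InfeasibleChangeType(
                f"graph cannot host any of the requested change types "
                f"after {len(changes)} changes")
        change = change.with_id(gen.next_id())
        working_new, _report = apply(ChangeSet([change]), working,
                                     config=ApplyConfig(id_namespace=namespace))
        sampler.g = working_new
        working = working_new
        changes.append(change)
    return ChangeSet(changes)
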