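"""The change data model: a typed hierarchy of ontology/KG edit operations.

Every edit an ontology curator commonly performs — renaming a term,
obsoleting it, editing definitions and synonyms, rewiring edges — is one
concrete subclass of :class:`Change`. The hierarchy has two branches:
node changes (:class:`NodeChange`) and edge changes (:class:`EdgeChange`).

Changes are plain frozen dataclasses. Constructing an ill-formed change never
raises; :func:`validate` reports invariant violations as a list of messages so
that callers (CLIs, bots) can surface all problems at once. The ``id`` field
tracks a change through a workflow and is deliberately excluded from equality:
two NodeRenames describing the same edit are the same edit.
"""

from __future__ import annotations

import itertools
import uuid
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Optional

from .errors import NotInvertible
from .vocab import SYNONYM_SCOPES, is_curie

__all__ = [
    "NodeRef",
    "Change",
    "NodeChange",
    "EdgeChange",
    "NodeRename",
    "NodeObsoletion",
    "NodeDeletion",
    "ClassCreation",
    "SynonymReplacement",
    "NewSynonym",
    "RemoveSynonym",
    "NewTextDefinition",
    "RemoveTextDefinition",
    "NodeTextDefinitionChange",
    "EdgeCreation",
    "EdgeDeletion",
    "NodeMove",
    "PredicateChange",
    "ChangeSet",
    "ChangeIdGenerator",
    "CHANGE_TYPES",
    "invert",
    "validate",
]


@dataclass(frozen=True)
class NodeRef:
    """A reference to a node, by CURIE, by label, or both.

    Commands may name terms either way ("obsolete 'trachea'" vs
    "obsolete UBERON:0003126"); resolution against a graph happens late,
    in the apply engine.
    """

    curie: Optional[str] = None
    label: Optional[str] = None

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.curie if self.curie else f"'{self.label}'"


def ref(value: str | NodeRef) -> NodeRef:
    """Coerce a bare string into a NodeRef (CURIE-shaped → curie, else label)."""
    if isinstance(value, NodeRef):
        return value
    if is_curie(value):
        return NodeRef(curie=value)
    return NodeRef(label=value)


@dataclass(frozen=True)
class Change:
    """Abstract base: one atomic edit. ``id`` is workflow metadata, not identity."""

    id: Optional[str] = field(default=None, compare=False, kw_only=True)

    @property
    def type_name(self) -> str:
        return type(self).__name__

    def with_id(self, change_id: str) -> "Change":
        return replace(self, id=change_id)


@dataclass(frozen=True)
class NodeChange(Change):
    """A change affecting a single node (term)."""


@dataclass(frozen=True)
class EdgeChange(Change):
    """A change affecting one edge (relationship) or a pair of edges."""


@dataclass(frozen=True)
class NodeRename(NodeChange):
    """The node's name (rdfs:label) changes from old_value to new_value."""

    about_node: NodeRef = None  # type: ignore[assignment]
    old_value: str = ""
    new_value: str = ""


@dataclass(frozen=True)
class NodeObsoletion(NodeChange):
    """Deprecate the node without deleting it, optionally naming a replacement."""

    about_node: NodeRef = None  # type: ignore[assignment]
    has_direct_replacement: Optional[NodeRef] = None


@dataclass(frozen=True)
class NodeDeletion(NodeChange):
    """Remove the node (and its incident edges) from the graph."""

    about_node: NodeRef = None  # type: ignore[assignment]


@dataclass(frozen=True)
class ClassCreation(NodeChange):
    """Create a new class node with the given name.

    ``about_node`` may carry an explicit CURIE; when absent, the apply engine
    mints one. Definitions and synonyms for the new class are supplied by
    follow-up changes.
    """

    about_node: Optional[NodeRef] = None
    name: str = ""


@dataclass(frozen=True)
class SynonymReplacement(NodeChange):
    """The text of an existing synonym changes; its scope is kept."""

    about_node: NodeRef = None  # type: ignore[assignment]
    old_value: str = ""
    new_value: str = ""


@dataclass(frozen=True)
class NewSynonym(NodeChange):
    """Add a synonym, optionally scoped (exact | narrow | broad | related)."""

    about_node: NodeRef = None  # type: ignore[assignment]
    new_value: str = ""
    qualifier: Optional[str] = None


@dataclass(frozen=True)
class RemoveSynonym(NodeChange):
    """Remove the synonym with the given text (any scope)."""

    about_node: NodeRef = None  # type: ignore[assignment]
    old_value: str = ""


@dataclass(frozen=True)
class NewTextDefinition(NodeChange):
    """Give a node a de novo text definition."""

    about_node: NodeRef = None  # type: ignore[assignment]
    new_value: str = ""


@dataclass(frozen=True)
class RemoveTextDefinition(NodeChange):
    """Delete a node's text definition."""

    about_node: NodeRef = None  # type: ignore[assignment]


@dataclass(frozen=True)
class NodeTextDefinitionChange(NodeChange):
    """Replace a node's text definition.

    ``old_value`` is optional; when present, the apply engine verifies it
    against the current definition before overwriting.
    """

    about_node: NodeRef = None  # type: ignore[assignment]
    new_value: str = ""
    old_value: Optional[str] = None


@dataclass(frozen=True)
class EdgeCreation(EdgeChange):
    """Assert a de novo subject–predicate–object edge."""

    subject: NodeRef = None  # type: ignore[assignment]
    predicate: str = ""
    object: NodeRef = None  # type: ignore[assignment]


@dataclass(frozen=True)
class EdgeDeletion(EdgeChange):
    """Retract an existing edge."""

    subject: NodeRef = None  # type: ignore[assignment]
    predicate: str = ""
    object: NodeRef = None  # type: ignore[assignment]


@dataclass(frozen=True)
class NodeMove(EdgeChange):
    """Re-parent a node: delete (node, pred, old_object), add (node, pred, new_object).

    ``old_object`` may be left unset (the short command form "move X under Y");
    the apply engine then infers it when the node has exactly one parent edge
    with the given predicate.
    """

    about_node: NodeRef = None  # type: ignore[assignment]
    new_object: NodeRef = None  # type: ignore[assignment]
    old_object: Optional[NodeRef] = None
    predicate: str = "rdfs:subClassOf"


@dataclass(frozen=True)
class PredicateChange(EdgeChange):
    """Keep an edge's endpoints but change its predicate."""

    subject: NodeRef = None  # type: ignore[assignment]
    object: NodeRef = None  # type: ignore[assignment]
    old_predicate: str = ""
    new_predicate: str = ""


#: Every concrete change type, keyed by its canonical name.
CHANGE_TYPES: dict[str, type[Change]] = {
    cls.__name__: cls
    for cls in (
        NodeRename,
        NodeObsoletion,
        NodeDeletion,
        ClassCreation,
        SynonymReplacement,
        NewSynonym,
        RemoveSynonym,
        NewTextDefinition,
        RemoveTextDefinition,
        NodeTextDefinitionChange,
        EdgeCreation,
        EdgeDeletion,
        NodeMove,
        PredicateChange,
    )
}


@dataclass(frozen=True)
class ChangeSet:
    """An ordered sequence of changes, applied first-to-last."""

    changes: tuple[Change, ...] = ()

    def __init__(self, changes=()):
        object.__setattr__(self, "changes", tuple(changes))

    def __len__(self) -> int:
        return len(self.changes)

    def __iter__(self) -> Iterator[Change]:
        return iter(self.changes)

    def __getitem__(self, i):
        return self.changes[i]

    def with_ids(self, generator: "ChangeIdGenerator") -> "ChangeSet":
        """Return a copy in which every change without an id gets a fresh one."""
        return ChangeSet(
            c if c.id else c.with_id(generator.next_id()) for c in self.changes
        )


class ChangeIdGenerator:
    """Mint change ids.

    Defaults to a monotonically numbered, zero-padded scheme
    (``kgcl:000001``, ...), so runs are reproducible and the numeric order of
    ids mirrors the order in which changes were created. Pass ``use_uuid=True``
    for UUID4 ids; with a ``seed``, the UUID stream is itself reproducible.
    """

    def __init__(self, prefix: str = "kgcl", start: int = 1,
                 use_uuid: bool = False, seed: int | None = None):
        self.prefix = prefix
        self._counter = itertools.count(start)
        self._use_uuid = use_uuid
        if use_uuid and seed is not None:
            import random

            self._rng = random.Random(seed)
        else:
            self._rng = None

    def next_id(self) -> str:
        if self._use_uuid:
            if self._rng is not None:
                return str(uuid.UUID(int=self._rng.getrandbits(128), version=4))
            return str(uuid.uuid4())
        return f"{self.prefix}:{next(self._counter):06d}"


def new_change_id(generator: ChangeIdGenerator | None = None) -> str:
    """Mint one change id from *generator* (a fresh default generator if None)."""
    return (generator or ChangeIdGenerator()).next_id()


# ---------------------------------------------------------------------------
# Inversion


def invert(change: Change) -> Change:
    """Return the change that undoes *change*.

    Defined exactly for the types whose fields determine their inverse:
    renames, synonym/definition replacements carrying the old value, edge
    creations/deletions, moves and predicate changes. Obsoletions, deletions
    and removals that do not store what they removed raise
    :class:`~kgclite.errors.NotInvertible`.
    """
    if isinstance(change, NodeRename):
        return NodeRename(about_node=change.about_node,
                          old_value=change.new_value, new_value=change.old_value)
    if isinstance(change, SynonymReplacement):
        return SynonymReplacement(about_node=change.about_node,
                                  old_value=change.new_value, new_value=change.old_value)
    if isinstance(change, NewSynonym):
        return RemoveSynonym(about_node=change.about_node, old_value=change.new_value)
    if isinstance(change, NewTextDefinition):
        return RemoveTextDefinition(about_node=change.about_node)
    if isinstance(change, NodeTextDefinitionChange):
        if change.old_value is None:
            raise NotInvertible("NodeTextDefinitionChange without old_value")
        return NodeTextDefinitionChange(about_node=change.about_node,
                                        new_value=change.old_value,
                                        old_value=change.new_value)
    if isinstance(change, ClassCreation):
        about = change.about_node or NodeRef(label=change.name)
        return NodeDeletion(about_node=about)
    if isinstance(change, EdgeCreation):
        return EdgeDeletion(subject=change.subject, predicate=change.predicate,
                            object=change.object)
    if isinstance(change, EdgeDeletion):
        return EdgeCreation(subject=change.subject, predicate=change.predicate,
                            object=change.object)
    if isinstance(change, NodeMove):
        if change.old_object is None:
            raise NotInvertible("NodeMove without an explicit old_object")
        return NodeMove(about_node=change.about_node, new_object=change.old_object,
                        old_object=change.new_object, predicate=change.predicate)
    if isinstance(change, PredicateChange):
        return PredicateChange(subject=change.subject, object=change.object,
                               old_predicate=change.new_predicate,
                               new_predicate=change.old_predicate)
    raise NotInvertible(f"{change.type_name} has no defined inverse")


# ---------------------------------------------------------------------------
# Validation


def _check_ref(value, name: str, violations: list[str], required: bool = True) -> None:
    if value is None:
        if required:
            violations.append(f"{name} is required")
        return
    if not isinstance(value, NodeRef):
        violations.append(f"{name} must be a NodeRef")
        return
    if value.curie is None and value.label is None:
        violations.append(f"{name} must carry a curie or a label")
        return
    if value.curie is not None and not is_curie(value.curie):
        violations.append(f"{name}.curie {value.curie!r} is not prefix:localpart")


def _nonempty(value, name: str, violations: list[str]) -> None:
    if not isinstance(value, str) or not value:
        violations.append(f"{name} must be a non-empty string")


def validate(change: Change) -> list[str]:
    """Check every invariant of *change*; return violation messages (empty = valid).

    Total: never raises, whatever the field values.
    """
    v: list[str] = []
    if not isinstance(change, Change):
        return ["not a Change"]
    if type(change) not in CHANGE_TYPES.values():
        return [f"{type(change).__name__} is not a concrete change type"]
    if change.id is not None and (not isinstance(change.id, str) or not change.id):
        v.append("id, when present, must be a non-empty string")

    if isinstance(change, NodeRename):
        _check_ref(change.about_node, "about_node", v)
        _nonempty(change.old_value, "old_value", v)
        _nonempty(change.new_value, "new_value", v)
        if change.old_value == change.new_value:
            v.append("old_value must differ from new_value")
    elif isinstance(change, NodeObsoletion):
        _check_ref(change.about_node, "about_node", v)
        _check_ref(change.has_direct_replacement, "has_direct_replacement", v,
                   required=False)
        if (change.has_direct_replacement is not None
                and change.has_direct_replacement == change.about_node):
            v.append("replacement must differ from the obsoleted node")
    elif isinstance(change, NodeDeletion):
        _check_ref(change.about_node, "about_node", v)
    elif isinstance(change, ClassCreation):
        _check_ref(change.about_node, "about_node", v, required=False)
        _nonempty(change.name, "name", v)
    elif isinstance(change, SynonymReplacement):
        _check_ref(change.about_node, "about_node", v)
        _nonempty(change.old_value, "old_value", v)
        _nonempty(change.new_value, "new_value", v)
        if change.old_value == change.new_value:
            v.append("old_value must differ from new_value")
    elif isinstance(change, NewSynonym):
        _check_ref(change.about_node, "about_node", v)
        _nonempty(change.new_value, "new_value", v)
        if change.qualifier is not None and change.qualifier not in SYNONYM_SCOPES:
            v.append(f"qualifier must be one of {SYNONYM_SCOPES}")
    elif isinstance(change, RemoveSynonym):
        _check_ref(change.about_node, "about_node", v)
        _nonempty(change.old_value, "old_value", v)
    elif isinstance(change, NewTextDefinition):
        _check_ref(change.about_node, "about_node", v)
        _nonempty(change.new_value, "new_value", v)
    elif isinstance(change, RemoveTextDefinition):
        _check_ref(change.about_node, "about_node", v)
    elif isinstance(change, NodeTextDefinitionChange):
        _check_ref(change.about_node, "about_node", v)
        _nonempty(change.new_value, "new_value", v)
        if change.old_value is not None and not change.old_value:
            v.append("old_value, when present, must be non-empty")
    elif isinstance(change, (EdgeCreation, EdgeDeletion)):
        _check_ref(change.subject, "subject", v)
        _check_ref(change.object, "object", v)
        _nonempty(change.predicate, "predicate", v)
        if change.subject is not None and change.subject == change.object:
            v.append("subject must differ from object")
    elif isinstance(change, NodeMove):
        _check_ref(change.about_node, "about_node", v)
        _check_ref(change.new_object, "new_object", v)
        _check_ref(change.old_object, "old_object", v, required=False)
        _nonempty(change.predicate, "predicate", v)
        if change.old_object is not None and change.old_object == change.new_object:
            v.append("old_object must differ from new_object")
    elif isinstance(change, PredicateChange):
        _check_ref(change.subject, "subject", v)
        _check_ref(change.object, "object", v)
        _nonempty(change.old_predicate, "old_predicate", v)
        _nonempty(change.new_predicate, "new_predicate", v)
        if change.old_predicate == change.new_predicate:
            v.append("old_predicate must differ from new_predicate")
    return v


def validate_changeset(cs: ChangeSet) -> list[str]:
    """Validate every member and the pairwise distinctness of assigned ids."""
    v: list[str] = []
    seen: set[str] = set()
    for i, c in enumerate(cs):
        for msg in validate(c):
            v.append(f"change {i} ({c.type_name}): {msg}")
        if c.id is not None:
            if c.id in seen:
                v.append(f"change {i}: duplicate id {c.id!r}")
            seen.add(c.id)
    return v
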