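"""Lossless change-set serialization: JSON, YAML, and a fixed-column TSV.

JSON and YAML carry the data model attributes verbatim (``type``, ``id``,
``about_node``, ``old_value``, ``new_value``, ...) and are
information-equivalent. Node references collapse to a single string — a CURIE
as-is, a label wrapped in single quotes — mirroring the CNL's dual reference
style.

The tabular form uses nine fixed columns
(id, type, about_node, old_value, new_value, subject, predicate, object,
qualifier) for spreadsheet use. It is lossy *by restriction only*: a change
whose values cannot sit in those columns (embedded tabs/newlines) raises
:class:`~kgclite.errors.NotTabularizable` instead of degrading silently.
"""

from __future__ import annotations

import csv
import io
import json
import warnings

import yaml

from .errors import (MissingField, NotTabularizable, TableParseError,
                     UnknownChangeType, UnknownField)
from .model import CHANGE_TYPES, Change, ChangeSet, NodeRef
from .vocab import is_curie

__all__ = [
    "to_document",
    "from_document",
    "change_to_dict",
    "change_from_dict",
    "to_table",
    "from_table",
    "TABLE_COLUMNS",
]

# (attribute, kind, required); kind: str | ref | pred
_FIELDS: dict[str, tuple[tuple[str, str, bool], ...]] = {
    "NodeRename": (("about_node", "ref", True), ("old_value", "str", True),
                   ("new_value", "str", True)),
    "NodeObsoletion": (("about_node", "ref", True),
                       ("has_direct_replacement", "ref", False)),
    "NodeDeletion": (("about_node", "ref", True),),
    "ClassCreation": (("about_node", "ref", False), ("name", "str", True)),
    "SynonymReplacement": (("about_node", "ref", True), ("old_value", "str", True),
                           ("new_value", "str", True)),
    "NewSynonym": (("about_node", "ref", True), ("new_value", "str", True),
                   ("qualifier", "str", False)),
    "RemoveSynonym": (("about_node", "ref", True), ("old_value", "str", True)),
    "NewTextDefinition": (("about_node", "ref", True), ("new_value", "str", True)),
    "RemoveTextDefinition": (("about_node", "ref", True),),
    "NodeTextDefinitionChange": (("about_node", "ref", True),
                                 ("new_value", "str", True),
                                 ("old_value", "str", False)),
    "EdgeCreation": (("subject", "ref", True), ("predicate", "pred", True),
                     ("object", "ref", True)),
    "EdgeDeletion": (("subject", "ref", True), ("predicate", "pred", True),
                     ("object", "ref", True)),
    "NodeMove": (("about_node", "ref", True), ("old_object", "ref", False),
                 ("new_object", "ref", True), ("predicate", "pred", True)),
    "PredicateChange": (("subject", "ref", True), ("object", "ref", True),
                        ("old_predicate", "pred", True),
                        ("new_predicate", "pred", True)),
}


def _ref_to_str(ref: NodeRef) -> str:
    if ref.curie is not None:
        return ref.curie
    escaped = ref.label.replace("\\", "\\\\").replace("'", "\\'")
    return f"'{escaped}'"


def _ref_from_str(text: str) -> NodeRef:
    if len(text) >= 2 and text[0] == "'" and text[-1] == "'":
        label = text[1:-1].replace("\\'", "'").replace("\\\\", "\\")
        return NodeRef(label=label)
    if is_curie(text):
        return NodeRef(curie=text)
    # bare non-CURIE text: read as a label for robustness
    return NodeRef(label=text)


def change_to_dict(change: Change) -> dict:
    """One change → a flat dict with deterministic key order (type, id, fields)."""
    type_name = change.type_name
    if type_name not in _FIELDS:
        raise UnknownChangeType(f"{type_name} is not a serializable change type")
    out: dict = {"type": type_name}
    if change.id is not None:
        out["id"] = change.id
    for attr, kind, _required in _FIELDS[type_name]:
        value = getattr(change, attr)
        if value is None:
            continue
        out[attr] = _ref_to_str(value) if kind == "ref" else value
    return out


def change_from_dict(doc: dict, strict: bool = True) -> Change:
    """Inverse of :func:`change_to_dict`.

    Unknown change-type names are always rejected; unknown keys are rejected
    in strict mode and warned about otherwise.
    """
    if "type" not in doc:
        raise UnknownChangeType("serialized change has no 'type' key")
    type_name = doc["type"]
    if type_name not in CHANGE_TYPES:
        raise UnknownChangeType(f"unknown change type {type_name!r}")
    fields = _FIELDS[type_name]
    known = {attr for attr, _k, _r in fields} | {"type", "id"}
    unknown = sorted(set(doc) - known)
    if unknown:
        msg = f"{type_name}: unknown field(s) {unknown}"
        if strict:
            raise UnknownField(msg)
        warnings.warn(msg, stacklevel=2)
    kwargs: dict = {}
    for attr, kind, required in fields:
        if attr not in doc or doc[attr] is None or doc[attr] == "":
            if required:
                raise MissingField(type_name, attr)
            continue
        value = doc[attr]
        if not isinstance(value, str):
            raise MissingField(type_name, attr)
        kwargs[attr] = _ref_from_str(value) if kind == "ref" else value
    change = CHANGE_TYPES[type_name](**kwargs)
    if doc.get("id"):
        change = change.with_id(doc["id"])
    return change


# ---------------------------------------------------------------------------
# JSON / YAML documents


def to_document(cs: ChangeSet, format: str = "json") -> str:
    """Serialize a ChangeSet as a JSON or YAML list of change objects."""
    docs = [change_to_dict(c) for c in cs]
    if format == "json":
        return json.dumps(docs, indent=2, ensure_ascii=False) + "\n"
    if format == "yaml":
        return yaml.safe_dump(docs, sort_keys=False, allow_unicode=True,
                              default_flow_style=False)
    raise ValueError(f"unknown format {format!r} (expected 'json' or 'yaml')")


def from_document(text: str, format: str = "json", strict: bool = True) -> ChangeSet:
    """Parse a JSON or YAML change-set document."""
    if format == "json":
        docs = json.loads(text)
    elif format == "yaml":
        docs = yaml.safe_load(text)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'json' or 'yaml')")
    if docs is None:
        docs = []
    if isinstance(docs, dict):
        docs = [docs]  # a single change object is accepted as a one-element set
    if not isinstance(docs, list):
        raise UnknownChangeType("document must be a list of change objects")
    return ChangeSet(change_from_dict(d, strict=strict) for d in docs)


# ---------------------------------------------------------------------------
# Tabular (TSV)

TABLE_COLUMNS = ("id", "type", "about_node", "old_value", "new_value",
                 "subject", "predicate", "object", "qualifier")

# attribute → table column, per type, where the attribute name is not itself
# a column. NodeMove's endpoints and PredicateChange's predicates ride in the
# old_value/new_value columns; the type column disambiguates.
_TABLE_ALIASES: dict[str, dict[str, str]] = {
    "NodeObsoletion": {"has_direct_replacement": "new_value"},
    "ClassCreation": {"name": "new_value"},
    "NodeMove": {"old_object": "old_value", "new_object": "new_value"},
    "PredicateChange": {"old_predicate": "old_value", "new_predicate": "new_value"},
}


def to_table(cs: ChangeSet) -> str:
    """Render a ChangeSet as TSV with the fixed column header."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n",
                        quoting=csv.QUOTE_NONE, quotechar=None, escapechar=None)
    writer.writerow(TABLE_COLUMNS)
    for change in cs:
        flat = change_to_dict(change)
        aliases = _TABLE_ALIASES.get(change.type_name, {})
        row = {col: "" for col in TABLE_COLUMNS}
        for key, value in flat.items():
            col = aliases.get(key, key)
            if col not in row:
                raise NotTabularizable(
                    f"{change.type_name}.{key} has no tabular column")
            if "\t" in value or "\n" in value or "\r" in value:
                raise NotTabularizable(
                    f"{change.type_name}.{key} contains a tab or newline")
            row[col] = value
        writer.writerow(row[col] for col in TABLE_COLUMNS)
    return buf.getvalue()


def from_table(text: str, strict: bool = True) -> ChangeSet:
    """Parse the fixed-column TSV form back into a ChangeSet."""
    reader = csv.reader(io.StringIO(text), delimiter="\t",
                        quoting=csv.QUOTE_NONE, quotechar=None, escapechar=None)
    rows = [row for row in reader]
    if not rows:
        return ChangeSet()
    header = tuple(rows[0])
    if header != TABLE_COLUMNS:
        raise TableParseError(
            f"unexpected header {header!r}; expected {TABLE_COLUMNS!r}")
    changes = []
    for rownum, row in enumerate(rows[1:], start=2):
        if not any(row):
            continue
        if len(row) != len(TABLE_COLUMNS):
            raise TableParseError(
                f"row {rownum}: {len(row)} columns, expected {len(TABLE_COLUMNS)}")
        record = dict(zip(TABLE_COLUMNS, row))
        type_name = record.pop("type")
        if type_name not in CHANGE_TYPES:
            raise UnknownChangeType(f"row {rownum}: unknown change type {type_name!r}")
        aliases = _TABLE_ALIASES.get(type_name, {})
        inverse = {col: attr for attr, col in aliases.items()}
        doc = {"type": type_name}
        for col, value in record.items():
            if value == "":
                continue
            doc[inverse.get(col, col)] = value
        changes.append(change_from_dict(doc, strict=strict))
    return ChangeSet(changes)
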