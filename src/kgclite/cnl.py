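"""The controlled natural language (CNL): parse and render change commands.

The CNL is the canonical human-facing syntax for changes — restricted English,
one command per line, keyword-led so that every line parses to at most one
change type::

    rename UBERON:0002398 from 'hand' to 'manus'
    obsolete 'trachea'
    obsolete EX:1234 with replacement EX:5678
    create exact synonym 'thigh bone' for 'femur'
    move 'Parkinson disease' under 'neurodegenerative disease'

Nodes are written as CURIEs or quoted labels; the parser accepts straight
single, straight double, and typographic quotes, while the renderer always
emits straight single quotes. Leading keywords match case-insensitively and a
trailing sentence period is tolerated, so commands printed inside prose still
parse. A quoted token whose content is CURIE-shaped (e.g. "obsolete
'UBERON:0003126'") is read as a CURIE reference.

The grammar is documented in EBNF form in ``grammar/kgcl.ebnf`` alongside
this module. One extension beyond the core grammar: ``move`` accepts an
optional ``via <pred>`` suffix so that re-parenting over a non-hierarchy
predicate survives a render→parse round trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import BlockParseError, CnlSyntaxError, UnrenderableChange
from .model import (Change, ChangeIdGenerator, ChangeSet, ClassCreation,
                    EdgeCreation, EdgeDeletion, NewSynonym, NewTextDefinition,
                    NodeDeletion, NodeMove, NodeObsoletion, NodeRef,
                    NodeRename, NodeTextDefinitionChange, PredicateChange,
                    RemoveSynonym, RemoveTextDefinition, SynonymReplacement,
                    validate)
from .vocab import (IS_A, SYNONYM_SCOPES, is_curie, normalize_predicate,
                    predicate_alias)

__all__ = ["parse_command", "render_command", "parse_block", "render_block"]

# Opening quote character → set of accepted closers.
_QUOTE_PAIRS = {
    "'": {"'"},
    '"': {'"'},
    "‘": {"’"},  # ‘ ’
    "“": {"”"},  # “ ”
}


@dataclass(frozen=True)
class _Token:
    kind: str  # "w" (word) or "q" (quoted)
    value: str


def _tokenize(line: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(line)
    while i < n:
        ch = line[i]
        if ch.isspace():
            i += 1
            continue
        if ch in _QUOTE_PAIRS:
            closers = _QUOTE_PAIRS[ch]
            i += 1
            buf: list[str] = []
            closed = False
            while i < n:
                c = line[i]
                if c == "\\" and i + 1 < n and (line[i + 1] in closers
                                                or line[i + 1] == "\\"):
                    buf.append(line[i + 1])
                    i += 2
                    continue
                if c in closers:
                    closed = True
                    i += 1
                    break
                buf.append(c)
                i += 1
            if not closed:
                raise CnlSyntaxError(f"unterminated quote starting at column {i}")
            tokens.append(_Token("q", "".join(buf)))
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            tokens.append(_Token("w", line[i:j]))
            i = j
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token], line: str):
        self.tokens = tokens
        self.line = line
        self.pos = 0

    def peek(self) -> Optional[_Token]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise CnlSyntaxError(f"unexpected end of command: {self.line!r}")
        self.pos += 1
        return tok

    def at_word(self, *keywords: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == "w" and tok.value.lower() in keywords

    def expect_word(self, keyword: str) -> None:
        tok = self.take()
        if tok.kind != "w" or tok.value.lower() != keyword:
            raise CnlSyntaxError(
                f"expected {keyword!r}, found {tok.value!r}", token=tok.value)

    def take_quoted(self, what: str) -> str:
        tok = self.take()
        if tok.kind != "q":
            raise CnlSyntaxError(
                f"expected quoted {what}, found {tok.value!r}", token=tok.value)
        return tok.value

    def take_node(self) -> NodeRef:
        tok = self.take()
        if tok.kind == "q":
            # a quoted CURIE-shaped token names the term by id, not by label
            if is_curie(tok.value):
                return NodeRef(curie=tok.value)
            return NodeRef(label=tok.value)
        if is_curie(tok.value):
            return NodeRef(curie=tok.value)
        raise CnlSyntaxError(
            f"expected a CURIE or quoted label, found {tok.value!r}", token=tok.value)

    def take_pred(self) -> str:
        tok = self.take()
        return normalize_predicate(tok.value)

    def end(self) -> None:
        tok = self.peek()
        if tok is not None:
            raise CnlSyntaxError(
                f"unexpected trailing token {tok.value!r}", token=tok.value)


_PRODUCTIONS = (
    "rename", "obsolete", "delete node", "delete edge", "create",
    "create synonym", "create edge", "remove synonym", "replace synonym",
    "add definition", "add synonym", "remove definition", "change definition",
    "change relationship", "move",
)


def parse_command(text: str) -> Change:
    """Parse one CNL command line into a change object.

    Node references stay as written (label or CURIE); no graph is consulted.
    The returned change carries no id. Raises
    :class:`~kgclite.errors.CnlSyntaxError` on any line outside the grammar.
    """
    line = text.strip()
    for bullet in ("- ", "* ", "• "):
        if line.startswith(bullet):
            line = line[len(bullet):].strip()
    # tolerate one trailing sentence period (commands printed inside prose)
    if line.endswith("."):
        line = line[:-1].rstrip()
    tokens = _tokenize(line)
    if not tokens:
        raise CnlSyntaxError("empty command")
    head = tokens[0]
    if head.kind != "w":
        raise CnlSyntaxError(f"command must start with a keyword, found a quoted "
                             f"string {head.value!r}", token=head.value)
    p = _Parser(tokens, line)
    keyword = p.take().value.lower()
    handler = _HANDLERS.get(keyword)
    if handler is None:
        raise CnlSyntaxError(
            f"unknown command keyword {keyword!r}; expected one of: "
            f"{', '.join(sorted(set(w.split()[0] for w in _PRODUCTIONS)))}",
            token=keyword)
    change = handler(p)
    p.end()
    return change


def _parse_rename(p: _Parser) -> Change:
    node = p.take_node()
    p.expect_word("from")
    old = p.take_quoted("old name")
    p.expect_word("to")
    new = p.take_quoted("new name")
    return NodeRename(about_node=node, old_value=old, new_value=new)


def _parse_obsolete(p: _Parser) -> Change:
    node = p.take_node()
    replacement = None
    if p.at_word("with"):
        p.expect_word("with")
        p.expect_word("replacement")
        replacement = p.take_node()
    return NodeObsoletion(about_node=node, has_direct_replacement=replacement)


def _parse_delete(p: _Parser) -> Change:
    if p.at_word("node"):
        p.expect_word("node")
        return NodeDeletion(about_node=p.take_node())
    if p.at_word("edge"):
        p.expect_word("edge")
        subject = p.take_node()
        pred = p.take_pred()
        obj = p.take_node()
        return EdgeDeletion(subject=subject, predicate=pred, object=obj)
    tok = p.peek()
    raise CnlSyntaxError(
        "delete requires the noun 'node' or 'edge' "
        f"(found {tok.value!r})" if tok else "delete requires 'node' or 'edge'",
        token=tok.value if tok else None)


def _parse_synonym_tail(p: _Parser, qualifier: Optional[str]) -> Change:
    value = p.take_quoted("synonym")
    p.expect_word("for")
    node = p.take_node()
    return NewSynonym(about_node=node, new_value=value, qualifier=qualifier)


def _parse_create(p: _Parser) -> Change:
    tok = p.peek()
    if tok is None:
        raise CnlSyntaxError("create requires an argument")
    if tok.kind == "w":
        word = tok.value.lower()
        if word == "edge":
            p.take()
            subject = p.take_node()
            pred = p.take_pred()
            obj = p.take_node()
            return EdgeCreation(subject=subject, predicate=pred, object=obj)
        if word in SYNONYM_SCOPES:
            p.take()
            p.expect_word("synonym")
            return _parse_synonym_tail(p, word)
        if word == "synonym":
            p.take()
            return _parse_synonym_tail(p, None)
        raise CnlSyntaxError(
            f"after 'create', expected a quoted name, 'edge', or "
            f"'[scope] synonym', found {tok.value!r}", token=tok.value)
    name = p.take_quoted("class name")
    return ClassCreation(name=name)


def _parse_remove(p: _Parser) -> Change:
    if p.at_word("synonym"):
        p.expect_word("synonym")
        value = p.take_quoted("synonym")
        p.expect_word("for")
        return RemoveSynonym(about_node=p.take_node(), old_value=value)
    if p.at_word("definition"):
        p.expect_word("definition")
        p.expect_word("for")
        return RemoveTextDefinition(about_node=p.take_node())
    tok = p.peek()
    raise CnlSyntaxError(
        f"after 'remove', expected 'synonym' or 'definition'"
        + (f", found {tok.value!r}" if tok else ""),
        token=tok.value if tok else None)


def _parse_replace(p: _Parser) -> Change:
    p.expect_word("synonym")
    old = p.take_quoted("old synonym")
    p.expect_word("with")
    new = p.take_quoted("new synonym")
    p.expect_word("for")
    return SynonymReplacement(about_node=p.take_node(), old_value=old, new_value=new)


def _parse_add(p: _Parser) -> Change:
    if p.at_word("definition"):
        p.expect_word("definition")
        value = p.take_quoted("definition")
        p.expect_word("to")
        return NewTextDefinition(about_node=p.take_node(), new_value=value)
    # "add [scope] synonym <q> to <node>" — accepted as an input alias for
    # synonym creation; the canonical rendering uses "create ... synonym".
    qualifier = None
    if p.peek() is not None and p.peek().kind == "w" \
            and p.peek().value.lower() in SYNONYM_SCOPES:
        qualifier = p.take().value.lower()
    if p.at_word("synonym"):
        p.expect_word("synonym")
        value = p.take_quoted("synonym")
        p.expect_word("to")
        return NewSynonym(about_node=p.take_node(), new_value=value,
                          qualifier=qualifier)
    tok = p.peek()
    raise CnlSyntaxError(
        f"after 'add', expected 'definition' or '[scope] synonym'"
        + (f", found {tok.value!r}" if tok else ""),
        token=tok.value if tok else None)


def _parse_change(p: _Parser) -> Change:
    if p.at_word("definition"):
        p.expect_word("definition")
        p.expect_word("of")
        node = p.take_node()
        p.expect_word("to")
        new = p.take_quoted("definition")
        return NodeTextDefinitionChange(about_node=node, new_value=new)
    if p.at_word("relationship"):
        p.expect_word("relationship")
        p.expect_word("between")
        subject = p.take_node()
        p.expect_word("and")
        obj = p.take_node()
        p.expect_word("from")
        old_pred = p.take_pred()
        p.expect_word("to")
        new_pred = p.take_pred()
        return PredicateChange(subject=subject, object=obj,
                               old_predicate=old_pred, new_predicate=new_pred)
    tok = p.peek()
    raise CnlSyntaxError(
        f"after 'change', expected 'definition' or 'relationship'"
        + (f", found {tok.value!r}" if tok else ""),
        token=tok.value if tok else None)


def _parse_move(p: _Parser) -> Change:
    node = p.take_node()
    if p.at_word("under"):
        p.expect_word("under")
        new_obj = p.take_node()
        old_obj = None
    elif p.at_word("from"):
        p.expect_word("from")
        old_obj = p.take_node()
        p.expect_word("to")
        new_obj = p.take_node()
    else:
        tok = p.peek()
        raise CnlSyntaxError(
            f"after 'move <node>', expected 'under' or 'from'"
            + (f", found {tok.value!r}" if tok else ""),
            token=tok.value if tok else None)
    predicate = IS_A
    if p.at_word("via"):
        p.expect_word("via")
        predicate = p.take_pred()
    return NodeMove(about_node=node, new_object=new_obj, old_object=old_obj,
                    predicate=predicate)


_HANDLERS = {
    "rename": _parse_rename,
    "obsolete": _parse_obsolete,
    "delete": _parse_delete,
    "create": _parse_create,
    "remove": _parse_remove,
    "replace": _parse_replace,
    "add": _parse_add,
    "change": _parse_change,
    "move": _parse_move,
}


# ---------------------------------------------------------------------------
# Rendering


def _q(value: str) -> str:
    escaped = value.replace("\\", "\\\\").replace("'", "\\'")
    return f"'{escaped}'"


def _n(ref: NodeRef, what: str = "node") -> str:
    if ref is None:
        raise UnrenderableChange(f"{what} reference is missing")
    if ref.curie is not None:
        return ref.curie
    if ref.label is None:
        raise UnrenderableChange(f"{what} reference has neither curie nor label")
    return _q(ref.label)


def render_command(change: Change) -> str:
    """Render a change in canonical CNL: lowercase keyword, straight single
    quotes, CURIEs bare, predicates as their bare aliases.

    ``parse_command(render_command(c)) == c`` for every change the CNL can
    express. Two fields have no CNL slot and are dropped when present: an
    explicit CURIE on a ClassCreation (the CNL names new classes only by
    label) and the old_value of a NodeTextDefinitionChange.
    """
    problems = [m for m in validate(change) if "is required" in m or "missing" in m]
    if problems:
        raise UnrenderableChange("; ".join(problems))
    if isinstance(change, NodeRename):
        return (f"rename {_n(change.about_node)} from {_q(change.old_value)} "
                f"to {_q(change.new_value)}")
    if isinstance(change, NodeObsoletion):
        base = f"obsolete {_n(change.about_node)}"
        if change.has_direct_replacement is not None:
            base += f" with replacement {_n(change.has_direct_replacement)}"
        return base
    if isinstance(change, NodeDeletion):
        return f"delete node {_n(change.about_node)}"
    if isinstance(change, ClassCreation):
        if not change.name:
            raise UnrenderableChange("ClassCreation without a name")
        return f"create {_q(change.name)}"
    if isinstance(change, SynonymReplacement):
        return (f"replace synonym {_q(change.old_value)} with "
                f"{_q(change.new_value)} for {_n(change.about_node)}")
    if isinstance(change, NewSynonym):
        scope = f"{change.qualifier} " if change.qualifier else ""
        return (f"create {scope}synonym {_q(change.new_value)} "
                f"for {_n(change.about_node)}")
    if isinstance(change, RemoveSynonym):
        return f"remove synonym {_q(change.old_value)} for {_n(change.about_node)}"
    if isinstance(change, NewTextDefinition):
        return f"add definition {_q(change.new_value)} to {_n(change.about_node)}"
    if isinstance(change, RemoveTextDefinition):
        return f"remove definition for {_n(change.about_node)}"
    if isinstance(change, NodeTextDefinitionChange):
        return (f"change definition of {_n(change.about_node)} "
                f"to {_q(change.new_value)}")
    if isinstance(change, EdgeCreation):
        return (f"create edge {_n(change.subject)} "
                f"{predicate_alias(change.predicate)} {_n(change.object)}")
    if isinstance(change, EdgeDeletion):
        return (f"delete edge {_n(change.subject)} "
                f"{predicate_alias(change.predicate)} {_n(change.object)}")
    if isinstance(change, NodeMove):
        if change.old_object is None:
            base = f"move {_n(change.about_node)} under {_n(change.new_object)}"
        else:
            base = (f"move {_n(change.about_node)} from {_n(change.old_object)} "
                    f"to {_n(change.new_object)}")
        if change.predicate != IS_A:
            base += f" via {predicate_alias(change.predicate)}"
        return base
    if isinstance(change, PredicateChange):
        return (f"change relationship between {_n(change.subject)} and "
                f"{_n(change.object)} from {predicate_alias(change.old_predicate)} "
                f"to {predicate_alias(change.new_predicate)}")
    raise UnrenderableChange(f"no CNL form for {change.type_name}")


# ---------------------------------------------------------------------------
# Blocks


def parse_block(text: str, id_generator: ChangeIdGenerator | None = None) -> ChangeSet:
    """Parse a multi-line block of commands into a ChangeSet.

    Blank lines and '#' comment lines are skipped; leading bullets are
    stripped; a header line ending in "apply:" (the bot-invocation form) is
    ignored. Every remaining line must parse — on any failure a
    :class:`~kgclite.errors.BlockParseError` lists all failing lines and no
    partial set is returned. Ids are assigned in order.
    """
    gen = id_generator or ChangeIdGenerator()
    changes: list[Change] = []
    errors: list[CnlSyntaxError] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().rstrip().endswith("apply:"):
            continue
        try:
            changes.append(parse_command(line).with_id(gen.next_id()))
        except CnlSyntaxError as exc:
            errors.append(CnlSyntaxError(str(exc), line=lineno, token=exc.token))
    if errors:
        raise BlockParseError(errors)
    return ChangeSet(changes)


def render_block(cs: ChangeSet, bullets: bool = False) -> str:
    """Render a ChangeSet as one canonical command per line."""
    prefix = "- " if bullets else ""
    return "\n".join(prefix + render_command(c) for c in cs)
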