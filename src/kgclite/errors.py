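"""Exception hierarchy shared across the package.

Violations of *data* invariants are reported as values by
:func:`kgclite.model.validate`; exceptions are reserved for operations that
cannot produce a result (parse failures, unresolvable references,
precondition failures during apply, ...).
"""

from __future__ import annotations


class KgclError(Exception):
    """Base class for all package-specific errors."""


# ---------------------------------------------------------------------------
# CNL / serialization


class CnlSyntaxError(KgclError):
    """A command line does not match any production of the CNL grammar.

    Carries the offending token and the candidate productions when known.
    """

    def __init__(self, message: str, *, line: int | None = None, token: str | None = None):
        self.line = line
        self.token = token
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class BlockParseError(KgclError):
    """Aggregated syntax errors from a multi-line command block."""

    def __init__(self, errors: list[CnlSyntaxError]):
        self.errors = errors
        super().__init__("; ".join(str(e) for e in errors))


class UnrenderableChange(KgclError):
    """A change lacks a field that the CNL rendering requires."""


class UnknownChangeType(KgclError):
    """A serialized document names a change type outside the model."""


class MissingField(KgclError):
    """A serialized change omits a mandatory field."""

    def __init__(self, type_name: str, field: str):
        self.type_name = type_name
        self.field = field
        super().__init__(f"{type_name} is missing required field {field!r}")


class UnknownField(KgclError):
    """A serialized change carries a key the model does not define (strict mode)."""


class NotTabularizable(KgclError):
    """A change cannot be expressed in the fixed tabular columns."""


class TableParseError(KgclError):
    """A TSV document is structurally malformed (e.g. ragged row)."""


# ---------------------------------------------------------------------------
# Graph I/O and reference resolution


class ParseFailure(KgclError):
    """An ontology document is not well-formed in the expected dialect."""


class DuplicateNodeId(ParseFailure):
    """Two node records share an id."""


class UnknownLabel(KgclError):
    """A label reference matches no node."""


class AmbiguousLabel(KgclError):
    """A label reference matches more than one node."""


class UnknownCurie(KgclError):
    """A CURIE reference names a node absent from the graph (strict mode)."""


class UnresolvableReference(KgclError):
    """Umbrella for resolution failures raised while applying changes."""


# ---------------------------------------------------------------------------
# Apply / diff engines


class PreconditionFailed(KgclError):
    """The graph does not satisfy a change's precondition (strict mode)."""

    def __init__(self, change_id: str | None, detail: str):
        self.change_id = change_id
        self.detail = detail
        super().__init__(f"change {change_id or '<unassigned>'}: {detail}")


class UnknownPendingId(KgclError):
    """A pending-change selector names an id not stored in the graph."""


class NotInvertible(KgclError):
    """The change type does not determine its own inverse."""


class UnliftableDelta(KgclError):
    """A raw graph delta has no counterpart in the change vocabulary.

    Examples: a node flipping from deprecated back to active, a node changing
    kind, or a new node that is not a class.
    """


class InfeasibleChangeType(KgclError):
    """The graph cannot host a requested random change type."""
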