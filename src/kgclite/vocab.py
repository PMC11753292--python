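"""Shared controlled vocabulary: synonym scopes, predicate aliases, CURIEs.

Predicates are held internally as CURIEs. The alias table maps the bare
identifiers conventionally written in commands (``is_a``, ``part_of``) to
their CURIEs and back; it can be extended by callers that work with other
hierarchy predicates.
"""

from __future__ import annotations

import re

# The four standard synonym scopes, in canonical order.
SYNONYM_SCOPES = ("exact", "narrow", "broad", "related")

# oboInOwl annotation properties marking each scope.
SCOPE_TO_SYNONYM_PRED = {
    "exact": "hasExactSynonym",
    "narrow": "hasNarrowSynonym",
    "broad": "hasBroadSynonym",
    "related": "hasRelatedSynonym",
}
SYNONYM_PRED_TO_SCOPE = {v: k for k, v in SCOPE_TO_SYNONYM_PRED.items()}

# Scope used when a new synonym is created without an explicit qualifier;
# "related" is the weakest claim and the customary default in OBO tooling.
DEFAULT_SYNONYM_SCOPE = "related"

IS_A = "rdfs:subClassOf"
PART_OF = "BFO:0000050"

# Bare-identifier aliases accepted in commands and emitted by the renderer.
PREDICATE_ALIASES = {
    "is_a": IS_A,
    "subClassOf": IS_A,
    "part_of": PART_OF,
}
# Reverse map; prefer the canonical alias for each CURIE.
CURIE_TO_ALIAS = {IS_A: "is_a", PART_OF: "part_of"}

# Annotation property pointing from an obsoleted term to its replacement
# ("term replaced by").
REPLACED_BY = "IAO:0100001"

# Property key under which provisional (not-yet-applied) changes are stored
# inside the ontology document.
PENDING_CHANGE_PRED = "KGCL:pendingChange"

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*:[A-Za-z0-9_.#-]+$")


def is_curie(text: str) -> bool:
    """True if *text* is syntactically a prefix:localpart CURIE."""
    return bool(_CURIE_RE.match(text)) and "//" not in text


def normalize_predicate(pred: str) -> str:
    """Map a bare alias to its CURIE; pass CURIEs and unknown tokens through."""
    return PREDICATE_ALIASES.get(pred, pred)


def predicate_alias(pred: str) -> str:
    """Render a predicate CURIE as its bare alias when one is defined."""
    return CURIE_TO_ALIAS.get(pred, pred)
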