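# Methods

This note records the model implemented by `kgclite`, the parameters and
their defaults, the numerical/tie-breaking choices, and the known
limitations. It is written in the package's own terms; the README gives the
motivation and a worked example.

## Change model

A change is a frozen dataclass in one of two branches: **node changes**
(`NodeRename`, `NodeObsoletion`, `NodeDeletion`, `ClassCreation`,
`SynonymReplacement`, `NewSynonym`, `RemoveSynonym`, `NewTextDefinition`,
`RemoveTextDefinition`, `NodeTextDefinitionChange`) and **edge changes**
(`EdgeCreation`, `EdgeDeletion`, `NodeMove`, `PredicateChange`) — 14
concrete types. Entity references are `NodeRef(curie=..., label=...)`
values: exactly one of the two is set. Each change carries an optional `id`
that is excluded from equality, so two structurally identical changes
compare equal regardless of bookkeeping ids. Sequential ids
(`kgcl:000001`, ...) sort in creation order; a seeded-UUID mode exists for
globally unique ids.

`validate(change)` is total: it returns a list of human-readable invariant
violations (old and new value must differ, synonym qualifier must be a known
scope, CURIEs must look like `prefix:localpart`, ...) and never raises, even
on garbage field types. `invert(change)` returns the undoing change where
one is determined by the change itself: renames, moves, predicate changes
and definition changes carrying their old value swap fields; creations and
deletions of edges swap type; `ClassCreation` inverts to `NodeDeletion`
(one-way). Changes that do not store the prior state (`NodeObsoletion`,
`NodeDeletion`, `RemoveSynonym`, `RemoveTextDefinition`, and
`NodeTextDefinitionChange` without `old_value`) raise `NotInvertible`
rather than guess.

## Controlled natural language

The grammar (documented in `src/kgclite/grammar/kgcl.ebnf`) is keyword-led
and unambiguous: the first word of a command determines a unique parse, so a
hand-written tokenizer plus recursive-descent parser suffices and gives
precise error messages (line and offending token). Lexical tolerance is
deliberate, because commands are pasted from documents and issue comments:
straight and typographic single/double quotes are accepted, keywords are
case-insensitive, one trailing period is ignored, and `-`/`*`/`•` bullets
are stripped. A quoted token shaped like a CURIE is treated as a CURIE
reference, since labels that look like `prefix:localpart` are not realistic
and CURIEs in quotes are common in practice.

Rendering is canonical: lowercase keywords, straight single quotes with
backslash escaping, bare predicate aliases (`is_a`, `part_of`). `parse ∘
render` is the identity on every change except two documented elisions: the
CNL names a created class by label only (an explicitly chosen CURIE is not
expressible), and the definition-change form carries no old value. `move X
under Y` leaves the source parent implicit (the apply engine infers it when
it is unique); a `via <predicate>` suffix extends the move forms to
non-`is_a` hierarchies.

Multi-line blocks skip blank lines, `#` comments, and a leading bot
invocation line ending in `apply:`; any bad line fails the whole block with
all line-numbered errors aggregated.

## Graph model and the OBO Graphs dialect

`OntologyGraph` holds nodes (id, label, definition, scoped synonyms,
deprecation flag, replacement pointer), a set of subject–predicate–object
edges, a prefix map, and an ordered list of provisional changes. The
on-disk format is single-graph OBO Graphs JSON: definitions under
`meta.definition.val`, synonyms under `meta.synonyms` with the four
`oboInOwl` scope predicates, deprecation under `meta.deprecated`, the
replacement pointer as an `IAO:0100001` basic property value, and `is_a`
written in its shorthand form. Full IRIs are compressed to CURIEs via the
prefix map (with a fallback for OBO PURLs); identifiers are CURIEs
internally. Serialization sorts nodes, edges, and synonyms, so saving is
byte-deterministic and `save ∘ load` is the identity. Unrecognized node and
graph metadata is preserved verbatim.

Label resolution is exact and case-sensitive; an ambiguous label is an
error, never a guess.

## Apply semantics

Changes are applied in order against the evolving graph, so a label
introduced by change *i* is visible to change *i+1*. **Strict** mode
verifies every precondition (stated old values match, edges to delete
exist, created ids are fresh) and is atomic: the first failure raises and
the input graph is returned untouched. **Lenient** mode downgrades
old-value mismatches to warnings and records skipped changes in the report
instead of failing.

Obsoletion deprecates a node without deleting it, removes the node's own
out-edges (an obsolete term should assert nothing), records the replacement
pointer when given, and leaves incoming edges in place as dangling-reference
lint for downstream curation. A replacement reference is not required to be
present in the graph — it may live in another ontology or be created later
in the same change set. Deletion removes the node and all incident edges.
`ClassCreation` without an explicit CURIE mints one from a configurable
namespace (`ApplyConfig(id_namespace="EX", id_start=1)`), zero-padded to
seven digits. Synonym identity is (value, scope): the same text under a
different scope is a distinct assertion.

### Provisional changes

`store_provisional` serializes each change to JSON and stores it in the
graph against the node it targets (the about-node or edge subject);
creations and changes whose target is not yet in the graph are stored at
graph level. On disk these become `KGCL:pendingChange` basic property
values on the node (or the graph). Each payload records its position in the
deferred change set in a `seq` field, so the original order — which
matters, because later changes may depend on earlier ones — survives the
save/load regrouping by node. `apply_pending` enacts all pending changes or
a selected list of ids, removes enacted entries, and is equivalent to
having applied the change set directly.

## Diff

`raw_diff(a, b)` computes the low-level delta: nodes added/removed, per-node
scalar field changes (label, definition, deprecation, replacement, kind),
synonym additions/removals, and edges added/removed. `lift` then rewrites
the delta into high-level changes by ordered rules:

1. a node present only in `b` becomes `ClassCreation` plus follow-up
   changes for its definition and synonyms (synthesized as if the node had
   been created bare);
2. a label change becomes `NodeRename`;
3. definition transitions become `NewTextDefinition` /
   `RemoveTextDefinition` / `NodeTextDefinitionChange` (with the old value);
4. one synonym removed and one added **in the same scope** pair into a
   `SynonymReplacement`; pairing is greedy in lexicographic order of the
   values, which makes the output deterministic when several pairings are
   possible;
5. a newly set deprecation flag becomes `NodeObsoletion`, carrying the
   replacement pointer when newly set;
6. after simulating the node-level operations — a deleted node consumes all
   its incident edge removals, an obsoleted node consumes its out-edge
   removals — a remaining removed+added edge pair sharing (subject,
   predicate) becomes `NodeMove`;
7. a pair sharing (subject, object) becomes `PredicateChange`;
8. residual edges become `EdgeCreation` / `EdgeDeletion`; in particular, an
   out-edge that an obsoleted node *retains* in `b` is re-added explicitly,
   since obsoletion removes out-edges on apply.

Node changes are ordered by (node id, a fixed type rank placing creation
first and deletion last), edge changes by subject; together with the greedy
pairings this makes `diff` fully deterministic. The soundness property
`apply(diff(a, b), a) ≅ b` is enforced by the test suite over hundreds of
seeded random pairs.

Deltas the 14 types cannot express raise `UnliftableDelta` instead of
producing a silently wrong change set: un-deprecating a node, rewriting a
replacement pointer without a deprecation flip, and the appearance of an
unlabeled or non-class node.

## Synthetic fixtures

`generate_graph(FixtureSpec)` builds a deterministic ontology: nodes
`EX:0000001...` with unique labels `term i`, definitions and one synonym
present with probabilities `p_definition`/`p_synonym` (defaults 0.5), and a
DAG of `n_edges` edges pointing from later to earlier nodes, 80% `is_a` /
20% `part_of` (reverse-direction fill only when a spec demands more edges
than the DAG shape allows). Defaults: 20 nodes, 25 edges, seed 0. The
generator emulates the *shape* of curated ontologies (unique labels, scoped
synonyms, mostly-hierarchical edges); it does not emulate their content,
logical axioms, cross-references, or realistic label distributions.

`random_changeset(graph, n, seed)` draws change types from a weight table
over the sorted type names and samples each change by simulating its
application on a working copy, so every sampled set is feasible by
construction (strict apply succeeds). Infeasible types are resampled;
`InfeasibleChangeType` is raised only when no requested type is feasible.
All randomness flows from explicit seeds via `random.Random`; nothing
depends on hash ordering, which the test suite checks by running under
several `PYTHONHASHSEED` values.

## Limitations

* The CNL cannot express a created class's chosen CURIE or a definition
  change's old value; use JSON/YAML/TSV when those matter.
* Diff recovers *a* parsimonious explanation, not necessarily the edit
  sequence a curator performed; e.g. a rename plus independent re-label can
  in principle be confounded, and greedy synonym pairing picks one of
  several equally small explanations.
* Obsoletion does not rewrite the obsolete node's label (no `obsolete `
  prefixing) and does not touch incoming edges.
* Only one graph per OBO Graphs document is supported, and logical
  definitions/axioms beyond the node/edge model are carried opaquely, not
  diffed.
* RDF/OWL serializations are out of scope; OBO Graphs JSON is the single
  interchange format.
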