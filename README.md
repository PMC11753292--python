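# kgclite

A Knowledge Graph Change Language toolkit: a typed vocabulary of ontology and
knowledge-graph edit operations, a controlled natural language (CNL) to read
and write them, an apply engine that enacts them, and a diff engine that
recovers them from two ontology versions.

## The problem

Ontologies and biomedical knowledge graphs evolve constantly: terms are
renamed, obsoleted with replacement pointers, re-parented, given new
definitions and synonyms. Today this evolution is communicated in two
unsatisfying ways: free-text issue trackers ("please rename X to Y"), which a
machine cannot enact, and low-level axiom diffs (thousands of added/removed
triples), which a human cannot review. Both lose the *intent* of the edit —
a single re-parenting of one term shows up as one deleted and one added edge
with no statement that they belong together.

kgclite closes that gap with a small, closed vocabulary of **14 high-level
change types**, each of which is simultaneously:

* **parseable** — a curator writes `move 'Parkinson disease' under
  'neurodegenerative disease'` and a machine turns it into a typed object;
* **executable** — an apply engine enacts the change on an OBO Graphs JSON
  ontology, checking preconditions (the old label really is the current
  label, the edge to delete really exists);
* **recoverable** — a diff engine compares two ontology versions and lifts
  the low-level delta back into the smallest set of high-level changes that
  explains it, so `apply(diff(a, b), a)` equals `b`.

The audience is ontology curators, knowledge-graph release engineers, and
tool builders who need change requests, change review, and change logs to
share one machine-readable representation.

## The change model

Node changes: `NodeRename`, `NodeObsoletion` (deprecate, keep the node,
optionally point at a replacement), `NodeDeletion`, `ClassCreation`,
`SynonymReplacement`, `NewSynonym` / `RemoveSynonym` (with exact / narrow /
broad / related scopes), `NewTextDefinition` / `RemoveTextDefinition` /
`NodeTextDefinitionChange`.

Edge changes: `EdgeCreation`, `EdgeDeletion`, `NodeMove` (one child is
re-parented under one predicate), `PredicateChange`.

Every change can be serialized four ways — CNL text, JSON, YAML, and a flat
TSV table — and all four round-trip. Changes can also be stored *inside* the
ontology as provisional (pending) annotations and enacted later, so a
proposed edit can travel with the ontology through a review cycle.

## Worked example

Create a small deterministic ontology, apply three changes, and diff the two
versions:

```console
$ kgcl fixture --nodes 6 --edges 5 --seed 7 -o cell.json
$ kgcl apply -i cell.json -o cell2.json \
    -k "rename 'term 2' from 'term 2' to 'ciliated cell'" \
    -k "create exact synonym 'motile cilium cell' for 'ciliated cell'" \
    -k "obsolete 'term 5'"
applied 3 change(s); skipped 0
$ kgcl diff cell.json cell2.json
rename EX:0000002 from 'term 2' to 'ciliated cell'
create exact synonym 'motile cilium cell' for EX:0000002
obsolete EX:0000005
```

The diff is itself a valid change script: feeding it back through `kgcl
apply` onto `cell.json` reproduces `cell2.json`. The same diff in JSON:

```console
$ kgcl diff cell.json cell2.json --format json
[
  {
    "type": "NodeRename",
    "id": "kgcl:000001",
    "about_node": "EX:0000002",
    "old_value": "term 2",
    "new_value": "ciliated cell"
  },
  {
    "type": "NewSynonym",
    "id": "kgcl:000002",
    "about_node": "EX:0000002",
    "new_value": "motile cilium cell",
    "qualifier": "exact"
  },
  {
    "type": "NodeObsoletion",
    "id": "kgcl:000003",
    "about_node": "EX:0000005"
  }
]
```

The parser normalizes typographic quotes, case, and trailing punctuation, so
commands pasted from documents or issue comments work as-is:

```console
$ kgcl parse "Rename UBERON:0002398 from “hand” to “manus”."
rename UBERON:0002398 from 'hand' to 'manus'
```

The same machinery from Python:

```python
from kgclite import ChangeSet, apply, diff, parse_command, render_command

change = parse_command(
    "move 'Parkinson disease' under 'neurodegenerative disease'")
# NodeMove(about_node=NodeRef(label='Parkinson disease'),
#          new_object=NodeRef(label='neurodegenerative disease'),
#          old_object=None, predicate='rdfs:subClassOf')

new_graph, report = apply(ChangeSet([change.with_id("kgcl:000001")]), graph)
print(render_command(diff(graph, new_graph)[0]))
# move MONDO:0005180 from MONDO:0000001 to MONDO:0005559
```

Labels are resolved against the evolving graph (case-sensitively, and never
when ambiguous), and the recovered change above is a single `NodeMove`, not
an unrelated edge deletion plus edge creation.

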