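"""Shared fixtures: tiny hand-built anatomy graphs and an example command corpus."""

from __future__ import annotations

import pytest

from kgclite import EdgeRecord, NodeRecord, OntologyGraph, Synonym
from kgclite.vocab import IS_A, PART_OF


def make_graph(nodes, edges=()):
    """Build a graph from (id, label, **fields) tuples and (s, p, o) triples."""
    g = OntologyGraph()
    for spec in nodes:
        nid, label = spec[0], spec[1]
        fields = spec[2] if len(spec) > 2 else {}
        g.nodes[nid] = NodeRecord(id=nid, label=label, **fields)
    for s, p, o in edges:
        g.edges.add(EdgeRecord(s, p, o))
    return g


@pytest.fixture
def anatomy():
    """A small anatomy-flavoured graph exercising every node feature."""
    g = make_graph(
        [
            ("UBERON:0002398", "hand"),
            ("UBERON:0000948", "heart",
             {"definition": "A muscular organ that pumps blood through the body."}),
            ("UBERON:0003126", "trachea"),
            ("UBERON:0002107", "liver", {"definition": "A lobed organ."}),
            ("UBERON:0000062", "hepatocyte"),
            ("UBERON:0000916", "abdomen"),
            ("UBERON:0000981", "femur",
             {"synonyms": {Synonym("thighbone", "related")}}),
            ("UBERON:0000976", "humerus",
             {"synonyms": {Synonym("arm bone", "exact")}}),
        ],
        [
            ("UBERON:0000062", PART_OF, "UBERON:0002107"),
            ("UBERON:0002107", IS_A, "UBERON:0000916"),
            ("UBERON:0002398", IS_A, "UBERON:0000916"),
        ],
    )
    return g


# A corpus of example commands, as they appear in curation requests (note the
# typographic quotes), paired with the change type each must parse to.
COMMAND_CORPUS = [
    ("Rename UBERON:0002398 from “hand” to “manus”", "NodeRename"),
    ("Obsolete “trachea”", "NodeObsoletion"),
    ("Delete node “heart”", "NodeDeletion"),
    ("Create “digestive system”", "ClassCreation"),
    ("Replace synonym “intestine” with “gut” for “alimentary canal”",
     "SynonymReplacement"),
    ("Add definition “A muscular organ that pumps blood through the body” "
     "to “heart”", "NewTextDefinition"),
    ("Remove definition for “liver”", "RemoveTextDefinition"),
    ("Change definition of “kidney” to “An organ that filters blood to produce "
     "urine”", "NodeTextDefinitionChange"),
    ("Create exact synonym “thigh bone” for “femur”", "NewSynonym"),
    ("Remove synonym “arm bone” for “humerus”", "RemoveSynonym"),
    ("Create edge “hepatocyte” part_of “liver”", "EdgeCreation"),
    ("Delete edge “hepatocyte” part_of “lung”", "EdgeDeletion"),
    ("Change relationship between “stomach” and “digestive system” from “is_a” "
     "to “part_of”", "PredicateChange"),
]

# The alternative spelling of the obsoletion command: CURIE instead of label.
OBSOLETE_BY_CURIE = ("obsolete “UBERON:0003126”", "NodeObsoletion")
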