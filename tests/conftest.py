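from __future__ import annotations

import networkx as nx
import pytest

from semmod.ontology import GeneOntology, build_annotation_table


def build_ontology(edges, root, namespace="biological_process"):
    """Assemble a GeneOntology directly from (child, parent, relation) triples."""
    g = nx.MultiDiGraph()
    g.add_node(root, name=root)
    for c, p, r in edges:
        g.add_node(c, name=c)
        g.add_node(p, name=p)
        g.add_edge(c, p, key=r)
    return GeneOntology(graph=g, root=root, namespace=namespace)


#: the 5-term DAG: R; A is_a R; B part_of R; C is_a A; C part_of B
FIVE_TERM_EDGES = [
    ("A", "R", "is_a"),
    ("B", "R", "part_of"),
    ("C", "A", "is_a"),
    ("C", "B", "part_of"),
    ("D", "A", "is_a"),
]


@pytest.fixture(scope="session")
def five_term_ontology():
    return build_ontology(FIVE_TERM_EDGES, root="R")


@pytest.fixture(scope="session")
def five_term_edges():
    return FIVE_TERM_EDGES


FIVE_TERM_OBO = """format-version: 1.2

[Term]
id: R
name: root
namespace: biological_process

[Term]
id: A
name: a
namespace: biological_process
is_a: R ! root

[Term]
id: B
name: b
namespace: biological_process
relationship: part_of R ! root

[Term]
id: C
name: c
namespace: biological_process
is_a: A ! a
relationship: part_of B ! b

[Term]
id: D
name: d
namespace: biological_process
is_a: A ! a
"""


@pytest.fixture()
def five_term_obo_path(tmp_path):
    p = tmp_path / "five.obo"
    p.write_text(FIVE_TERM_OBO)
    return p


@pytest.fixture(scope="session")
def extension_fixture():
    """5-gene module + 4 pool genes with hand-set annotations and edges.

    Terms TA, TB, TC are siblings under R (pairwise Wang similarity 4/9).
    m1..m4 -> {TA}, m5 -> {TB}; candidates c1 -> {TA} (4 module edges),
    c2 -> {TB} (3), c3 -> {TC} (2), c4 -> {TA} (1 edge: not a candidate).
    """
    onto = build_ontology(
        [("TA", "R", "is_a"), ("TB", "R", "is_a"), ("TC", "R", "is_a")],
        root="R",
    )
    direct = {
        "m1": {"TA"}, "m2": {"TA"}, "m3": {"TA"}, "m4": {"TA"}, "m5": {"TB"},
        "c1": {"TA"}, "c2": {"TB"}, "c3": {"TC"}, "c4": {"TA"},
    }
    ann = build_annotation_table(direct, onto, universe=sorted(direct))
    g = nx.Graph()
    g.add_edges_from([("c1", m) for m in ["m1", "m2", "m3", "m4"]])
    g.add_edges_from([("c2", m) for m in ["m1", "m2", "m3"]])
    g.add_edges_from([("c3", m) for m in ["m1", "m2"]])
    g.add_edge("c4", "m1")
    from semmod.similarity import InteractionNetwork

    return onto, ann, InteractionNetwork(graph=g)
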