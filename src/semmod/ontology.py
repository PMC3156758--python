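"""Ontology and annotation parsing.

Reads an OBO v1.2 ontology restricted to one namespace, keeping only the
``is_a`` and ``part_of`` relations (the two relations carrying semantic
contribution weights), and reads GAF 2.x gene-association files, applying
the true-path rule (every gene annotated to a term is implicitly annotated
to all of the term's ancestors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

log = logging.getLogger(__name__)

VALID_NAMESPACES = frozenset(
    {"biological_process", "molecular_function", "cellular_component"}
)
KEPT_RELATIONS = frozenset({"is_a", "part_of"})


class OntologyError(ValueError):
    """Raised for malformed or inconsistent ontology input."""


@dataclass
class GeneOntology:
    """A single-namespace ontology as a rooted DAG.

    ``graph`` is a MultiDiGraph with child -> parent edges keyed by relation
    type (``is_a`` or ``part_of``).  ``root`` is the unique term with no
    parents; every other term reaches it.
    """

    graph: nx.MultiDiGraph
    root: str
    namespace: str
    alt_ids: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def resolve(self, term: str) -> str | None:
        """Map an alt_id to its primary term; return None for unknown ids."""
        if term in self.graph:
            return term
        return self.alt_ids.get(term)

    def parents(self, term: str) -> set[tuple[str, str]]:
        """(parent, relation) pairs of *term*."""
        return {(p, k) for _, p, k in self.graph.out_edges(term, keys=True)}

    def children(self, term: str) -> set[tuple[str, str]]:
        """(child, relation) pairs of *term*."""
        return {(c, k) for c, _, k in self.graph.in_edges(term, keys=True)}

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from *term* along child->parent edges (excl. term)."""
        if term not in self.graph:
            raise OntologyError(f"unknown term: {term}")
        return nx.descendants(self.graph, term)

    def ancestral_closure(self, term: str) -> set[str]:
        """*term* together with all its ancestors."""
        return self.ancestors(term) | {term}

    def depth(self, term: str) -> int:
        """Shortest directed path length (in edges) from *term* to the root,
        counting is_a and part_of edges equally."""
        if term not in self.graph:
            raise OntologyError(f"unknown term: {term}")
        return nx.shortest_path_length(self.graph, term, self.root)


def term_depth(ontology: GeneOntology, term: str) -> int:
    """Shortest-path depth of *term* below the namespace root."""
    return ontology.depth(term)


def parse_obo(path: str | Path, namespace: str) -> GeneOntology:
    """Parse an OBO v1.2 file into a single-namespace :class:`GeneOntology`.

    Terms flagged ``is_obsolete`` are dropped together with their edges;
    only is_a and part_of relationships are kept; edges leaving the
    namespace are discarded.
    """
    if namespace not in VALID_NAMESPACES:
        raise OntologyError(f"invalid namespace: {namespace}")
    raw = obonet.read_obo(path)  # obonet drops obsolete stanzas itself
    keep = {
        n
        for n, data in raw.nodes(data=True)
        if data.get("namespace") == namespace
    }
    if not keep:
        raise OntologyError(f"namespace {namespace!r} absent from {path}")

    g = nx.MultiDiGraph()
    g.add_nodes_from(
        (n, {"name": raw.nodes[n].get("name", n)}) for n in keep
    )
    for child, parent, rel in raw.edges(keys=True):
        if rel in KEPT_RELATIONS and child in keep and parent in keep:
            g.add_edge(child, parent, key=rel)

    if not nx.is_directed_acyclic_graph(g):
        raise OntologyError("cycle detected in ontology")

    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise OntologyError(
            f"expected a single root for {namespace}, found {sorted(roots)}"
        )
    root = roots[0]

    alt_ids: dict[str, str] = {}
    for n in keep:
        for alt in raw.nodes[n].get("alt_id", []):
            alt_ids[alt] = n

    return GeneOntology(graph=g, root=root, namespace=namespace, alt_ids=alt_ids)


def write_obo(ontology: GeneOntology, path: str | Path) -> None:
    """Serialize back to OBO v1.2 (round-trip partner of :func:`parse_obo`)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(ontology.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {ontology.graph.nodes[term].get('name', term)}\n")
            fh.write(f"namespace: {ontology.namespace}\n")
            for parent, rel in sorted(ontology.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")


@dataclass
class AnnotationTable:
    """Direct and ancestor-propagated gene -> term annotations over a gene
    universe (the set of genes of interest, V)."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    universe: list[str]

    def direct_terms(self, gene: str) -> set[str]:
        return self.direct.get(gene, set())

    def propagated_terms(self, gene: str) -> set[str]:
        return self.propagated.get(gene, set())


def propagate(
    direct: Mapping[str, set[str]], ontology: GeneOntology
) -> dict[str, set[str]]:
    """Close each gene's annotation set under ancestors (true-path rule)."""
    closure_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        acc: set[str] = set()
        for t in terms:
            if t not in closure_cache:
                closure_cache[t] = ontology.ancestral_closure(t)
            acc |= closure_cache[t]
        out[gene] = acc
    return out


def build_annotation_table(
    direct: Mapping[str, Iterable[str]],
    ontology: GeneOntology,
    universe: Iterable[str] | None = None,
) -> AnnotationTable:
    """Assemble an :class:`AnnotationTable` from direct annotations."""
    d = {g: set(ts) for g, ts in direct.items() if ts}
    uni = list(universe) if universe is not None else sorted(d)
    return AnnotationTable(direct=d, propagated=propagate(d, ontology), universe=uni)


def parse_gaf(
    path: str | Path,
    ontology: GeneOntology,
    exclude_evidence: set[str] | frozenset[str] = frozenset(),
    id_column: str = "object_id",
    universe: Iterable[str] | None = None,
) -> AnnotationTable:
    """Parse a GAF 2.x file against a parsed ontology.

    Rows are skipped when the qualifier contains NOT, the evidence code is
    excluded, or the term (after alt_id resolution) is not in the ontology
    namespace.  ``id_column`` selects the gene key: ``"object_id"`` (column
    2) or ``"symbol"`` (column 3).
    """
    if id_column not in ("object_id", "symbol"):
        raise ValueError(f"id_column must be 'object_id' or 'symbol', got {id_column!r}")
    idx = 1 if id_column == "object_id" else 2
    direct: dict[str, set[str]] = {}
    n_used = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:  # GAF 2.x has 17 columns; 15 are mandatory
                log.warning("line %d: %d columns, expected >= 15; skipped", lineno, len(cols))
                continue
            qualifier, go_id, evidence = cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in exclude_evidence:
                continue
            term = ontology.resolve(go_id)
            if term is None:
                continue
            gene = cols[idx]
            if not gene:
                log.warning("line %d: empty gene id; skipped", lineno)
                continue
            direct.setdefault(gene, set()).add(term)
            n_used += 1
    if n_used == 0:
        raise OntologyError(f"no usable annotation rows in {path}")
    return build_annotation_table(direct, ontology, universe=universe)


def parse_term_gene_mapping(
    path: str | Path, universe: Iterable[str] | None = None
) -> dict[str, set[str]]:
    """Generic two-column TSV term -> gene mapping for non-GO annotation
    schemes; returns gene -> set of terms (no propagation: flat scheme)."""
    direct: dict[str, set[str]] = {}
    uni = set(universe) if universe is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                log.warning("line %d: fewer than 2 columns; skipped", lineno)
                continue
            term, gene = cols[0], cols[1]
            if uni is not None and gene not in uni:
                continue
            direct.setdefault(gene, set()).add(term)
    return direct
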