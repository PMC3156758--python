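"""Wang's GO-DAG semantic similarity.

A term's semantic profile assigns an S-value to itself (1) and to each of
its ancestors, decayed multiplicatively along the best child->parent path
by a per-relation semantic contribution weight.  Term-term similarity is
the overlap of two profiles normalized by their totals; gene-gene
similarity is the best-match average over the genes' direct annotation
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .ontology import AnnotationTable, GeneOntology
from .similarity import SimilarityMatrix

log = logging.getLogger(__name__)

#: Default Wang-measure semantic contribution weights per relation type.
DEFAULT_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


@dataclass(frozen=True)
class TermSemanticProfile:
    """S-values of a term over its ancestral closure, and their sum."""

    term: str
    svalues: dict[str, float]
    sv_total: float


def svalue_profile(
    ontology: GeneOntology,
    term: str,
    weights: dict[str, float] | None = None,
) -> TermSemanticProfile:
    """Compute the S-value profile of *term*.

    S_term(term) = 1; for an ancestor t,
    S_term(t) = max over children c of t inside term's ancestral closure
    of w(relation(c, t)) * S_term(c).
    """
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    for rel, val in w.items():
        if not (0.0 < val < 1.0):
            raise ValueError(f"weight for {rel} must lie in (0,1), got {val}")
    closure = ontology.ancestral_closure(term)  # raises for unknown term

    # Process ancestors in increasing distance from `term` is not sufficient
    # on a DAG; a topological order of the closure (children before parents)
    # guarantees every S(c) is final before S(t) is taken.
    sub = ontology.graph.subgraph(closure)
    order = list(nx.topological_sort(sub))  # child precedes parent
    sval: dict[str, float] = {term: 1.0}
    for t in order:
        if t == term:
            continue
        best = 0.0
        for child, _, rel in sub.in_edges(t, keys=True):
            if child in sval and rel in w:
                best = max(best, w[rel] * sval[child])
        if best > 0.0:
            sval[t] = best
    return TermSemanticProfile(term=term, svalues=sval, sv_total=float(sum(sval.values())))


def term_similarity(pA: TermSemanticProfile, pB: TermSemanticProfile) -> float:
    """Wang similarity of two terms from their profiles; 1 for identical
    terms, 0 when the ancestral closures are disjoint."""
    common = pA.svalues.keys() & pB.svalues.keys()
    if not common:
        return 0.0
    num = sum(pA.svalues[t] + pB.svalues[t] for t in common)
    return num / (pA.sv_total + pB.sv_total)


class ProfileStore:
    """Memoizes term profiles and term-term similarities for one ontology."""

    def __init__(self, ontology: GeneOntology, weights: dict[str, float] | None = None):
        self.ontology = ontology
        self.weights = weights
        self._profiles: dict[str, TermSemanticProfile] = {}
        self._pairs: dict[tuple[str, str], float] = {}

    def profile(self, term: str) -> TermSemanticProfile:
        if term not in self._profiles:
            self._profiles[term] = svalue_profile(self.ontology, term, self.weights)
        return self._profiles[term]

    def sim(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        if key not in self._pairs:
            self._pairs[key] = term_similarity(self.profile(a), self.profile(b))
        return self._pairs[key]


def gene_similarity(
    termsA: set[str], termsB: set[str], profiles: ProfileStore
) -> float:
    """Best-match-average similarity between two direct annotation sets;
    0 when either set is empty, 1 for identical non-empty sets."""
    if not termsA or not termsB:
        return 0.0
    fwd = sum(max(profiles.sim(a, b) for b in termsB) for a in termsA)
    rev = sum(max(profiles.sim(a, b) for a in termsA) for b in termsB)
    return (fwd + rev) / (len(termsA) + len(termsB))


def pairwise_semantic_matrix(
    annotations: AnnotationTable,
    ontology: GeneOntology,
    weights: dict[str, float] | None = None,
) -> SimilarityMatrix:
    """Gene x gene Wang similarity matrix over the annotation universe.

    Diagonal is 1 for annotated genes and 0 for unannotated genes, which
    score 0 against every partner (no evidence of similarity).
    """
    genes = list(annotations.universe)
    if not genes:
        raise ValueError("empty gene universe")
    store = ProfileStore(ontology, weights)
    n = len(genes)
    unannotated = [g for g in genes if not annotations.direct_terms(g)]
    if unannotated:
        log.info("%d of %d genes carry no direct annotation; their semantic "
                 "similarity is 0 to all partners", len(unannotated), n)
    values = np.zeros((n, n))
    term_sets = [frozenset(annotations.direct_terms(g)) for g in genes]
    # pairs of identical term-set pairs share one computation
    cache: dict[frozenset, float] = {}
    for i in range(n):
        if term_sets[i]:
            values[i, i] = 1.0
        for j in range(i + 1, n):
            a, b = term_sets[i], term_sets[j]
            if not a or not b:
                continue
            key = frozenset((a, b))
            if key not in cache:
                cache[key] = gene_similarity(set(a), set(b), store)
            values[i, j] = values[j, i] = cache[key]
    return SimilarityMatrix(genes=genes, values=values, channel="semantic")
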