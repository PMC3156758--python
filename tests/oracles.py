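"""Independent brute-force oracles used to check the implementation.

Each oracle recomputes a quantity by the most direct route available
(path enumeration, exhaustive subset search, pmf summation) without
touching the code paths it validates.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def enumerate_upward_paths(edges, start, target):
    """All child->parent relation paths from start to target.

    ``edges`` is an iterable of (child, parent, relation) triples.
    Yields lists of relation names.
    """
    out_edges = {}
    for c, p, r in edges:
        out_edges.setdefault(c, []).append((p, r))

    def walk(node, rels):
        if node == target:
            yield list(rels)
            return
        for parent, rel in out_edges.get(node, []):
            rels.append(rel)
            yield from walk(parent, rels)
            rels.pop()

    yield from walk(start, [])


def svalues_by_path_enumeration(edges, term, weights):
    """S-values of *term* as max over all upward paths of the product of
    relation weights along the path."""
    nodes = {term}
    frontier = [term]
    out_edges = {}
    for c, p, r in edges:
        out_edges.setdefault(c, []).append(p)
    while frontier:
        nxt = []
        for n in frontier:
            for p in out_edges.get(n, []):
                if p not in nodes:
                    nodes.add(p)
                    nxt.append(p)
        frontier = nxt
    sv = {}
    for anc in nodes:
        best = 0.0
        for rels in enumerate_upward_paths(edges, term, anc):
            prod = 1.0
            for r in rels:
                prod *= weights[r]
            best = max(best, prod)
        if best > 0:
            sv[anc] = best
    return sv


def wang_term_sim_oracle(edges, a, b, weights):
    sa = svalues_by_path_enumeration(edges, a, weights)
    sb = svalues_by_path_enumeration(edges, b, weights)
    common = sa.keys() & sb.keys()
    if not common:
        return 0.0
    return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))


def bma_gene_sim_oracle(edges, terms_a, terms_b, weights):
    """Best-match-average gene similarity by direct re-evaluation."""
    if not terms_a or not terms_b:
        return 0.0
    fwd = sum(
        max(wang_term_sim_oracle(edges, a, b, weights) for b in terms_b)
        for a in terms_a
    )
    rev = sum(
        max(wang_term_sim_oracle(edges, a, b, weights) for a in terms_a)
        for b in terms_b
    )
    return (fwd + rev) / (len(terms_a) + len(terms_b))


def hypergeom_tail_oracle(overlap, universe, term_count, module_size):
    """P[X >= overlap] by direct summation of the hypergeometric pmf."""
    total = 0.0
    denom = comb(universe, module_size)
    upper = min(term_count, module_size)
    for x in range(overlap, upper + 1):
        total += comb(term_count, x) * comb(universe - term_count, module_size - x) / denom
    return total


def brute_force_exemplar_optimum(s, preference):
    """Exhaustive search over non-empty exemplar subsets maximizing the net
    similarity: members join their best exemplar."""
    n = s.shape[0]
    best = -np.inf
    for r in range(1, n + 1):
        for ex in itertools.combinations(range(n), r):
            tot = r * preference
            for i in range(n):
                if i not in ex:
                    tot += max(s[i, k] for k in ex)
            best = max(best, tot)
    return best


def ecdf_count_oracle(upper_values, x):
    """(# upper-triangle values <= x) / n_pairs by direct counting."""
    vals = list(upper_values)
    return sum(1 for v in vals if v <= x) / len(vals)
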