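"""Module-set scoring.

Annotation-term enrichment by the one-sided Fisher exact
(hypergeometric) test without multiple-testing correction;
sensitivity/specificity/F summaries; coherency and depth of enriched
terms; expression homogeneity and network connectivity; consensus over
stochastic runs; conservation across preference sweeps; cross-tabulation
of two module sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .clustering import ModuleAssignment
from .ontology import AnnotationTable, GeneOntology
from .semantics import ProfileStore
from .similarity import ExpressionMatrix, InteractionNetwork

log = logging.getLogger(__name__)

#: default significance levels (uncorrected, per the method's convention)
SUMMARY_THRESHOLD = 1e-4
COHERENCE_THRESHOLD = 1e-5

ENRICHMENT_COLUMNS = [
    "module",
    "term",
    "overlap",
    "module_size",
    "term_size",
    "universe_size",
    "p_value",
]


def fisher_enrichment(
    assignment: ModuleAssignment,
    annotations: AnnotationTable,
    min_term_size: int = 1,
) -> pd.DataFrame:
    """Per-(module, term) over-representation p-values.

    The gene universe is the assignment's gene list; term gene-sets come
    from PROPAGATED annotations restricted to that universe.  For each pair
    with overlap >= 1, p = P[X >= overlap] under the hypergeometric null
    (one-sided Fisher exact test); no multiple-testing correction.
    """
    universe = list(assignment.genes)
    uni_set = set(universe)
    N = len(universe)

    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in annotations.propagated_terms(g):
            term_genes.setdefault(t, set()).add(g)
    term_genes = {
        t: gs for t, gs in term_genes.items() if len(gs) >= min_term_size
    }

    rows = []
    for module, members in assignment.modules().items():
        mset = set(members) & uni_set
        n = len(mset)
        for term, gs in term_genes.items():
            overlap = len(mset & gs)
            if overlap == 0:
                continue
            K = len(gs)
            p = float(hypergeom.sf(overlap - 1, N, K, n))
            rows.append((module, term, overlap, n, K, N, min(p, 1.0)))
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


@dataclass
class EnrichmentSummary:
    """Sensitivity / specificity / F of a module set at one p threshold.

    sensitivity: fraction of universe terms enriched in >= 1 module;
    specificity: fraction of modules enriched with >= 1 term; the raw
    counts are carried alongside the fractions.
    """

    threshold: float
    sensitivity: float
    specificity: float
    f_measure: float
    n_enriched_terms: int
    n_enriched_modules: int
    n_terms_in_universe: int
    n_modules: int


def f_measure(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of sensitivity and specificity (0 when both are 0)."""
    denom = sensitivity + specificity
    return 2.0 * sensitivity * specificity / denom if denom > 0 else 0.0


def enrichment_summary(
    table: pd.DataFrame,
    threshold: float,
    n_modules: int,
    n_terms_in_universe: int,
) -> EnrichmentSummary:
    """Count enriched terms/modules at ``p < threshold`` and fold them into
    sensitivity, specificity and their harmonic-mean F."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    if n_modules <= 0 or n_terms_in_universe <= 0:
        raise ValueError("n_modules and n_terms_in_universe must be positive")
    hits = table[table["p_value"] < threshold]
    n_terms = int(hits["term"].nunique())
    n_mods = int(hits["module"].nunique())
    sens = n_terms / n_terms_in_universe
    spec = n_mods / n_modules
    return EnrichmentSummary(
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        f_measure=f_measure(sens, spec),
        n_enriched_terms=n_terms,
        n_enriched_modules=n_mods,
        n_terms_in_universe=n_terms_in_universe,
        n_modules=n_modules,
    )


def summary_grid(
    table: pd.DataFrame,
    n_modules: int,
    n_terms_in_universe: int,
    exponents: Sequence[int] = range(1, 21),
) -> pd.DataFrame:
    """Enrichment summaries over the p = 10^-1 ... 10^-20 threshold grid."""
    rows = []
    for e in exponents:
        s = enrichment_summary(table, 10.0 ** -e, n_modules, n_terms_in_universe)
        rows.append(
            (s.threshold, s.n_enriched_terms, s.n_enriched_modules,
             s.sensitivity, s.specificity, s.f_measure)
        )
    return pd.DataFrame(
        rows,
        columns=["threshold", "n_enriched_terms", "n_enriched_modules",
                 "sensitivity", "specificity", "f_measure"],
    )


@dataclass
class ModuleCoherence:
    """Per-module coherency (mean pairwise Wang similarity of enriched
    terms, needs >= 2 terms) and depth (mean shortest-path distance of
    enriched terms to the namespace root, needs >= 1 term)."""

    per_module: pd.DataFrame  # columns: module, n_terms, coherency, depth
    average_coherency: float
    average_depth: float
    n_modules_coherency: int
    n_modules_depth: int


def coherence_depth(
    table: pd.DataFrame,
    ontology: GeneOntology,
    threshold: float = COHERENCE_THRESHOLD,
    weights: dict[str, float] | None = None,
) -> ModuleCoherence:
    """Coherency G and depth D of each module's enriched terms at
    ``p < threshold``; averages taken over modules meeting the respective
    minimum term counts."""
    store = ProfileStore(ontology, weights)
    hits = table[table["p_value"] < threshold]
    rows = []
    for module, sub in hits.groupby("module"):
        terms = sorted(sub["term"].unique())
        m = len(terms)
        if m >= 2:
            sims = [store.sim(a, b) for a, b in itertools.combinations(terms, 2)]
            g = float(np.mean(sims))
        else:
            g = np.nan
        d = float(np.mean([ontology.depth(t) for t in terms])) if m >= 1 else np.nan
        rows.append((module, m, g, d))
    per_module = pd.DataFrame(rows, columns=["module", "n_terms", "coherency", "depth"])
    coh = per_module["coherency"].dropna()
    dep = per_module["depth"].dropna()
    return ModuleCoherence(
        per_module=per_module,
        average_coherency=float(coh.mean()) if len(coh) else float("nan"),
        average_depth=float(dep.mean()) if len(dep) else float("nan"),
        n_modules_coherency=int(len(coh)),
        n_modules_depth=int(len(dep)),
    )


def homogeneity_and_connectivity(
    assignment: ModuleAssignment,
    expr: ExpressionMatrix,
    net: InteractionNetwork,
) -> pd.DataFrame:
    """Expression homogeneity and topological connectivity per module.

    Homogeneity is the mean pairwise-complete Pearson correlation over all
    within-module gene pairs (singletons excluded, logged); connectivity is
    the mean local clustering coefficient over the module-induced subgraph,
    nodes of induced degree < 2 contributing 0.  Returns one row per module
    plus an ``overall`` row holding unweighted means across modules.
    """
    rows = []
    for module, members in sorted(assignment.modules().items()):
        if len(members) < 2:
            log.info("module %s is a singleton; homogeneity undefined", module)
            hom = np.nan
        else:
            sub = expr.data.loc[[g for g in members if g in expr.data.index]]
            corr = sub.T.corr(method="pearson", min_periods=3).to_numpy()
            iu = np.triu_indices(corr.shape[0], k=1)
            vals = corr[iu]
            vals = vals[~np.isnan(vals)]
            hom = float(np.mean(vals)) if vals.size else np.nan
        present = [g for g in members if g in net.graph]
        subg = net.graph.subgraph(present)
        cc = nx.clustering(subg)  # degree<2 nodes get 0
        conn = float(np.mean([cc.get(g, 0.0) for g in members])) if members else 0.0
        rows.append((module, len(members), hom, conn))
    df = pd.DataFrame(
        rows, columns=["module", "size", "homogeneity", "connectivity"]
    )
    overall = pd.DataFrame(
        [("overall", int(df["size"].sum()),
          float(df["homogeneity"].dropna().mean()) if df["homogeneity"].notna().any() else np.nan,
          float(df["connectivity"].mean()) if len(df) else np.nan)],
        columns=df.columns,
    )
    return pd.concat([df, overall], ignore_index=True)


def consensus_matrix(runs: Sequence[ModuleAssignment]) -> np.ndarray:
    """Fraction of runs in which each gene pair shares a module; the
    diagonal is 1."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for a consensus")
    genes = runs[0].genes
    for r in runs[1:]:
        if r.genes != genes:
            raise ValueError("all runs must share the same gene list")
    n = len(genes)
    C = np.zeros((n, n))
    for r in runs:
        lab = r.label_array()
        C += (lab[:, None] == lab[None, :]).astype(float)
    return C / len(runs)


def consensus_assignment(
    runs: Sequence[ModuleAssignment], k: int
) -> ModuleAssignment:
    """Most-likely assignment across stochastic runs: average-linkage
    hierarchical clustering of 1 - consensus, cut to *k* groups, with each
    group's medoid under the consensus as its exemplar."""
    genes = runs[0].genes
    n = len(genes)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} genes")
    C = consensus_matrix(runs)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    flat = fcluster(Z, t=k, criterion="maxclust")
    labels = {genes[i]: int(flat[i]) - 1 for i in range(n)}
    exemplars: dict[int, str] = {}
    for m in sorted(set(flat)):
        idx = np.flatnonzero(flat == m)
        medoid = idx[np.argmax(C[np.ix_(idx, idx)].sum(axis=1))]
        exemplars[int(m) - 1] = genes[int(medoid)]
    return ModuleAssignment(
        genes=list(genes),
        labels=labels,
        exemplars=exemplars,
        n_modules=len(exemplars),
        converged=True,
        net_similarity=float("nan"),
    )


def conservation_matrix(module_sets: Sequence[ModuleAssignment]) -> np.ndarray:
    """Gene x gene count of module sets in which each pair co-clusters
    (0 = never; diagonal = number of sets)."""
    if not module_sets:
        raise ValueError("need at least one module set")
    genes = module_sets[0].genes
    for s in module_sets[1:]:
        if s.genes != genes:
            raise ValueError("gene lists differ across module sets")
    n = len(genes)
    M = np.zeros((n, n), dtype=int)
    for s in module_sets:
        lab = s.label_array()
        M += (lab[:, None] == lab[None, :]).astype(int)
    return M


def nestedness_fraction(fine: ModuleAssignment, coarse: ModuleAssignment) -> float:
    """Fraction of gene pairs co-clustered in the finer module set that are
    also co-clustered in the coarser one (1.0 = perfectly nested)."""
    if fine.genes != coarse.genes:
        raise ValueError("gene lists differ")
    lf, lc = fine.label_array(), coarse.label_array()
    iu = np.triu_indices(len(lf), k=1)
    co_f = (lf[:, None] == lf[None, :])[iu]
    co_c = (lc[:, None] == lc[None, :])[iu]
    n_fine = int(co_f.sum())
    if n_fine == 0:
        return 1.0
    return float((co_f & co_c).sum() / n_fine)


def module_overlap(a: ModuleAssignment, b: ModuleAssignment) -> pd.DataFrame:
    """Cross-tabulation of two module sets over the same universe: shared
    gene counts and the fraction of each module of *a* they cover."""
    if set(a.genes) != set(b.genes):
        raise ValueError("module sets cover different gene universes")
    rows = []
    b_modules = b.modules()
    for ma, members_a in sorted(a.modules().items()):
        sa = set(members_a)
        for mb, members_b in sorted(b_modules.items()):
            shared = len(sa & set(members_b))
            rows.append((ma, mb, len(sa), shared, shared / len(sa)))
    return pd.DataFrame(
        rows, columns=["module_a", "module_b", "size_a", "shared", "fraction_of_a"]
    )
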