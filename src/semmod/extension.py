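"""Greedy semantic-gated extension of a module with interaction neighbors.

Genes outside the originally selected set (V^C, the "back nodes") that
interact with at least two module genes are visited in descending order of
module edge count; a candidate is admitted when its mean Wang similarity
to the current module exceeds the module's own mean pairwise similarity,
so the module's average semantic similarity never decreases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .ontology import AnnotationTable
from .semantics import ProfileStore, gene_similarity
from .similarity import ExpressionMatrix, InteractionNetwork


@dataclass
class ExtensionContext:
    """A module (subset of the selected genes V), its candidate pool
    (genes of V^C present in the network), and the shared evidence."""

    module: set[str]
    candidate_pool: set[str]
    annotations: AnnotationTable
    network: InteractionNetwork
    profiles: ProfileStore
    expression: ExpressionMatrix | None = None

    def __post_init__(self) -> None:
        overlap = self.module & self.candidate_pool
        if overlap:
            raise ValueError(
                f"module and candidate pool overlap: {sorted(overlap)[:5]}"
            )


@dataclass
class ExtensionStep:
    """One audit-trail entry: the candidate, its module edge count, the
    decision, and the module mean similarity before/after."""

    gene: str
    n_module_edges: int
    candidate_mean: float
    module_mean_before: float
    module_mean_after: float
    admitted: bool


def _mean_pairwise(genes: list[str], ann: AnnotationTable, store: ProfileStore) -> float:
    sims = [
        gene_similarity(ann.direct_terms(a), ann.direct_terms(b), store)
        for a, b in itertools.combinations(genes, 2)
    ]
    return float(np.mean(sims))


def _mean_to_module(
    gene: str, module: list[str], ann: AnnotationTable, store: ProfileStore
) -> float:
    sims = [
        gene_similarity(ann.direct_terms(gene), ann.direct_terms(m), store)
        for m in module
    ]
    return float(np.mean(sims))


def _mean_expression_corr(genes: list[str], expr: ExpressionMatrix) -> float:
    present = [g for g in genes if g in expr.data.index]
    if len(present) < 2:
        return float("nan")
    corr = expr.data.loc[present].T.corr(min_periods=3).to_numpy()
    iu = np.triu_indices(corr.shape[0], k=1)
    vals = corr[iu]
    vals = vals[~np.isnan(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def extend_module(
    ctx: ExtensionContext, include_expression: bool = False
) -> tuple[set[str], list[ExtensionStep]]:
    """Extend a module by annotated interaction neighbors.

    Candidates with >= 2 direct edges into the module are frozen in
    descending edge-count order (ties broken lexicographically) and visited
    once each; a candidate is admitted iff its mean semantic similarity to
    ALL current module genes strictly exceeds the module's mean pairwise
    similarity, which is recomputed after every admission.  With
    *include_expression*, mean expression correlation must additionally
    exceed the module's mean internal correlation.
    """
    module = sorted(ctx.module)
    annotated = [g for g in module if ctx.annotations.direct_terms(g)]
    if len(annotated) < 2:
        raise ValueError(
            "module needs >= 2 annotated genes for a defined mean similarity"
        )

    edge_counts = {}
    for cand in ctx.candidate_pool:
        k = sum(1 for nb in ctx.network.neighbors(cand) if nb in ctx.module)
        if k >= 2:
            edge_counts[cand] = k
    ordered = sorted(edge_counts, key=lambda g: (-edge_counts[g], g))

    current = list(module)
    trail: list[ExtensionStep] = []
    for cand in ordered:
        mean_before = _mean_pairwise(current, ctx.annotations, ctx.profiles)
        cand_mean = _mean_to_module(cand, current, ctx.annotations, ctx.profiles)
        admit = cand_mean > mean_before
        if admit and include_expression and ctx.expression is not None:
            mod_corr = _mean_expression_corr(current, ctx.expression)
            cand_corr = float(
                np.nanmean(
                    [
                        ctx.expression.data.loc[[cand, m]].T.corr(min_periods=3).iloc[0, 1]
                        for m in current
                        if cand in ctx.expression.data.index
                        and m in ctx.expression.data.index
                    ]
                    or [np.nan]
                )
            )
            admit = bool(np.isfinite(cand_corr) and np.isfinite(mod_corr) and cand_corr > mod_corr)
        if admit:
            current.append(cand)
            mean_after = _mean_pairwise(current, ctx.annotations, ctx.profiles)
        else:
            mean_after = mean_before
        trail.append(
            ExtensionStep(
                gene=cand,
                n_module_edges=edge_counts[cand],
                candidate_mean=cand_mean,
                module_mean_before=mean_before,
                module_mean_after=mean_after,
                admitted=admit,
            )
        )
    return set(current), trail
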