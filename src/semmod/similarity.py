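"""Expression and interaction-topology similarity channels.

Expression similarity is the pairwise-complete Pearson correlation between
gene profiles.  Topological similarity is a neighborhood-overlap score on
the protein-interaction network: directly interacting genes score 1, and
non-adjacent genes score the fraction of the smaller neighborhood they
share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Channel = Literal["expression", "topology", "semantic", "combined"]

#: minimum shared observed conditions for a Pearson correlation
MIN_SHARED_CONDITIONS = 3


@dataclass
class SimilarityMatrix:
    """Symmetric gene x gene similarity for one evidence channel."""

    genes: list[str]
    values: np.ndarray
    channel: Channel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} genes"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path: str | Path, channel: Channel) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(genes=list(df.index), values=df.to_numpy(), channel=channel)


@dataclass
class ExpressionMatrix:
    """Gene x condition real-valued matrix; entries may be missing (NaN)."""

    data: pd.DataFrame  # index: gene ids, columns: condition ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class InteractionNetwork:
    """Undirected protein-interaction network (no self-loops, deduplicated)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Expression TSV: first column gene id, header row of condition ids,
    empty cells / NA tokens treated as missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    return ExpressionMatrix(data=df)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Two-column TSV edge list; extra columns ignored, ``#`` comment lines
    skipped, reversed duplicates collapsed, self-loops dropped."""
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                continue
            a, b = cols[0], cols[1]
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
    if n_self:
        log.info("dropped %d self-loops from %s", n_self, path)
    return InteractionNetwork(graph=g)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


def expression_similarity(
    expr: ExpressionMatrix, universe: Sequence[str]
) -> SimilarityMatrix:
    """Pairwise-complete Pearson correlation e_ij over *universe*.

    Pairs with fewer than 3 shared observed conditions, and pairs involving
    a constant (zero-variance) profile, get e_ij = 0.  Diagonal is 1.
    """
    universe = list(universe)
    missing = [g for g in universe if g not in expr.data.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:10]}")
    sub = expr.data.loc[universe]
    # pandas corr(min_periods) is pairwise-complete Pearson
    corr = sub.T.corr(method="pearson", min_periods=MIN_SHARED_CONDITIONS)
    values = corr.to_numpy()
    n_undef = int(np.isnan(values).sum())
    if n_undef:
        log.warning(
            "%d gene pairs had <%d shared conditions or zero variance; "
            "their expression similarity is set to 0",
            (n_undef - np.isnan(np.diag(values)).sum()) // 2,
            MIN_SHARED_CONDITIONS,
        )
    values = np.nan_to_num(values, nan=0.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(genes=universe, values=values, channel="expression")


def topological_overlap(
    net: InteractionNetwork,
    universe: Sequence[str],
    mode: Literal["direct_one", "tom_standard"] = "direct_one",
    restrict_to_universe: bool = False,
) -> SimilarityMatrix:
    """Topological similarity t_ij over *universe*.

    Default ``direct_one`` mode: t_ij = 1 for a direct interaction,
    otherwise |N(i) ∩ N(j)| / min(k_i, k_j) (0 when either gene is
    isolated).  ``tom_standard`` mode uses the classical overlap formula
    (|N(i) ∩ N(j)| + a_ij) / (min(k_i, k_j) + 1 - a_ij).  Neighborhoods are
    taken on the full network before restriction to the universe unless
    *restrict_to_universe* is set.
    """
    universe = list(universe)
    if restrict_to_universe:
        g = net.graph.subgraph([u for u in universe if u in net.graph])
        work = InteractionNetwork(graph=nx.Graph(g))
    else:
        work = net
    n = len(universe)
    nbrs = [work.neighbors(g) for g in universe]
    deg = [work.degree(g) for g in universe]
    values = np.zeros((n, n))
    adj = work.graph
    for i in range(n):
        for j in range(i + 1, n):
            a_ij = 1 if adj.has_edge(universe[i], universe[j]) else 0
            shared = len(nbrs[i] & nbrs[j])
            kmin = min(deg[i], deg[j])
            if mode == "direct_one":
                if a_ij:
                    t = 1.0
                elif kmin > 0:
                    t = shared / kmin
                else:
                    t = 0.0
            elif mode == "tom_standard":
                denom = kmin + 1 - a_ij
                t = (shared + a_ij) / denom if denom > 0 else 0.0
            else:
                raise ValueError(f"unknown mode: {mode}")
            values[i, j] = values[j, i] = t
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(genes=universe, values=values, channel="topology")
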