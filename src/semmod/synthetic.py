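"""Seeded synthetic datasets with planted module structure.

Emulates the joint shape of a stress-response study: a gene x condition
expression matrix whose genes fall into co-expressed groups, a
planted-partition interaction network denser within groups than between,
and a toy one-namespace ontology whose annotations track the groups.  The
planted labels provide clustering ground truth, and optional "outsider"
genes outside the universe play the role of back nodes for extension
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import AnnotationTable, GeneOntology, build_annotation_table, write_obo
from .similarity import ExpressionMatrix, InteractionNetwork, write_edge_list, write_expression_tsv

N_BACKGROUND_TERMS = 5


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    network: InteractionNetwork
    ontology: GeneOntology
    annotations: AnnotationTable
    planted_labels: dict[str, int]
    outsiders: list[str]
    params: dict = field(default_factory=dict)

    @property
    def universe(self) -> list[str]:
        return list(self.annotations.universe)

    def planted_array(self) -> np.ndarray:
        return np.array([self.planted_labels[g] for g in self.universe])


def _toy_ontology(n_modules: int, terms_per_module: int) -> GeneOntology:
    """Root + one is_a chain of terms per module + shared background terms."""
    g = nx.MultiDiGraph()
    root = "T:ROOT"
    g.add_node(root, name="root")
    for m in range(n_modules):
        prev = root
        for d in range(terms_per_module):
            t = f"T:M{m}D{d + 1}"
            g.add_node(t, name=f"module {m} term depth {d + 1}")
            g.add_edge(t, prev, key="is_a")
            prev = t
    for b in range(N_BACKGROUND_TERMS):
        t = f"T:BG{b}"
        g.add_node(t, name=f"background term {b}")
        g.add_edge(t, root, key="is_a")
    return GeneOntology(graph=g, root=root, namespace="biological_process")


def generate_dataset(
    n_genes: int = 120,
    n_modules: int = 4,
    n_conditions: int = 30,
    expr_noise_sd: float = 0.5,
    p_in: float = 0.3,
    p_out: float = 0.02,
    terms_per_module: int = 3,
    annotation_fidelity: float = 0.9,
    outsider_fraction: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a dataset with *n_modules* planted gene modules.

    Genes are split evenly into modules.  Expression profiles are a
    module-specific standard-normal prototype plus N(0, expr_noise_sd)
    gene-level noise; the network is a planted partition (edge probability
    p_in within modules, p_out between); each gene is annotated to a term
    of its module's chain with probability *annotation_fidelity*, otherwise
    to a random background term.  ``outsider_fraction`` extra genes are
    generated outside the universe, wired into a host module and annotated
    to that module's terms, for extension tests.

    Three independent random streams (expression / network / annotation),
    all derived from *seed*, keep the components decoupled.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if not (0.0 <= annotation_fidelity <= 1.0):
        raise ValueError("annotation_fidelity must lie in [0,1]")
    if not (0.0 <= outsider_fraction < 1.0):
        raise ValueError("outsider_fraction must lie in [0,1)")
    if n_modules > n_genes:
        raise ValueError("n_modules cannot exceed n_genes")

    ss = np.random.SeedSequence(seed)
    rng_expr, rng_net, rng_ann = (np.random.default_rng(s) for s in ss.spawn(3))

    genes = [f"g{i:04d}" for i in range(n_genes)]
    labels = {g: i % n_modules for i, g in enumerate(genes)}
    n_out = int(round(outsider_fraction * n_genes))
    outsiders = [f"x{i:04d}" for i in range(n_out)]
    out_labels = {g: i % n_modules for i, g in enumerate(outsiders)}

    # expression: module prototypes + per-gene noise
    prototypes = rng_expr.standard_normal((n_modules, n_conditions))
    values = np.vstack(
        [
            prototypes[labels[g]]
            + rng_expr.standard_normal(n_conditions) * expr_noise_sd
            for g in genes
        ]
    )
    expr = ExpressionMatrix(
        data=pd.DataFrame(
            values, index=genes, columns=[f"c{j:03d}" for j in range(n_conditions)]
        )
    )

    # network: planted partition over universe + outsiders wired to hosts
    g_net = nx.Graph()
    g_net.add_nodes_from(genes + outsiders)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            p = p_in if labels[genes[i]] == labels[genes[j]] else p_out
            if rng_net.random() < p:
                g_net.add_edge(genes[i], genes[j])
    for o in outsiders:
        host = out_labels[o]
        for g in genes:
            if labels[g] == host and rng_net.random() < p_in:
                g_net.add_edge(o, g)
    network = InteractionNetwork(graph=g_net)

    ontology = _toy_ontology(n_modules, terms_per_module)
    module_terms = {
        m: [f"T:M{m}D{d + 1}" for d in range(terms_per_module)]
        for m in range(n_modules)
    }
    background = [f"T:BG{b}" for b in range(N_BACKGROUND_TERMS)]

    direct: dict[str, set[str]] = {}
    for g in genes + outsiders:
        m = labels.get(g, out_labels.get(g))
        if rng_ann.random() < annotation_fidelity:
            term = module_terms[m][rng_ann.integers(len(module_terms[m]))]
        else:
            term = background[rng_ann.integers(len(background))]
        direct[g] = {term}
    annotations = build_annotation_table(direct, ontology, universe=genes)

    params = dict(
        n_genes=n_genes, n_modules=n_modules, n_conditions=n_conditions,
        expr_noise_sd=expr_noise_sd, p_in=p_in, p_out=p_out,
        terms_per_module=terms_per_module,
        annotation_fidelity=annotation_fidelity,
        outsider_fraction=outsider_fraction, seed=seed,
    )
    return SyntheticDataset(
        expression=expr,
        network=network,
        ontology=ontology,
        annotations=annotations,
        planted_labels=labels,
        outsiders=outsiders,
        params=params,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact on-disk formats the pipeline reads
    (expression TSV, edge TSV, OBO, GAF, universe list, planted labels)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "network": outdir / "network.tsv",
        "obo": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
        "universe": outdir / "universe.txt",
        "labels": outdir / "planted_labels.tsv",
    }
    write_expression_tsv(ds.expression, paths["expression"])
    write_edge_list(ds.network, paths["network"])
    write_obo(ds.ontology, paths["obo"])
    with open(paths["gaf"], "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in sorted(ds.annotations.direct):
            for term in sorted(ds.annotations.direct[gene]):
                cols = ["SYN", gene, gene, "", term, "SYN:0000001", "IDA", "",
                        "P", "", "", "gene", "taxon:0", "20200101", "SYN", "", ""]
                fh.write("\t".join(cols) + "\n")
    with open(paths["universe"], "w") as fh:
        fh.write("\n".join(ds.universe) + "\n")
    with open(paths["labels"], "w") as fh:
        fh.write("gene_id\tplanted_module\n")
        for g in ds.universe:
            fh.write(f"{g}\t{ds.planted_labels[g]}\n")
    return paths
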