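"""Run configuration and end-to-end pipeline orchestration.

The pipeline reads expression / network / ontology / annotation files,
computes the three similarity channels, fuses them, clusters with
affinity propagation, evaluates the modules, and stamps every run with a
provenance record (config, seed, version, input checksums) sufficient to
reproduce the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import ClusterConfig, affinity_propagation, find_preference, preference_sweep
from .evaluation import (
    SUMMARY_THRESHOLD,
    coherence_depth,
    fisher_enrichment,
    homogeneity_and_connectivity,
    summary_grid,
)
from .integration import combine
from .ontology import parse_gaf, parse_obo
from .semantics import pairwise_semantic_matrix
from .similarity import (
    expression_similarity,
    read_edge_list,
    read_expression_tsv,
    topological_overlap,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    expression: str
    network: str
    obo: str
    gaf: str
    universe: str | None = None
    output_dir: str = "semmod_out"

    channels: list[str] = field(
        default_factory=lambda: ["expression", "topology", "semantic"]
    )
    tom_mode: str = "direct_one"
    restrict_to_universe: bool = False
    is_a_weight: float = 0.8
    part_of_weight: float = 0.6
    exclude_evidence: list[str] = field(default_factory=list)
    gaf_id_column: str = "object_id"
    namespace: str = "biological_process"

    target_k: int | None = None
    preference: float | None = None
    sweep: list[float] | None = None
    damping: float = 0.9
    max_iterations: int = 1000
    convergence_iterations: int = 100
    seed: int = 0

    summary_threshold: float = SUMMARY_THRESHOLD
    coherence_threshold: float = 1e-5
    write_similarities: bool = False

    def validate(self) -> None:
        modes = [self.target_k is not None, self.preference is not None,
                 self.sweep is not None]
        if sum(modes) != 1:
            raise ValueError(
                "exactly one of target_k / preference / sweep must be set"
            )
        for name in ("expression", "network", "obo", "gaf"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.universe is not None and not Path(self.universe).is_file():
            raise FileNotFoundError(f"universe file not found: {self.universe}")
        bad = set(self.channels) - {"expression", "topology", "semantic"}
        if bad:
            raise ValueError(f"unknown channels: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full modularization pipeline; returns output paths.

    Partial outputs are removed when any stage fails.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        expr = read_expression_tsv(config.expression)
        net = read_edge_list(config.network)
        onto = parse_obo(config.obo, config.namespace)
        if config.universe:
            universe = [
                ln.strip() for ln in open(config.universe) if ln.strip()
            ]
        else:
            universe = expr.genes
        ann = parse_gaf(
            config.gaf,
            onto,
            exclude_evidence=set(config.exclude_evidence),
            id_column=config.gaf_id_column,
            universe=universe,
        )

        weights = {"is_a": config.is_a_weight, "part_of": config.part_of_weight}
        channels = []
        if "expression" in config.channels:
            channels.append(expression_similarity(expr, universe))
        if "topology" in config.channels:
            channels.append(
                topological_overlap(
                    net, universe, mode=config.tom_mode,
                    restrict_to_universe=config.restrict_to_universe,
                )
            )
        if "semantic" in config.channels:
            channels.append(pairwise_semantic_matrix(ann, onto, weights=weights))
        combined = combine(*channels)

        if config.write_similarities:
            for ch in channels:
                p = outdir / f"similarity_{ch.channel}.tsv"
                ch.write_tsv(p)
                written[f"similarity_{ch.channel}"] = p
            p = outdir / "similarity_combined.tsv"
            combined.write_tsv(p)
            written["similarity_combined"] = p

        cc = ClusterConfig(
            preference=config.preference if config.preference is not None else -0.5,
            damping=config.damping,
            max_iterations=config.max_iterations,
            convergence_iterations=config.convergence_iterations,
            seed=config.seed,
        )
        if config.target_k is not None:
            pref, assignment = find_preference(combined, config.target_k, cc)
            assignments = [assignment]
        elif config.sweep is not None:
            assignments = preference_sweep(combined, config.sweep, cc)
        else:
            assignments = [affinity_propagation(combined, cc)]

        for i, asg in enumerate(assignments):
            tag = f"_{i}" if len(assignments) > 1 else ""
            p = outdir / f"modules{tag}.tsv"
            asg.write_tsv(p)
            written[f"modules{tag}"] = p

            table = fisher_enrichment(asg, ann)
            p = outdir / f"enrichment{tag}.tsv"
            table.to_csv(p, sep="\t", index=False)
            written[f"enrichment{tag}"] = p

            n_terms = len(
                {t for g in universe for t in ann.propagated_terms(g)}
            )
            grid = summary_grid(table, asg.n_modules, max(n_terms, 1))
            p = outdir / f"enrichment_summary{tag}.tsv"
            grid.to_csv(p, sep="\t", index=False)
            written[f"enrichment_summary{tag}"] = p

            coh = coherence_depth(table, onto, config.coherence_threshold, weights)
            p = outdir / f"coherence{tag}.tsv"
            coh.per_module.to_csv(p, sep="\t", index=False)
            written[f"coherence{tag}"] = p

            hc = homogeneity_and_connectivity(asg, expr, net)
            p = outdir / f"homogeneity_connectivity{tag}.tsv"
            hc.to_csv(p, sep="\t", index=False)
            written[f"homogeneity_connectivity{tag}"] = p

        prov = {
            "tool": "semmod",
            "version": __version__,
            "config": asdict(config),
            "input_checksums": {
                name: _sha256(getattr(config, name))
                for name in ("expression", "network", "obo", "gaf")
            },
            "n_genes": len(universe),
            "n_modules": [a.n_modules for a in assignments],
            "preferences": [a.preference for a in assignments],
            "converged": [a.converged for a in assignments],
        }
        p = outdir / "provenance.json"
        with open(p, "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)
        written["provenance"] = p
        return written
    except Exception:
        for p in written.values():
            if p.is_file():
                p.unlink()
        raise
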