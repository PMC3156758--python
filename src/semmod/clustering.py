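"""Affinity propagation clustering of the fused gene similarity.

Exemplar-based clustering by message passing: responsibilities and
availabilities are exchanged between genes until a stable set of exemplars
emerges.  A single globally shared preference (the self-similarity s(k,k))
controls the number of modules: larger (less negative) preferences produce
more, tighter modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .integration import CombinedSimilarity

log = logging.getLogger(__name__)


class NoExemplarError(RuntimeError):
    """No gene accumulated positive evidence of being an exemplar."""


@dataclass
class ClusterConfig:
    """Affinity propagation settings.

    preference: globally shared self-similarity, <= 0 on the shifted scale.
    damping: message mixing factor lambda in [0.5, 1).
    seed: seeds the tiny degeneracy-breaking noise added to similarities.
    """

    preference: float = -0.5
    damping: float = 0.9
    max_iterations: int = 1000
    convergence_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.damping < 1.0):
            raise ValueError(f"damping must lie in [0.5, 1), got {self.damping}")
        if self.convergence_iterations >= self.max_iterations:
            raise ValueError("convergence_iterations must be < max_iterations")
        if self.preference > 0:
            raise ValueError("preference must be <= 0")


@dataclass
class ModuleAssignment:
    """One clustering result: gene -> module labels with one exemplar each."""

    genes: list[str]
    labels: dict[str, int]
    exemplars: dict[int, str]
    n_modules: int
    converged: bool
    net_similarity: float
    preference: float | None = None
    seed: int | None = None

    def members(self, module: int) -> list[str]:
        return [g for g in self.genes if self.labels[g] == module]

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {m: [] for m in self.exemplars}
        for g in self.genes:
            out[self.labels[g]].append(g)
        return out

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[g] for g in self.genes])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# preference={self.preference}\n")
            fh.write(f"# seed={self.seed}\n")
            fh.write(f"# converged={self.converged}\n")
            fh.write(f"# n_modules={self.n_modules}\n")
            fh.write("gene_id\tmodule_index\tis_exemplar\n")
            for g in self.genes:
                m = self.labels[g]
                fh.write(f"{g}\t{m}\t{int(self.exemplars[m] == g)}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ModuleAssignment":
        meta: dict[str, str] = {}
        genes: list[str] = []
        labels: dict[str, int] = {}
        exemplars: dict[int, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    k, _, v = line[1:].strip().partition("=")
                    meta[k] = v
                    continue
                if not line or line.startswith("gene_id"):
                    continue
                g, m, is_ex = line.split("\t")
                genes.append(g)
                labels[g] = int(m)
                if is_ex == "1":
                    exemplars[int(m)] = g
        pref = meta.get("preference")
        seed = meta.get("seed")
        return cls(
            genes=genes,
            labels=labels,
            exemplars=exemplars,
            n_modules=len(exemplars),
            converged=meta.get("converged", "True") == "True",
            net_similarity=float("nan"),
            preference=None if pref in (None, "None") else float(pref),
            seed=None if seed in (None, "None") else int(seed),
        )


def _net_similarity(
    s_clean: np.ndarray, preference: float, labels: np.ndarray, exemplar_idx: np.ndarray
) -> float:
    """Sum of member-to-exemplar similarities plus exemplar preferences."""
    total = len(exemplar_idx) * preference
    for i, lab in enumerate(labels):
        k = exemplar_idx[lab]
        if i != k:
            total += s_clean[i, k]
    return float(total)


def affinity_propagation(
    sim: CombinedSimilarity, config: ClusterConfig
) -> ModuleAssignment:
    """Cluster genes by Frey-Dueck message passing on the shifted joint
    similarity.

    Runs damped responsibility/availability sweeps until the exemplar set
    {k : r(k,k) + a(k,k) > 0} is stable for ``convergence_iterations``
    sweeps; members are then assigned to their most similar exemplar.
    Raises :class:`NoExemplarError` when no exemplar emerges (the
    preference is too negative for any point to self-nominate).
    """
    s_clean = np.asarray(sim.ap_input, dtype=float)
    n = s_clean.shape[0]
    if s_clean.shape != (n, n) or n != len(sim.genes):
        raise ValueError("ap_input must be square and match the gene list")

    S = s_clean.copy()
    np.fill_diagonal(S, config.preference)
    # tiny seeded noise breaks exact ties that would otherwise oscillate
    rng = np.random.default_rng(config.seed)
    scale = 1e-12 * (np.max(np.abs(S)) or 1.0)
    S = S + rng.standard_normal((n, n)) * scale

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    lam = config.damping
    idx = np.arange(n)

    stable_count = 0
    prev_exemplars: frozenset[int] = frozenset()
    converged = False
    for _ in range(config.max_iterations):
        # responsibilities
        AS = A + S
        first = np.max(AS, axis=1)
        first_k = np.argmax(AS, axis=1)
        AS[idx, first_k] = -np.inf
        second = np.max(AS, axis=1)
        Rnew = S - first[:, None]
        Rnew[idx, first_k] = S[idx, first_k] - second
        R = lam * R + (1 - lam) * Rnew

        # availabilities
        Rp = np.maximum(R, 0)
        Rp[idx, idx] = R[idx, idx]
        col = np.sum(Rp, axis=0)
        Anew = col[None, :] - Rp
        diag = Anew[idx, idx].copy()
        Anew = np.minimum(Anew, 0)
        Anew[idx, idx] = diag
        A = lam * A + (1 - lam) * Anew

        ex = frozenset(np.flatnonzero(np.diag(R) + np.diag(A) > 0).tolist())
        if ex and ex == prev_exemplars:
            stable_count += 1
            if stable_count >= config.convergence_iterations:
                converged = True
                break
        else:
            stable_count = 0
        prev_exemplars = ex

    exemplar_idx = np.flatnonzero(np.diag(R) + np.diag(A) > 0)
    if exemplar_idx.size == 0:
        raise NoExemplarError(
            "no exemplar emerged; increase the preference (make it less negative)"
        )
    if not converged:
        warnings.warn(
            "affinity propagation did not converge within "
            f"{config.max_iterations} iterations; returning best-so-far",
            RuntimeWarning,
            stacklevel=2,
        )

    # members go to their most similar exemplar; exemplars stay their own
    labels = np.argmax(S[:, exemplar_idx], axis=1)
    labels[exemplar_idx] = np.arange(exemplar_idx.size)

    genes = sim.genes
    label_map = {genes[i]: int(labels[i]) for i in range(n)}
    exemplar_map = {m: genes[int(k)] for m, k in enumerate(exemplar_idx)}
    return ModuleAssignment(
        genes=list(genes),
        labels=label_map,
        exemplars=exemplar_map,
        n_modules=int(exemplar_idx.size),
        converged=converged,
        net_similarity=_net_similarity(s_clean, config.preference, labels, exemplar_idx),
        preference=config.preference,
        seed=config.seed,
    )


def find_preference(
    sim: CombinedSimilarity,
    target_k: int,
    config: ClusterConfig | None = None,
    tol: float = 1e-6,
    max_bisections: int = 60,
) -> tuple[float, ModuleAssignment]:
    """Bisection search for the shared preference producing *target_k* modules.

    Exploits the (empirically monotone) growth of the module count with the
    preference.  Returns the preference and the assignment whose module
    count is closest to *target_k* (ties favor fewer modules); the achieved
    count is logged when the target is unreachable.
    """
    n = len(sim.genes)
    if not (1 <= target_k <= n):
        raise ValueError(f"target_k must lie in [1, {n}], got {target_k}")
    base = config or ClusterConfig()

    def run(pref: float) -> ModuleAssignment | None:
        cfg = ClusterConfig(
            preference=pref,
            damping=base.damping,
            max_iterations=base.max_iterations,
            convergence_iterations=base.convergence_iterations,
            seed=base.seed,
        )
        try:
            return affinity_propagation(sim, cfg)
        except NoExemplarError:
            return None

    best: ModuleAssignment | None = None
    best_pref = 0.0

    def consider(pref: float, asg: ModuleAssignment | None) -> None:
        nonlocal best, best_pref
        if asg is None:
            return
        if best is None:
            best, best_pref = asg, pref
            return
        d_new, d_old = abs(asg.n_modules - target_k), abs(best.n_modules - target_k)
        if d_new < d_old or (d_new == d_old and asg.n_modules < best.n_modules):
            best, best_pref = asg, pref

    lower = float(np.min(sim.ap_input)) * n
    if lower == 0.0:
        lower = -float(n)
    asg_low = run(lower)
    doublings = 0
    while asg_low is not None and asg_low.n_modules > target_k and doublings < 30:
        lower *= 2
        asg_low = run(lower)
        doublings += 1
    consider(lower, asg_low)

    upper = 0.0
    asg_up = run(upper)
    consider(upper, asg_up)

    if best is not None and best.n_modules == target_k:
        return best_pref, best

    for _ in range(max_bisections):
        if upper - lower < tol:
            break
        mid = (lower + upper) / 2
        asg_mid = run(mid)
        consider(mid, asg_mid)
        if asg_mid is not None and asg_mid.n_modules == target_k:
            return mid, asg_mid
        if asg_mid is None or asg_mid.n_modules < target_k:
            lower = mid
        else:
            upper = mid

    if best is None:
        raise NoExemplarError("no preference produced any exemplars")
    if best.n_modules != target_k:
        log.warning(
            "target of %d modules unreachable; closest achieved: %d "
            "(preference %.6g)", target_k, best.n_modules, best_pref,
        )
    return best_pref, best


def preference_sweep(
    sim: CombinedSimilarity,
    preferences: list[float],
    config: ClusterConfig | None = None,
) -> list[ModuleAssignment]:
    """Cluster once per preference to expose the module hierarchy; smaller
    preferences yield coarser module sets."""
    base = config or ClusterConfig()
    out = []
    for pref in preferences:
        cfg = ClusterConfig(
            preference=pref,
            damping=base.damping,
            max_iterations=base.max_iterations,
            convergence_iterations=base.convergence_iterations,
            seed=base.seed,
        )
        out.append(affinity_propagation(sim, cfg))
    return out
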