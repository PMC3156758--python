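"""Rank-based fusion of similarity channels.

Each channel's pairwise values are converted to probabilities through the
channel's empirical CDF over all strictly-upper-triangle pairs, the
probabilities are multiplied under an independence assumption, and the
joint probability minus one becomes the non-positive input required by
affinity propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix


@dataclass
class EmpiricalCDF:
    """ECDF over the n(n-1)/2 upper-triangle similarities of one channel.

    evaluate(x) = (# observed values <= x) / n_pairs, so the largest
    observed value maps to probability 1 and ties share a probability.
    """

    sorted_values: np.ndarray
    n_pairs: int

    def evaluate(self, x: np.ndarray | float) -> np.ndarray | float:
        counts = np.searchsorted(self.sorted_values, x, side="right")
        return counts / self.n_pairs


def empirical_cdf(matrix: SimilarityMatrix) -> EmpiricalCDF:
    """ECDF of a channel's strictly-upper-triangle values (diagonal excluded)."""
    n = len(matrix.genes)
    if n < 2:
        raise ValueError("need at least 2 genes to form pairs")
    iu = np.triu_indices(n, k=1)
    vals = np.sort(matrix.values[iu])
    return EmpiricalCDF(sorted_values=vals, n_pairs=vals.size)


@dataclass
class CombinedSimilarity:
    """Joint channel probability per gene pair and its shift to AP input.

    ``joint`` holds Pr(E<=e_ij) * Pr(T<=t_ij) * Pr(G<=g_ij) in (0,1];
    ``ap_input`` = joint - 1 lies in [-1,0].  The diagonal is a placeholder
    (1 / 0): clustering replaces self-similarity by the preference.
    """

    genes: list[str]
    joint: np.ndarray
    ap_input: np.ndarray

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.joint, index=self.genes, columns=self.genes).to_csv(
            path, sep="\t", index_label="gene"
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CombinedSimilarity":
        df = pd.read_csv(path, sep="\t", index_col=0)
        joint = df.to_numpy()
        return cls(genes=list(df.index), joint=joint, ap_input=joint - 1.0)


def combine(*channels: SimilarityMatrix) -> CombinedSimilarity:
    """Fuse any subset of similarity channels (default use: all three).

    Every channel is mapped through its own ECDF and the per-pair
    probabilities are multiplied; ranks within a channel are preserved and
    a constant channel multiplies every pair by 1.
    """
    if not channels:
        raise ValueError("need at least one similarity channel")
    genes = channels[0].genes
    for ch in channels[1:]:
        if ch.genes != genes:
            raise ValueError(
                f"gene ordering mismatch between channels "
                f"({ch.channel} vs {channels[0].channel})"
            )
    n = len(genes)
    joint = np.ones((n, n))
    for ch in channels:
        cdf = empirical_cdf(ch)
        joint *= np.asarray(cdf.evaluate(ch.values))
    joint = (joint + joint.T) / 2.0  # symmetric channels give symmetric output
    np.fill_diagonal(joint, 1.0)
    return CombinedSimilarity(genes=list(genes), joint=joint, ap_input=joint - 1.0)
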