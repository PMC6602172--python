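"""Shared container for bootstrapped feature rankings."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ImportanceRanking", "rank_by_magnitude"]


def rank_by_magnitude(scores: np.ndarray, taxon_ids: list[str]) -> np.ndarray:
    """Rank 1..M by |score| descending; ties broken by taxon id (lexicographic).

    ``rank[m]`` is the rank of taxon m (1 = most important).
    """
    scores = np.asarray(scores, dtype=float)
    order = sorted(
        range(len(scores)), key=lambda m: (-abs(scores[m]), taxon_ids[m])
    )
    rank = np.empty(len(scores), dtype=int)
    for pos, m in enumerate(order):
        rank[m] = pos + 1
    return rank


@dataclass
class ImportanceRanking:
    """Per-taxon importance with bootstrap replicates and a 1..M ranking.

    ``mean_importance`` is signed for gradient-based (neural-network)
    importance — positive values mean the taxon pushes the predicted
    function up — and non-negative for impurity-based (random-forest)
    importance.
    """

    taxon_ids: list[str]
    mean_importance: np.ndarray
    per_bootstrap: np.ndarray
    rank: np.ndarray
    signed: bool
    method: str = ""

    def __post_init__(self) -> None:
        m = len(self.taxon_ids)
        self.mean_importance = np.asarray(self.mean_importance, dtype=float)
        self.per_bootstrap = np.atleast_2d(
            np.asarray(self.per_bootstrap, dtype=float)
        )
        self.rank = np.asarray(self.rank, dtype=int)
        if self.mean_importance.shape != (m,) or self.rank.shape != (m,):
            raise ValueError("importance/rank length must match taxon_ids")
        if self.per_bootstrap.shape[1] != m:
            raise ValueError("per_bootstrap must have one column per taxon")
        if sorted(self.rank) != list(range(1, m + 1)):
            raise ValueError("rank must be a permutation of 1..M")

    @property
    def n_bootstrap(self) -> int:
        return self.per_bootstrap.shape[0]

    def ordered_taxa(self) -> list[str]:
        """Taxon ids from most to least important."""
        return [t for _, t in sorted(zip(self.rank, self.taxon_ids))]

    def top(self, k: int) -> set[str]:
        """The top-k taxon ids as a set."""
        if k <= 0:
            raise ValueError("k must be positive")
        return set(self.ordered_taxa()[:k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": self.taxon_ids,
                "mean_importance": self.mean_importance,
                "sd": self.per_bootstrap.std(axis=0, ddof=0),
                "rank": self.rank,
            }
        ).sort_values("rank", ignore_index=True)
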