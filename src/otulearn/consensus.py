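"""Consensus feature selection across NN, RF and indicator-taxa rankings.

Because no ground truth exists for which taxa drive an ecosystem function,
the intersection of independently derived feature selections is taken as
the robust "consensus" set: taxa ranked in the top k by the neural-network
gradient importance, in the top k by random-forest impurity importance, and
significant under indicator analysis (whose count defines the default k).
A Monte Carlo null — three independently shuffled orderings of the same M
taxa — quantifies how many shared taxa pure chance would produce: the
expected triple overlap of top-k prefixes is k^3/M^2 and each pairwise
overlap k^2/M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indicators import (
    HIGH,
    IndicatorResult,
    indicator_ordering,
    significant_taxa,
)
from .ranking import ImportanceRanking

__all__ = [
    "top_k_sets",
    "overlap_curve",
    "mc_overlap_null",
    "OverlapNull",
    "sign_agreement",
    "consensus_table",
    "performance_vs_features",
]


def top_k_sets(
    nn_ranking: ImportanceRanking,
    rf_ranking: ImportanceRanking,
    indicator_results: list[IndicatorResult],
    k: int | None = None,
) -> tuple[set[str], set[str], set[str]]:
    """(NN top-k, RF top-k, significant indicator taxa).

    By default k equals the number of significant indicator taxa, so the
    three selections are size-matched.
    """
    ind_set = significant_taxa(indicator_results)
    if k is None:
        k = len(ind_set)
    if k <= 0:
        raise ValueError("k must be positive (no significant indicator taxa?)")
    return nn_ranking.top(k), rf_ranking.top(k), ind_set


def overlap_curve(
    nn_order: list[str],
    rf_order: list[str],
    indicator_order: list[str],
    k_max: int,
) -> pd.DataFrame:
    """Shared-taxa counts among top-k prefixes for k = 1..k_max.

    Returns columns ``nn_rf``, ``nn_is``, ``rf_is``, ``triple`` indexed by
    k; every curve is monotone non-decreasing because top-k sets are nested.
    """
    m = min(len(nn_order), len(rf_order), len(indicator_order))
    if k_max > m:
        raise ValueError(f"k_max {k_max} exceeds ranking length {m}")
    pos = {}
    for name, order in (
        ("nn", nn_order), ("rf", rf_order), ("is", indicator_order)
    ):
        pos[name] = {t: i for i, t in enumerate(order)}
    curves = {}
    # a taxon enters a curve at k = 1 + max(position across the lists); the
    # curve at k is the count of shared taxa whose entry point is <= k
    for key, names in (("nn_rf", ("nn", "rf")), ("nn_is", ("nn", "is")),
                       ("rf_is", ("rf", "is")), ("triple", ("nn", "rf", "is"))):
        shared = set.intersection(*(set(
            {"nn": nn_order, "rf": rf_order, "is": indicator_order}[n]
        ) for n in names))
        entry = [max(pos[n][t] for n in names) for t in shared]
        hist = np.bincount([e for e in entry if e < k_max], minlength=k_max)
        curves[key] = np.cumsum(hist[:k_max])
    return pd.DataFrame(curves, index=pd.RangeIndex(1, k_max + 1, name="k"))


@dataclass
class OverlapNull:
    """Monte Carlo null for top-k overlaps of independently shuffled rankings."""

    k: np.ndarray
    triple_mean: np.ndarray
    triple_lo: np.ndarray
    triple_hi: np.ndarray
    pairwise_mean: np.ndarray
    pairwise_lo: np.ndarray
    pairwise_hi: np.ndarray
    n_sim: int
    ci: float


def mc_overlap_null(
    M_total: int,
    k_max: int,
    n_sim: int = 1000,
    ci: float = 0.99,
    seed: int = 0,
) -> OverlapNull:
    """Simulate overlaps of top-k prefixes of three random orderings.

    For each simulation three independent uniform permutations of
    ``M_total`` items are drawn; for every k the triple (and one pairwise)
    top-k intersection is counted. Reports the mean and equal-tailed
    ``ci`` interval across simulations. E[triple] = k^3/M^2,
    E[pairwise] = k^2/M.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if k_max > M_total:
        raise ValueError("k_max exceeds M_total")
    rng = np.random.default_rng(seed)
    triple = np.empty((n_sim, k_max), dtype=int)
    pair = np.empty((n_sim, k_max), dtype=int)
    for s in range(n_sim):
        pa = rng.permutation(M_total)
        pb = rng.permutation(M_total)
        pc = rng.permutation(M_total)
        # item i is in all three top-k sets iff max(position) < k
        mx3 = np.maximum(np.maximum(pa, pb), pc)
        mx2 = np.maximum(pa, pb)
        triple[s] = np.cumsum(np.bincount(mx3, minlength=M_total)[:k_max])
        pair[s] = np.cumsum(np.bincount(mx2, minlength=M_total)[:k_max])
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    return OverlapNull(
        k=np.arange(1, k_max + 1),
        triple_mean=triple.mean(axis=0),
        triple_lo=np.quantile(triple, lo_q, axis=0),
        triple_hi=np.quantile(triple, hi_q, axis=0),
        pairwise_mean=pair.mean(axis=0),
        pairwise_lo=np.quantile(pair, lo_q, axis=0),
        pairwise_hi=np.quantile(pair, hi_q, axis=0),
        n_sim=n_sim,
        ci=ci,
    )


def sign_agreement(
    nn_ranking: ImportanceRanking,
    indicator_results: list[IndicatorResult],
    k: int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Direction agreement between NN importance signs and indicator classes.

    Over taxa in both selected sets (NN top-k and significant indicators), a
    taxon agrees when its NN sensitivity is positive and its indicator class
    is "high", or negative and "low". Returns the agreement fraction and a
    per-taxon table.
    """
    ind_set = significant_taxa(indicator_results)
    if k is None:
        k = len(ind_set)
    shared = nn_ranking.top(k) & ind_set
    if not shared:
        raise ValueError("no taxa shared between the selected sets")
    sign = dict(zip(nn_ranking.taxon_ids, np.sign(nn_ranking.mean_importance)))
    cls = {r.taxon_id: r.best_class for r in indicator_results}
    rows = []
    for t in sorted(shared):
        agree = (sign[t] > 0 and cls[t] == HIGH) or (
            sign[t] < 0 and cls[t] != HIGH
        )
        rows.append((t, sign[t], cls[t], agree))
    df = pd.DataFrame(
        rows, columns=["taxon_id", "nn_sign", "indicator_class", "agree"]
    )
    return float(df["agree"].mean()), df


def consensus_table(
    nn_ranking: ImportanceRanking,
    rf_ranking: ImportanceRanking,
    indicator_results: list[IndicatorResult],
    k: int | None = None,
) -> pd.DataFrame:
    """Combined per-taxon table with top-k membership flags and the consensus
    indicator (member of all three selections), sorted by the indicator
    statistic among consensus taxa first."""
    nn_set, rf_set, ind_set = top_k_sets(
        nn_ranking, rf_ranking, indicator_results, k
    )
    iv = {r.taxon_id: r for r in indicator_results}
    nn_imp = dict(zip(nn_ranking.taxon_ids, nn_ranking.mean_importance))
    rf_imp = dict(zip(rf_ranking.taxon_ids, rf_ranking.mean_importance))
    rows = []
    for t in nn_ranking.taxon_ids:
        r = iv.get(t)
        rows.append(
            {
                "taxon_id": t,
                "nn_importance": nn_imp.get(t, np.nan),
                "rf_importance": rf_imp.get(t, np.nan),
                "indval_best": r.best_score if r else np.nan,
                "indval_class": r.best_class if r else "",
                "in_nn": t in nn_set,
                "in_rf": t in rf_set,
                "in_indicator": t in ind_set,
                "in_consensus": t in nn_set and t in rf_set and t in ind_set,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["in_consensus", "indval_best"], ascending=[False, False],
        ignore_index=True,
    )


def performance_vs_features(
    order: list[str],
    taxon_ids: list[str],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    fit_predict,
    k_min: int = 10,
    k_max: int | None = None,
    bin_size: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Test correlation as the model sees an increasing prefix of a ranking.

    For every k in ``k_min..k_max`` the model is retrained on the top-k
    features of ``order`` alone and scored by Pearson r on the test set;
    trials are averaged in bins of ``bin_size`` consecutive k values.

    ``fit_predict(X_tr, y_tr, X_te, seed) -> predictions`` abstracts the
    model (NN or RF).
    """
    from .evaluation import pearson_r

    if k_max is None:
        k_max = len(order)
    if k_max > len(order):
        raise ValueError("k_max exceeds ranking length")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    col = {t: j for j, t in enumerate(taxon_ids)}
    rng = np.random.default_rng(seed)
    ks, rs = [], []
    for k in range(k_min, k_max + 1):
        cols = [col[t] for t in order[:k]]
        pred = fit_predict(
            X_train[:, cols], y_train, X_test[:, cols],
            int(rng.integers(0, 2**31 - 1)),
        )
        ks.append(k)
        rs.append(pearson_r(y_test, pred))
    df = pd.DataFrame({"k": ks, "r": rs})
    df["bin"] = (df["k"] - k_min) // bin_size
    out = df.groupby("bin").agg(
        k_mid=("k", "mean"), r_mean=("r", "mean"), n=("k", "size")
    )
    return out.reset_index(drop=True)
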