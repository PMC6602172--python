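"""Indicator taxa analysis (Dufrene-Legendre IndVal) for a binarized target.

Samples are labelled "high" or "low" by splitting the continuous target
(default: median split). For each taxon t and class c the indicator value is
the product of

* specificity A_tc — mean abundance of t in class c divided by the sum of
  its class mean abundances, and
* fidelity B_tc — the fraction of class-c samples in which t is present
  (count > 0).

IndVal is maximal (1.0) for a taxon present in every sample of one class and
absent from the other. Confidence is assessed by recomputing each taxon's
best IndVal under randomly shuffled labels; a taxon is a significant
indicator when its observed best score beats at least 95% of the null
scores. The analysis runs on raw (rarefied) counts — presence/absence and
abundance shares are meaningless after z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import OtuTable, TargetVector

__all__ = [
    "IndicatorResult",
    "binarize_target",
    "indval_scores",
    "permutation_confidence",
    "significant_taxa",
    "indicator_ordering",
    "results_to_frame",
]

HIGH, LOW = "high", "low"


@dataclass
class IndicatorResult:
    """IndVal outcome for one taxon."""

    taxon_id: str
    indval_high: float
    indval_low: float
    best_class: str
    best_score: float
    confidence: float  # fraction of null best-scores strictly below observed
    significant: bool  # confidence >= 0.95


def binarize_target(
    y: TargetVector | np.ndarray, rule: str | tuple = "median"
) -> np.ndarray:
    """Label samples high/low on the target.

    ``rule`` is ``"median"`` (default; ties go to "low"), ``("quantile", q)``
    (high above the q-th quantile) or ``("threshold", t)`` (high strictly
    above t).
    """
    y = np.asarray(getattr(y, "values", y), dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("constant target cannot be binarized")
    if rule == "median":
        cut = float(np.median(y))
    elif isinstance(rule, tuple) and rule[0] == "quantile":
        cut = float(np.quantile(y, rule[1]))
    elif isinstance(rule, tuple) and rule[0] == "threshold":
        cut = float(rule[1])
    else:
        raise ValueError(f"unknown binarization rule: {rule!r}")
    labels = np.where(y > cut, HIGH, LOW)
    if len(np.unique(labels)) < 2:
        raise ValueError("binarization rule produced a single class")
    return labels


def _indval_arrays(counts: np.ndarray, is_high: np.ndarray):
    """Vectorized per-taxon (indval_high, indval_low)."""
    counts = np.asarray(counts, dtype=float)
    mean_high = counts[is_high].mean(axis=0)
    mean_low = counts[~is_high].mean(axis=0)
    denom = mean_high + mean_low
    safe = np.where(denom == 0, 1.0, denom)  # absent-everywhere -> 0/0 := 0
    a_high = np.where(denom == 0, 0.0, mean_high / safe)
    a_low = np.where(denom == 0, 0.0, mean_low / safe)
    b_high = (counts[is_high] > 0).mean(axis=0)
    b_low = (counts[~is_high] > 0).mean(axis=0)
    return a_high * b_high, a_low * b_low


def indval_scores(
    table: OtuTable, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon (indval_high, indval_low) for the given high/low labels."""
    if table.standardized:
        raise ValueError("indicator analysis requires raw counts")
    labels = np.asarray(labels)
    if len(labels) != table.n_samples:
        raise ValueError("labels length mismatch")
    is_high = labels == HIGH
    if is_high.all() or not is_high.any():
        raise ValueError("both classes must be non-empty")
    return _indval_arrays(table.counts, is_high)


def permutation_confidence(
    table: OtuTable,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[IndicatorResult]:
    """IndVal with label-permutation confidence for every taxon.

    For each of ``n_perm`` random label shuffles the best (max over classes)
    IndVal is recomputed per taxon; confidence is the fraction of null
    best-scores strictly below the observed best score, and a taxon is
    significant when confidence >= 1 - alpha. Ties with null scores count
    against significance (conservative).
    """
    if n_perm < 99:
        raise ValueError(
            "n_perm < 99 cannot resolve a 95% confidence threshold"
        )
    iv_high, iv_low = indval_scores(table, labels)
    best = np.maximum(iv_high, iv_low)
    is_high = np.asarray(labels) == HIGH
    rng = np.random.default_rng(seed)
    counts = np.asarray(table.counts, dtype=float)
    below = np.zeros(table.n_taxa)
    for _ in range(n_perm):
        perm = rng.permutation(is_high)
        ph, pl = _indval_arrays(counts, perm)
        below += np.maximum(ph, pl) < best
    conf = below / n_perm
    results = []
    for m, t in enumerate(table.taxon_ids):
        results.append(
            IndicatorResult(
                taxon_id=t,
                indval_high=float(iv_high[m]),
                indval_low=float(iv_low[m]),
                best_class=HIGH if iv_high[m] >= iv_low[m] else LOW,
                best_score=float(best[m]),
                confidence=float(conf[m]),
                significant=bool(conf[m] >= 1 - alpha),
            )
        )
    return results


def significant_taxa(results: list[IndicatorResult]) -> set[str]:
    return {r.taxon_id for r in results if r.significant}


def indicator_ordering(results: list[IndicatorResult]) -> list[str]:
    """Taxa ordered for rank-based comparisons: best IndVal descending,
    ties by confidence (descending) then taxon id."""
    return [
        r.taxon_id
        for r in sorted(
            results, key=lambda r: (-r.best_score, -r.confidence, r.taxon_id)
        )
    ]


def results_to_frame(results: list[IndicatorResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [r.taxon_id for r in results],
            "indval_high": [r.indval_high for r in results],
            "indval_low": [r.indval_low for r in results],
            "best_class": [r.best_class for r in results],
            "best_score": [r.best_score for r in results],
            "confidence": [r.confidence for r in results],
            "significant": [r.significant for r in results],
        }
    )
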