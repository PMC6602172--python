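"""Metrics and the repeated-split generalization experiments.

Contains the scalar metrics (Pearson r, MSE, residual correlation between
models), the 50-permutation experiment comparing model x feature-set arms
on shared replicate-aware splits, two-sample comparisons of per-permutation
correlations, the training-set-size sensitivity analysis, and per-taxon
abundance/prevalence summaries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import OtuTable, TargetVector, group_split, standardize
from .nn import NNTrainConfig, predict_nn, train_nn
from .rf import ForestConfig, predict_rf, train_rf

__all__ = [
    "pearson_r",
    "mse",
    "error_correlation",
    "permutation_experiment",
    "PermutationExperimentResult",
    "compare_arms",
    "sample_size_sensitivity",
    "abundance_prevalence",
]


def pearson_r(y_true, y_pred) -> float:
    """Product-moment correlation between true and predicted targets."""
    a = np.asarray(getattr(y_true, "values", y_true), dtype=float)
    b = np.asarray(getattr(y_pred, "values", y_pred), dtype=float)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if len(a) < 2:
        raise ValueError("need at least two samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)


def mse(y_true, y_pred) -> float:
    a = np.asarray(getattr(y_true, "values", y_true), dtype=float)
    b = np.asarray(getattr(y_pred, "values", y_pred), dtype=float)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if len(a) == 0:
        raise ValueError("empty vectors")
    return float(np.mean((a - b) ** 2))


def error_correlation(errors_a, errors_b) -> float:
    """Pearson correlation of two models' residual vectors on the same test
    samples (in the same order)."""
    return pearson_r(errors_a, errors_b)


# ---------------------------------------------------------------------------
# Repeated-split experiment


def _partition_checksum(table: OtuTable) -> str:
    h = hashlib.sha256()
    h.update("\n".join(table.sample_ids).encode())
    h.update(np.ascontiguousarray(table.counts).tobytes())
    return h.hexdigest()


@dataclass
class PermutationExperimentResult:
    """Per-permutation metrics for each (model x feature-set) arm.

    ``records`` has one row per permutation per arm (seed, sizes, r, mse);
    ``errors[arm][p]`` stores that arm's absolute test errors in permutation
    p, aligned across arms so per-sample win fractions can be computed;
    ``checksums[p]`` fingerprints the shared train/test partition.
    """

    records: pd.DataFrame
    errors: dict[str, list[np.ndarray]]
    checksums: list[tuple[str, str]]

    def arm_r(self, arm: str) -> np.ndarray:
        sub = self.records[self.records["arm"] == arm]
        return sub.sort_values("permutation")["r"].to_numpy()

    def summary(self) -> pd.DataFrame:
        return (
            self.records.groupby("arm")["r"]
            .agg(mean_r="mean", sd_r=lambda v: v.std(ddof=1), n="size")
            .reset_index()
        )


def _fit_predict_arm(arm, Xtr, ytr, Xte, nn_config, rf_config, seed, groups):
    model = arm.split("_")[0]
    if model == "nn":
        params = train_nn(
            Xtr, ytr, replace(nn_config, seed=seed), groups=groups
        )
        return predict_nn(params, Xte)
    if model == "rf":
        forest = train_rf(Xtr, ytr, replace(rf_config, seed=seed))
        return predict_rf(forest, Xte)
    raise ValueError(f"unknown arm {arm!r}")


def permutation_experiment(
    table: OtuTable,
    target: TargetVector,
    reduced_set: list[str] | None = None,
    n_perm: int = 50,
    test_fraction: float = 51 / 308,
    arms: tuple[str, ...] = ("nn_full", "nn_reduced", "rf_full", "rf_reduced"),
    nn_config: NNTrainConfig | None = None,
    rf_config: ForestConfig | None = None,
    seed: int = 0,
) -> PermutationExperimentResult:
    """Train/test every arm on ``n_perm`` replicate-aware random splits.

    Within a permutation all arms share the identical partition (verified by
    checksum) and identical standardization, so differences between arms
    reflect the model and feature set only. "reduced" arms restrict the
    feature matrix to ``reduced_set`` (e.g. the consensus taxa), which is
    held fixed across permutations.
    """
    if any(a.endswith("_reduced") for a in arms):
        if not reduced_set:
            raise ValueError("reduced arms require a non-empty reduced_set")
        missing = set(reduced_set) - set(table.taxon_ids)
        if missing:
            raise ValueError(f"reduced_set taxa not in table: {sorted(missing)}")
    nn_config = nn_config or NNTrainConfig()
    rf_config = rf_config or ForestConfig()
    rng = np.random.default_rng(seed)
    rows, checksums = [], []
    errors: dict[str, list[np.ndarray]] = {a: [] for a in arms}
    col = {t: j for j, t in enumerate(table.taxon_ids)}
    reduced_cols = [col[t] for t in (reduced_set or [])]
    for p in range(n_perm):
        split_seed = int(rng.integers(0, 2**31 - 1))
        (tr_t, tr_y), (te_t, te_y) = group_split(
            table, target, test_fraction, split_seed
        )
        (tr_s, te_s), _ = standardize(tr_t, [te_t])
        checksums.append(
            (_partition_checksum(tr_t), _partition_checksum(te_t))
        )
        for arm in arms:
            Xtr, Xte = tr_s.counts, te_s.counts
            if arm.endswith("_reduced"):
                Xtr, Xte = Xtr[:, reduced_cols], Xte[:, reduced_cols]
            pred = _fit_predict_arm(
                arm, Xtr, tr_y.values, Xte,
                nn_config, rf_config,
                int(rng.integers(0, 2**31 - 1)), tr_t.group_ids,
            )
            rows.append(
                {
                    "permutation": p,
                    "arm": arm,
                    "seed": split_seed,
                    "n_train": tr_t.n_samples,
                    "n_test": te_t.n_samples,
                    "r": pearson_r(te_y.values, pred),
                    "mse": mse(te_y.values, pred),
                }
            )
            errors[arm].append(np.abs(pred - te_y.values))
    return PermutationExperimentResult(
        records=pd.DataFrame(rows), errors=errors, checksums=checksums
    )


def compare_arms(
    result: PermutationExperimentResult,
    arm_a: str,
    arm_b: str,
    paired: bool = False,
) -> tuple[float, float]:
    """Two-tailed t-test on per-permutation r values plus a win fraction.

    Default is Welch's unpaired test; ``paired=True`` uses the paired test,
    defensible because arms share each permutation's split. The win fraction
    is the share of test samples (pooled over permutations) on which arm_a's
    absolute error is strictly smaller.
    """
    ra, rb = result.arm_r(arm_a), result.arm_r(arm_b)
    if len(ra) < 2 or len(rb) < 2:
        raise ValueError("need at least two permutations per arm")
    if paired:
        test = stats.ttest_rel(ra, rb)
    else:
        test = stats.ttest_ind(ra, rb, equal_var=False)
    ea = np.concatenate(result.errors[arm_a])
    eb = np.concatenate(result.errors[arm_b])
    win = float(np.mean(ea < eb))
    return float(test.pvalue), win


# ---------------------------------------------------------------------------
# Sample-size sensitivity


def sample_size_sensitivity(
    train: tuple[OtuTable, TargetVector],
    test: tuple[OtuTable, TargetVector],
    fractions: list[float],
    fit_predict,
    n_rep: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Learning curve: test r after training on random fractions of the
    training set (replicate-group-aware draws), ``n_rep`` draws each.

    ``fit_predict(X_tr, y_tr, X_te, seed, groups) -> predictions``.
    Returns one row per (fraction, replicate) plus use ``groupby`` for the
    mean +/- sd curve.
    """
    tr_t, tr_y = train
    te_t, te_y = test
    rng = np.random.default_rng(seed)
    rows = []
    groups = tr_t.group_ids or [str(i) for i in range(tr_t.n_samples)]
    uniq = list(dict.fromkeys(groups))
    by_group = {g: np.flatnonzero([gg == g for gg in groups]) for g in uniq}
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
        target_n = frac * tr_t.n_samples
        if target_n < 10:
            raise ValueError(
                f"fraction {frac} yields fewer than 10 training samples"
            )
        for rep in range(n_rep):
            if frac == 1.0:
                idx = np.arange(tr_t.n_samples)
            else:
                order = rng.permutation(len(uniq))
                chosen: list[int] = []
                for gi in order:
                    g = uniq[gi]
                    if abs(len(chosen) + len(by_group[g]) - target_n) <= abs(
                        len(chosen) - target_n
                    ):
                        chosen.extend(by_group[g])
                    else:
                        break
                idx = np.array(sorted(chosen))
            sub_t = tr_t.subset_samples(idx)
            sub_y = TargetVector(tr_y.values[idx])
            (sub_s, te_s), _ = standardize(sub_t, [te_t])
            pred = fit_predict(
                sub_s.counts, sub_y.values, te_s.counts,
                int(rng.integers(0, 2**31 - 1)), sub_t.group_ids,
            )
            rows.append(
                {
                    "fraction": frac,
                    "replicate": rep,
                    "n_train": len(idx),
                    "r": pearson_r(te_y.values, pred),
                }
            )
    return pd.DataFrame(rows)


def abundance_prevalence(table: OtuTable) -> pd.DataFrame:
    """Per-taxon mean count over all samples and fraction of samples where
    the taxon is present (count > 0). Raw counts only."""
    if table.standardized:
        raise ValueError("abundance/prevalence require raw counts")
    counts = np.asarray(table.counts, dtype=float)
    return pd.DataFrame(
        {
            "taxon_id": table.taxon_ids,
            "abundance": counts.mean(axis=0),
            "prevalence": (counts > 0).mean(axis=0),
        }
    )
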