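"""Random-forest regression with impurity importance and bootstrap ranking.

Tree induction is delegated to scikit-learn's
:class:`~sklearn.ensemble.RandomForestRegressor`; this module owns the
configuration contract (1000 trees, squared-error splits, two samples to
split an internal node, one per leaf), the importance normalization and the
80%-subsample / 50-iteration bootstrap ranking wrapper shared with the
neural-network path. Forest predictions are leaf averages, so they can never
leave the range of the training targets — a property exploited by the
community-design analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .ranking import ImportanceRanking, rank_by_magnitude

__all__ = [
    "ForestConfig",
    "TrainedForest",
    "train_rf",
    "predict_rf",
    "rf_importance",
    "bootstrap_rf_ranking",
    "random_search_rf",
]


@dataclass
class ForestConfig:
    """Random-forest hyperparameters (defaults follow common regression use:
    1000 trees, MSE splits, all features considered at every split)."""

    n_trees: int = 1000
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    max_features: float | int | None = 1.0  # fraction or count per split
    max_depth: int | None = None
    bootstrap: bool = True  # per-tree row resampling (bagging)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


@dataclass
class TrainedForest:
    """A fitted forest plus the training-target range (its prediction bounds)."""

    model: RandomForestRegressor
    y_min: float
    y_max: float
    config: ForestConfig


def train_rf(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: ForestConfig | None = None,
) -> TrainedForest:
    """Fit an ensemble of CART regression trees on (possibly bootstrapped)
    row subsamples; prediction is the mean over trees."""
    config = config or ForestConfig()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(getattr(y_train, "values", y_train), dtype=float)
    if X.shape[0] < config.min_samples_split:
        raise ValueError(
            f"{X.shape[0]} training rows < min_samples_split "
            f"{config.min_samples_split}"
        )
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        criterion="squared_error",
        min_samples_split=config.min_samples_split,
        min_samples_leaf=config.min_samples_leaf,
        max_features=config.max_features,
        max_depth=config.max_depth,
        bootstrap=config.bootstrap,
        random_state=config.seed % (2**32),
        n_jobs=1,
    )
    model.fit(X, y)
    return TrainedForest(
        model=model, y_min=float(y.min()), y_max=float(y.max()), config=config
    )


def predict_rf(forest: TrainedForest, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return forest.model.predict(X)


def rf_importance(forest: TrainedForest) -> np.ndarray:
    """Impurity-reduction importance per feature, non-negative, sum = 1.

    (All-zero importances — e.g. a forest of stumps on constant targets —
    are returned uniform so the normalization always holds.)
    """
    if not hasattr(forest.model, "feature_importances_"):
        raise ValueError("forest is not trained")
    imp = np.asarray(forest.model.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        return np.full_like(imp, 1.0 / len(imp))
    return imp / total


def bootstrap_rf_ranking(
    X_train: np.ndarray,
    y_train: np.ndarray,
    taxon_ids: list[str],
    config: ForestConfig | None = None,
    n_boot: int = 50,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ImportanceRanking:
    """Bootstrap the impurity importances over 80% row subsamples (without
    replacement) and rank taxa by descending bootstrap-mean importance."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    config = config or ForestConfig()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(getattr(y_train, "values", y_train), dtype=float)
    n = X.shape[0]
    n_sub = max(config.min_samples_split, int(round(subsample_fraction * n)))
    rng = np.random.default_rng(seed)
    per_boot = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.choice(n, size=n_sub, replace=False)
        cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        per_boot[b] = rf_importance(train_rf(X[idx], y[idx], cfg))
    mean = per_boot.mean(axis=0)
    return ImportanceRanking(
        taxon_ids=list(taxon_ids),
        mean_importance=mean,
        per_bootstrap=per_boot,
        rank=rank_by_magnitude(mean, taxon_ids),
        signed=False,
        method="rf",
    )


def random_search_rf(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_draws: int = 25,
    seed: int = 0,
    validation_fraction: float = 0.2,
    base_config: ForestConfig | None = None,
) -> ForestConfig:
    """Randomized tuning of min_samples_split / min_samples_leaf /
    max_features by validation MSE on an internal split of the training data.
    The default analysis path uses :class:`ForestConfig` defaults; this is
    the optional tuning contract."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    base = base_config or ForestConfig()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(getattr(y_train, "values", y_train), dtype=float)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(validation_fraction * n)))
    va, tr = perm[:n_val], perm[n_val:]
    best_cfg, best_cost = None, np.inf
    for _ in range(n_draws):
        cfg = replace(
            base,
            min_samples_split=int(rng.integers(2, 11)),
            min_samples_leaf=int(rng.integers(1, 6)),
            max_features=float(rng.uniform(0.1, 1.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fitted = train_rf(X[tr], y[tr], cfg)
        cost = float(np.mean((predict_rf(fitted, X[va]) - y[va]) ** 2))
        if cost < best_cost:
            best_cost, best_cfg = cost, cfg
    return best_cfg
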