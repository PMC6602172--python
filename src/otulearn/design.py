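"""In-silico community design along the learned importance gradient.

A trained network's sensitivity vector ``s`` points in the direction (in
standardized feature space) that most increases the predicted function, so
hypothetical communities can be proposed by stepping an observed community
along it: ``x_new = x + alpha * s``. Random-direction baselines — isotropic
Gaussian directions rescaled to the same step norm — show the increase is
not an artefact of merely moving away from the data. Forest predictions are
leaf averages and therefore stay inside the training-target range along any
trajectory; the network can extrapolate beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .nn import NeuralNetParams, predict_nn
from .rf import TrainedForest, predict_rf

__all__ = [
    "PerturbationConfig",
    "select_extremes",
    "default_alpha_grid",
    "gradient_trajectory",
    "random_trajectory",
]


@dataclass
class PerturbationConfig:
    """Perturbation magnitudes and baseline settings.

    ``alphas`` must be sorted ascending and include 0 (the unperturbed
    community) as its first element.
    """

    alphas: np.ndarray
    n_random_baselines: int = 20
    seed: int = 0
    start: str = "max_target"  # or "min_target" or an explicit sample id

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.alphas.ndim != 1 or len(self.alphas) == 0:
            raise ValueError("alphas must be a non-empty 1-D grid")
        if self.alphas[0] != 0:
            raise ValueError("alpha grid must start at 0")
        if np.any(np.diff(self.alphas) < 0) or np.any(self.alphas < 0):
            raise ValueError("alphas must be non-negative and ascending")


def select_extremes(y_train) -> tuple[int, int]:
    """(index of the highest-target sample, index of the lowest).

    Ties resolve to the first occurrence.
    """
    y = np.asarray(getattr(y_train, "values", y_train), dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant target has no extremes")
    return int(np.argmax(y)), int(np.argmin(y))


def default_alpha_grid(
    X_std: np.ndarray, s: np.ndarray, n_points: int = 21
) -> np.ndarray:
    """Linear grid [0, alpha_max] where ``alpha_max * ||s||`` equals twice
    the median inter-sample distance in standardized space."""
    s_norm = float(np.linalg.norm(s))
    if s_norm == 0:
        raise ValueError("zero importance vector")
    X = np.asarray(X_std, dtype=float)
    if X.shape[0] > 400:  # subsample pairs for the median distance
        rng = np.random.default_rng(0)
        X = X[rng.choice(X.shape[0], 400, replace=False)]
    med = float(np.median(pdist(X)))
    return np.linspace(0.0, 2.0 * med / s_norm, n_points)


def _predict_models(models: dict, X: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for name, model in models.items():
        if isinstance(model, NeuralNetParams):
            out[name] = predict_nn(model, X)
        elif isinstance(model, TrainedForest):
            out[name] = predict_rf(model, X)
        else:  # any callable model
            out[name] = np.asarray(model(X))
    return out


def gradient_trajectory(
    x0: np.ndarray,
    s: np.ndarray,
    alphas: np.ndarray,
    models: dict,
) -> pd.DataFrame:
    """Predictions along ``x0 + alpha * s`` for each model.

    ``x0`` and ``s`` live in standardized feature space; ``models`` maps a
    name (e.g. "nn", "rf") to a trained model. Returns a tidy frame with
    columns alpha, model, prediction.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    s = np.asarray(s, dtype=float).ravel()
    if x0.shape != s.shape:
        raise ValueError("x0 and s dimensions differ")
    alphas = np.asarray(alphas, dtype=float)
    X = x0[None, :] + alphas[:, None] * s[None, :]
    preds = _predict_models(models, X)
    rows = []
    for name, p in preds.items():
        for a, v in zip(alphas, p):
            rows.append({"alpha": float(a), "model": name,
                         "prediction": float(v)})
    return pd.DataFrame(rows)


def random_trajectory(
    x0: np.ndarray,
    alphas: np.ndarray,
    models: dict,
    norm_reference: np.ndarray,
    n_baselines: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-direction baselines with norm-matched steps.

    Each direction is drawn from a zero-mean isotropic Gaussian and rescaled
    so that ``||alpha * d|| == ||alpha * s||`` at every alpha, making the
    comparison with the gradient trajectory fair. Returns a tidy frame with
    columns alpha, model, direction, prediction.
    """
    if n_baselines < 1:
        raise ValueError("n_baselines must be >= 1")
    x0 = np.asarray(x0, dtype=float).ravel()
    s = np.asarray(norm_reference, dtype=float).ravel()
    s_norm = float(np.linalg.norm(s))
    if s_norm == 0:
        raise ValueError("zero norm_reference vector")
    alphas = np.asarray(alphas, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for d_id in range(n_baselines):
        d = rng.standard_normal(x0.shape[0])
        d *= s_norm / np.linalg.norm(d)
        X = x0[None, :] + alphas[:, None] * d[None, :]
        preds = _predict_models(models, X)
        for name, p in preds.items():
            for a, v in zip(alphas, p):
                rows.append(
                    {"alpha": float(a), "model": name, "direction": d_id,
                     "prediction": float(v)}
                )
    return pd.DataFrame(rows)
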