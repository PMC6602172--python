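"""Feed-forward neural-network regression with gradient feature importance.

The regressor is a fully connected network with sigmoid hidden units and a
linear output, trained by mini-batch stochastic gradient descent on an
L2-regularized mean-squared-error cost with early stopping on a held-out
validation split. The default architecture is a single hidden layer of 15
nodes.

Feature importance is derived from the gradient of the model output with
respect to the first-layer input weights: for a sample ``x`` the M x J
importance matrix has entries

    F[m, j] = d M(theta, x) / d W1[m, j] = x_m * delta_j,

where ``delta_j`` is the back-propagated sensitivity of the output to the
j-th pre-activation of the first hidden layer. Averaging F uniformly over
hidden nodes and then over training samples gives the signed
:func:`sensitivity` statistic; weighting the same ``delta`` by the input
weights instead gives the input-gradient :func:`saliency`
``mean_k d M / d x_km``, whose sign tracks the direction of association far
more reliably and which is therefore the default statistic for
:func:`bootstrap_importance` (see docs/methods.md for the comparison). A
positive importance means increasing the taxon (in standardized units)
increases the predicted function. Ranking |importance| across bootstrap
resamples of the training data yields a confidence-weighted feature
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ranking import ImportanceRanking, rank_by_magnitude

__all__ = [
    "NNTrainConfig",
    "NeuralNetParams",
    "train_nn",
    "predict_nn",
    "random_search",
    "importance_matrix",
    "importance_vector",
    "sensitivity",
    "saliency",
    "bootstrap_importance",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NNTrainConfig:
    """Hyperparameters for SGD training.

    ``hidden_layers`` lists the width of each hidden layer (default a single
    layer of 15). ``patience_epochs`` is the number of consecutive epochs
    the validation cost may fail to improve before training halts; the
    parameters returned are those of the best-validation epoch.
    """

    hidden_layers: tuple[int, ...] = (15,)
    learning_rate: float = 0.1
    l2_coefficient: float = 1e-4
    batch_size: int = 32
    patience_epochs: int = 10
    validation_fraction: float = 0.2
    max_epochs: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.hidden_layers, int):
            self.hidden_layers = (self.hidden_layers,)
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer widths must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l2_coefficient < 0:
            raise ValueError("l2_coefficient must be non-negative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class NeuralNetParams:
    """Full parameter set theta of the network.

    ``weights[0]`` is the M x J input-weight matrix (theta^In); subsequent
    entries are the deeper layer weights. ``val_costs``/``best_epoch`` record
    the early-stopping trace when produced by :func:`train_nn`.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    val_costs: np.ndarray | None = None
    train_costs: np.ndarray | None = None
    best_epoch: int | None = None

    def __post_init__(self) -> None:
        for i in range(len(self.weights) - 1):
            if self.weights[i].shape[1] != self.weights[i + 1].shape[0]:
                raise ValueError("inconsistent layer dimensions")
        for w, b in zip(self.weights, self.biases):
            if w.shape[1] != b.shape[0]:
                raise ValueError("bias/weight dimension mismatch")
        if self.weights[-1].shape[1] != 1:
            raise ValueError("output layer must have a single unit")

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    @property
    def architecture(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    @property
    def input_weights(self) -> np.ndarray:
        return self.weights[0]

    def copy(self) -> "NeuralNetParams":
        return NeuralNetParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            val_costs=self.val_costs,
            train_costs=self.train_costs,
            best_epoch=self.best_epoch,
        )


def _init_params(
    n_features: int, hidden_layers: tuple[int, ...], rng: np.random.Generator
) -> NeuralNetParams:
    # uniform init scaled by fan-in, symmetric around zero (sigmoid-friendly)
    dims = [n_features, *hidden_layers, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NeuralNetParams(weights=weights, biases=biases)


def _forward(params: NeuralNetParams, X: np.ndarray):
    """Return (prediction vector, pre-activations z, activations h)."""
    zs, hs = [], [np.asarray(X, dtype=float)]
    a = hs[0]
    n_layers = len(params.weights)
    for layer, (W, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ W + b
        zs.append(z)
        a = z if layer == n_layers - 1 else _sigmoid(z)  # linear output
        hs.append(a)
    return hs[-1][:, 0], zs, hs


def predict_nn(params: NeuralNetParams, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; returns one prediction per row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n_features:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {params.n_features}"
        )
    return _forward(params, X)[0]


def _cost_grads(params, X, y, l2):
    """Mean-squared-error + L2 cost and its parameter gradients."""
    pred, zs, hs = _forward(params, X)
    n = len(y)
    resid = pred - y
    cost = float(np.mean(resid**2)) + l2 * sum(
        float(np.sum(W**2)) for W in params.weights
    )
    gW, gb = [], []
    delta = (2.0 / n) * resid[:, None]  # d cost / d output pre-activation
    for layer in range(len(params.weights) - 1, -1, -1):
        gW.append(hs[layer].T @ delta + 2.0 * l2 * params.weights[layer])
        gb.append(delta.sum(axis=0))
        if layer > 0:
            h = hs[layer]  # sigmoid activations feeding this layer
            delta = (delta @ params.weights[layer].T) * h * (1.0 - h)
    return cost, gW[::-1], gb[::-1]


def _validation_split(n, groups, fraction, rng):
    """Indices (train, val); group-aware when replicate groups are known."""
    if groups is not None:
        uniq = list(dict.fromkeys(groups))
        order = rng.permutation(len(uniq))
        target = fraction * n
        val_groups, cum = set(), 0
        sizes = {}
        for g in groups:
            sizes[g] = sizes.get(g, 0) + 1
        for gi in order:
            g = uniq[gi]
            if abs(cum + sizes[g] - target) <= abs(cum - target):
                val_groups.add(g)
                cum += sizes[g]
            else:
                break
        mask = np.array([g in val_groups for g in groups])
        if 0 < mask.sum() < n:
            return np.flatnonzero(~mask), np.flatnonzero(mask)
    perm = rng.permutation(n)
    n_val = max(1, int(round(fraction * n)))
    n_val = min(n_val, n - 1)
    return perm[n_val:], perm[:n_val]


def train_nn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: NNTrainConfig | None = None,
    groups: list[str] | None = None,
) -> NeuralNetParams:
    """Fit the network by mini-batch SGD with early stopping.

    A validation subset (``validation_fraction`` of the rows, replicate-
    group-aware when ``groups`` is given) monitors the mean-squared-error
    cost each epoch; training stops once the validation cost has not
    improved for ``patience_epochs`` consecutive epochs, and the parameters
    from the best-validation epoch are returned with the recorded cost
    traces attached.
    """
    config = config or NNTrainConfig()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(getattr(y_train, "values", y_train), dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D and aligned with y")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target values")
    rng = np.random.default_rng(config.seed)
    tr, va = _validation_split(
        X.shape[0], groups, config.validation_fraction, rng
    )
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    params = _init_params(X.shape[1], config.hidden_layers, rng)
    best = params.copy()
    best_cost = np.inf
    best_epoch = -1
    stall = 0
    val_costs, train_costs = [], []
    n = len(ytr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            cost, gW, gb = _cost_grads(
                params, Xtr[idx], ytr[idx], config.l2_coefficient
            )
            if not np.isfinite(cost) or cost > 1e30:  # numeric blow-up
                raise FloatingPointError(
                    "training cost diverged; try a smaller learning_rate"
                )
            for W, b, dW, db in zip(params.weights, params.biases, gW, gb):
                W -= config.learning_rate * dW
                b -= config.learning_rate * db
        train_costs.append(float(np.mean((_forward(params, Xtr)[0] - ytr) ** 2)))
        vc = float(np.mean((_forward(params, Xva)[0] - yva) ** 2))
        if not np.isfinite(vc):
            raise FloatingPointError(
                "validation cost diverged; try a smaller learning_rate"
            )
        val_costs.append(vc)
        if vc < best_cost:
            best_cost = vc
            best = params.copy()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience_epochs:
                break
    best.val_costs = np.array(val_costs)
    best.train_costs = np.array(train_costs)
    best.best_epoch = best_epoch
    return best


# ---------------------------------------------------------------------------
# Randomized hyperparameter search

DEFAULT_SEARCH_SPACE = {
    "hidden_size": (5, 50),           # integer range, inclusive
    "learning_rate": (1e-4, 1e-1),    # log-uniform
    "l2_coefficient": (1e-6, 1e-1),   # log-uniform
}


def random_search(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_draws: int = 25,
    search_space: dict | None = None,
    seed: int = 0,
    groups: list[str] | None = None,
    base_config: NNTrainConfig | None = None,
) -> NNTrainConfig:
    """Randomized search over hidden size, learning rate and L2 coefficient.

    Each sampled configuration is scored by its best validation MSE on an
    internal split of the *training* data only; the argmin configuration is
    returned. Deterministic for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    space = dict(DEFAULT_SEARCH_SPACE)
    if search_space:
        space.update(search_space)
    for key, (lo, hi) in space.items():
        if not lo <= hi:
            raise ValueError(f"empty search range for {key}")
    rng = np.random.default_rng(seed)
    base = base_config or NNTrainConfig()
    best_cfg, best_cost = None, np.inf
    for draw in range(n_draws):
        cfg = replace(
            base,
            hidden_layers=(
                int(rng.integers(space["hidden_size"][0],
                                 space["hidden_size"][1] + 1)),
            ),
            learning_rate=float(
                np.exp(rng.uniform(*np.log(space["learning_rate"])))
            ),
            l2_coefficient=float(
                np.exp(rng.uniform(*np.log(space["l2_coefficient"])))
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            fitted = train_nn(X_train, y_train, cfg, groups=groups)
        except FloatingPointError:
            continue  # diverged draw: infinitely bad
        cost = float(np.min(fitted.val_costs))
        if cost < best_cost:
            best_cost, best_cfg = cost, cfg
    if best_cfg is None:
        raise FloatingPointError("all sampled configurations diverged")
    return best_cfg


# ---------------------------------------------------------------------------
# Gradient-based feature importance

def importance_matrix(params: NeuralNetParams, x: np.ndarray) -> np.ndarray:
    """M x J gradient of the output w.r.t. the input-weight matrix.

    Computed analytically: F[m, j] = x_m * delta_j with delta the
    back-propagated output sensitivity at the first hidden layer.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != params.n_features:
        raise ValueError("sample dimension does not match model")
    delta = _first_layer_delta(params, x[None, :])[0]
    return np.outer(x, delta)


def _first_layer_delta(params: NeuralNetParams, X: np.ndarray) -> np.ndarray:
    """d output / d z1 for each row of X (shape K x J)."""
    _, zs, hs = _forward(params, X)
    delta = np.ones((X.shape[0], 1))
    for layer in range(len(params.weights) - 1, 0, -1):
        h = hs[layer]
        delta = (delta @ params.weights[layer].T) * h * (1.0 - h)
    return delta


def importance_vector(F: np.ndarray) -> np.ndarray:
    """Marginalize the importance matrix over hidden nodes: f_m = mean_j F[m,j]."""
    F = np.asarray(F, dtype=float)
    return F.mean(axis=1)


def sensitivity(params: NeuralNetParams, X_train: np.ndarray) -> np.ndarray:
    """Signed per-feature sensitivity s: the importance vector averaged over
    training samples. Vectorized over samples."""
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("empty training set")
    if X.shape[1] != params.n_features:
        raise ValueError("sample dimension does not match model")
    delta = _first_layer_delta(params, X)       # K x J
    c = delta.mean(axis=1)                      # mean over hidden nodes
    return (X * c[:, None]).mean(axis=0)


def saliency(params: NeuralNetParams, X_train: np.ndarray) -> np.ndarray:
    """Signed input-gradient importance: the gradient of the model output
    with respect to the *features*, averaged over training samples.

    ``saliency_m = (1/K) sum_k d M(theta, x_k) / d x_km``. Like
    :func:`sensitivity` this is a signed, first-hidden-layer gradient
    statistic, but it weights each hidden node by its input weight
    (``sum_j W1[m, j] * delta_j``) instead of marginalizing uniformly, which
    makes its sign track the direction of association far more reliably. It
    is the default statistic for bootstrap ranking.
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("empty training set")
    if X.shape[1] != params.n_features:
        raise ValueError("sample dimension does not match model")
    delta = _first_layer_delta(params, X)  # K x J
    return (delta @ params.weights[0].T).mean(axis=0)


def bootstrap_importance(
    X_train: np.ndarray,
    y_train: np.ndarray,
    taxon_ids: list[str],
    base_config: NNTrainConfig | None = None,
    n_boot: int = 50,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    groups: list[str] | None = None,
    mode: str = "input_gradient",
) -> ImportanceRanking:
    """Bootstrap the signed gradient importance over resampled training sets.

    Each iteration draws ``subsample_fraction`` of the rows without
    replacement, retrains from a fresh seeded initialization, and evaluates
    the importance statistic over the subsample. Features are ranked by the
    magnitude of the bootstrap-mean importance; the sign (direction of
    association with the target) is retained.

    ``mode`` selects the per-iteration statistic: ``"input_gradient"``
    (default, :func:`saliency`) or ``"weight_gradient"``
    (:func:`sensitivity`, the uniform marginalization over hidden nodes).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if mode not in ("input_gradient", "weight_gradient"):
        raise ValueError(f"unknown importance mode {mode!r}")
    stat = saliency if mode == "input_gradient" else sensitivity
    config = base_config or NNTrainConfig()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(getattr(y_train, "values", y_train), dtype=float)
    n = X.shape[0]
    n_sub = max(2, int(round(subsample_fraction * n)))
    if n_sub < config.batch_size:
        raise ValueError(
            f"subsample of {n_sub} rows is smaller than batch size "
            f"{config.batch_size}"
        )
    rng = np.random.default_rng(seed)
    per_boot = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.choice(n, size=n_sub, replace=False)
        cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        sub_groups = None if groups is None else [groups[i] for i in idx]
        fitted = train_nn(X[idx], y[idx], cfg, groups=sub_groups)
        per_boot[b] = stat(fitted, X[idx])
    mean = per_boot.mean(axis=0)
    return ImportanceRanking(
        taxon_ids=list(taxon_ids),
        mean_importance=mean,
        per_bootstrap=per_boot,
        rank=rank_by_magnitude(mean, taxon_ids),
        signed=True,
        method="nn",
    )
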