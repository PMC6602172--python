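import numpy as np
import pytest

import otulearn as ol
from otulearn.nn import (
    NeuralNetParams,
    NNTrainConfig,
    _first_layer_delta,
    bootstrap_importance,
    importance_matrix,
    importance_vector,
    predict_nn,
    random_search,
    saliency,
    sensitivity,
    train_nn,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _random_params(rng, dims=(5, 3)):
    M, J = dims
    return NeuralNetParams(
        weights=[rng.normal(size=(M, J)), rng.normal(size=(J, 1))],
        biases=[rng.normal(size=J), rng.normal(size=1)],
    )


class TestForwardPass:
    def test_all_zero_weights_predict_output_bias(self):
        params = NeuralNetParams(
            weights=[np.zeros((4, 3)), np.zeros((3, 1))],
            biases=[np.zeros(3), np.array([2.5])],
        )
        pred = predict_nn(params, np.random.default_rng(0).normal(size=(6, 4)))
        np.testing.assert_allclose(pred, 2.5)

    def test_hand_computed_single_unit_network(self):
        # M=1, J=1, W1=1, b1=0, W2=1, b2=0, x=0 -> sigmoid(0) = 0.5
        params = NeuralNetParams(
            weights=[np.array([[1.0]]), np.array([[1.0]])],
            biases=[np.array([0.0]), np.array([0.0])],
        )
        assert predict_nn(params, np.array([[0.0]]))[0] == pytest.approx(0.5)

    def test_matches_naive_per_node_loop(self):
        # independently coded matrix-free evaluation, node by node
        rng = np.random.default_rng(42)
        params = _random_params(rng)
        X = rng.normal(size=(7, 5))
        naive = []
        for x in X:
            hidden = []
            for j in range(3):
                z = params.biases[0][j]
                for m in range(5):
                    z += params.weights[0][m, j] * x[m]
                hidden.append(_sigmoid(z))
            out = params.biases[1][0]
            for j in range(3):
                out += params.weights[1][j, 0] * hidden[j]
            naive.append(out)
        np.testing.assert_allclose(predict_nn(params, X), naive, atol=1e-12)

    def test_dimension_mismatch_errors(self):
        params = _random_params(np.random.default_rng(0))
        with pytest.raises(ValueError, match="features"):
            predict_nn(params, np.ones((2, 7)))


class TestTraining:
    def test_learns_noiseless_linear_target(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 5))
        y = 2.0 * X[:, 0]
        params = train_nn(X, y, NNTrainConfig(seed=0))
        resid = predict_nn(params, X) - y
        assert np.mean(resid**2) < 0.05 * np.var(y)

    def test_early_stopping_trace_is_consistent(self, trained_nn):
        # reference early-stopping oracle replayed on the recorded trace
        costs = trained_nn.val_costs
        patience = 10
        best, stall, stop = np.inf, 0, None
        best_epoch = -1
        for e, c in enumerate(costs):
            if c < best:
                best, best_epoch, stall = c, e, 0
            else:
                stall += 1
                if stall >= patience:
                    stop = e
                    break
        assert trained_nn.best_epoch == best_epoch
        assert costs[best_epoch] == costs.min()
        if stop is not None:
            assert len(costs) == stop + 1
        assert best_epoch >= len(costs) - 1 - patience

    def test_reproducible_for_fixed_seed(self, small_split):
        X = small_split["train"].counts
        y = small_split["train_y"].values
        a = train_nn(X, y, NNTrainConfig(seed=42))
        b = train_nn(X, y, NNTrainConfig(seed=42))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_divergent_learning_rate_raises_helpful_error(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 4)) * 10
        y = rng.standard_normal(50) * 100
        with pytest.raises(FloatingPointError, match="learning_rate"):
            train_nn(X, y, NNTrainConfig(seed=0, learning_rate=50.0))

    def test_l2_regularization_shrinks_weight_norm(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((150, 6))
        y = X @ rng.normal(size=6)
        norms = []
        for l2 in [1e-5, 1e-2, 1e0]:
            p = train_nn(X, y, NNTrainConfig(seed=7, l2_coefficient=l2))
            norms.append(sum(np.sum(w**2) for w in p.weights))
        assert norms[0] > norms[1] > norms[2]


class TestRandomSearch:
    def test_single_draw_returns_that_config(self, small_split):
        X = small_split["train"].counts[:, :10]
        y = small_split["train_y"].values
        cfg = random_search(X, y, n_draws=1, seed=0)
        assert isinstance(cfg, NNTrainConfig)

    def test_deterministic_for_fixed_seed(self, small_split):
        X = small_split["train"].counts[:, :10]
        y = small_split["train_y"].values
        a = random_search(X, y, n_draws=3, seed=5)
        b = random_search(X, y, n_draws=3, seed=5)
        assert a == b

    def test_returns_argmin_over_evaluated_configs(self, small_split):
        # replay the search manually and confirm the returned config attains
        # the minimal validation cost among all draws
        X = small_split["train"].counts[:, :10]
        y = small_split["train_y"].values
        best = random_search(X, y, n_draws=4, seed=9)
        refit = train_nn(X, y, best)
        best_cost = float(np.min(refit.val_costs))
        # every other config sampled under a different seed stream cannot be
        # checked directly; instead re-run and confirm idempotent choice
        again = random_search(X, y, n_draws=4, seed=9)
        assert again == best
        assert np.isfinite(best_cost)

    def test_empty_space_errors(self, small_split):
        X = small_split["train"].counts[:, :5]
        y = small_split["train_y"].values
        with pytest.raises(ValueError):
            random_search(X, y, n_draws=0, seed=0)
        with pytest.raises(ValueError, match="empty"):
            random_search(
                X, y, n_draws=2, seed=0,
                search_space={"hidden_size": (10, 5)},
            )


class TestImportanceMatrix:
    def test_zero_feature_gives_zero_row(self):
        rng = np.random.default_rng(0)
        params = _random_params(rng)
        x = rng.normal(size=5)
        x[2] = 0.0
        F = importance_matrix(params, x)
        np.testing.assert_array_equal(F[2], 0)

    def test_zero_downstream_weights_give_zero_matrix(self):
        params = NeuralNetParams(
            weights=[np.random.default_rng(0).normal(size=(4, 3)),
                     np.zeros((3, 1))],
            biases=[np.zeros(3), np.zeros(1)],
        )
        F = importance_matrix(params, np.ones(4))
        np.testing.assert_array_equal(F, 0)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(7)
        params = _random_params(rng, dims=(5, 3))
        x = rng.normal(size=5)
        F = importance_matrix(params, x)
        h = 1e-6
        for m in range(5):
            for j in range(3):
                hi = params.copy()
                lo = params.copy()
                hi.weights[0][m, j] += h
                lo.weights[0][m, j] -= h
                fd = (
                    predict_nn(hi, x[None, :])[0]
                    - predict_nn(lo, x[None, :])[0]
                ) / (2 * h)
                assert abs(F[m, j] - fd) < 1e-5 * max(1.0, abs(fd))

    def test_two_hidden_layer_gradients_match_finite_differences(self):
        rng = np.random.default_rng(8)
        params = NeuralNetParams(
            weights=[rng.normal(size=(4, 3)), rng.normal(size=(3, 2)),
                     rng.normal(size=(2, 1))],
            biases=[rng.normal(size=3), rng.normal(size=2),
                    rng.normal(size=1)],
        )
        x = rng.normal(size=4)
        F = importance_matrix(params, x)
        h = 1e-6
        for m in range(4):
            for j in range(3):
                hi, lo = params.copy(), params.copy()
                hi.weights[0][m, j] += h
                lo.weights[0][m, j] -= h
                fd = (
                    predict_nn(hi, x[None, :])[0]
                    - predict_nn(lo, x[None, :])[0]
                ) / (2 * h)
                assert abs(F[m, j] - fd) < 1e-5 * max(1.0, abs(fd))


class TestImportanceVector:
    def test_all_ones_matrix(self):
        np.testing.assert_array_equal(importance_vector(np.ones((6, 4))), 1)

    def test_hand_arithmetic(self):
        F = np.array([[1.0, 3.0], [-2.0, 0.0]])
        np.testing.assert_array_equal(importance_vector(F), [2.0, -1.0])

    def test_linearity_in_scaling(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            importance_vector(3.5 * F), 3.5 * importance_vector(F)
        )


class TestSensitivity:
    def test_single_sample_equals_its_importance_vector(self):
        rng = np.random.default_rng(1)
        params = _random_params(rng)
        x = rng.normal(size=5)
        np.testing.assert_allclose(
            sensitivity(params, x[None, :]),
            importance_vector(importance_matrix(params, x)),
        )

    def test_zero_feature_column_gives_zero_sensitivity(self):
        rng = np.random.default_rng(2)
        params = _random_params(rng)
        X = rng.normal(size=(10, 5))
        X[:, 3] = 0.0
        assert sensitivity(params, X)[3] == 0.0

    def test_equals_mean_of_per_sample_loop(self):
        rng = np.random.default_rng(3)
        params = _random_params(rng)
        X = rng.normal(size=(8, 5))
        loop = np.mean(
            [importance_vector(importance_matrix(params, x)) for x in X],
            axis=0,
        )
        np.testing.assert_allclose(sensitivity(params, X), loop, atol=1e-12)

    def test_empty_training_set_errors(self):
        params = _random_params(np.random.default_rng(0))
        with pytest.raises(ValueError):
            sensitivity(params, np.empty((0, 5)))


class TestSaliency:
    def test_matches_finite_differences_on_inputs(self):
        rng = np.random.default_rng(4)
        params = _random_params(rng)
        X = rng.normal(size=(6, 5))
        sal = saliency(params, X)
        h = 1e-6
        fd = np.zeros(5)
        for m in range(5):
            Xp, Xm = X.copy(), X.copy()
            Xp[:, m] += h
            Xm[:, m] -= h
            fd[m] = np.mean(
                (predict_nn(params, Xp) - predict_nn(params, Xm)) / (2 * h)
            )
        np.testing.assert_allclose(sal, fd, rtol=1e-5, atol=1e-8)


class TestBootstrapImportance:
    def test_shapes_and_rank_permutation(self, small_split):
        X = small_split["train"].counts
        y = small_split["train_y"].values
        ranking = bootstrap_importance(
            X, y, small_split["train"].taxon_ids,
            base_config=NNTrainConfig(seed=0), n_boot=5, seed=1,
        )
        assert ranking.per_bootstrap.shape == (5, X.shape[1])
        assert sorted(ranking.rank) == list(range(1, X.shape[1] + 1))

    def test_planted_strong_taxon_recovered_with_positive_sign(self):
        # one strongly positive planted taxon must land in the top 5% of
        # |mean importance| with a positive sign in nearly every iteration
        spec = ol.SyntheticSpec(
            n_groups=60, n_taxa=40, n_signal_taxa=1, effect_sizes=[3.0],
            noise_sd=0.1, seed=21,
        )
        table, target, truth = ol.generate(spec)
        (scaled,), _ = ol.standardize(table)
        ranking = bootstrap_importance(
            scaled.counts, target.values, scaled.taxon_ids,
            n_boot=50, seed=2, groups=scaled.group_ids,
        )
        j = scaled.taxon_ids.index(truth.taxon_ids[0])
        k_top = max(1, int(0.05 * len(scaled.taxon_ids)))
        per = ranking.per_bootstrap
        hits = 0
        for b in range(per.shape[0]):
            order = np.argsort(-np.abs(per[b]))
            if j in order[:k_top] and per[b, j] > 0:
                hits += 1
        assert hits >= 45
        assert ranking.mean_importance[j] > 0
        assert ranking.rank[j] == 1

    def test_subsample_smaller_than_batch_errors(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="batch"):
            bootstrap_importance(
                X, y, [f"t{i}" for i in range(4)],
                base_config=NNTrainConfig(batch_size=64), n_boot=2, seed=0,
            )

    def test_unknown_mode_rejected(self, small_split):
        with pytest.raises(ValueError, match="mode"):
            bootstrap_importance(
                small_split["train"].counts,
                small_split["train_y"].values,
                small_split["train"].taxon_ids,
                n_boot=1, mode="nonsense",
            )
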