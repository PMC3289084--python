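"""Backpropagation network: forward pass, gradients, training, persistence."""

import numpy as np
import pytest

from ppicomplex import (
    MLPModel,
    Subgraph,
    TrainingSet,
    forward,
    load_model,
    make_ensemble_scorer,
    make_scorer,
    predict_score,
    save_model,
    train,
)
from ppicomplex.features import FeatureExtractor
from ppicomplex.mlp import backprop_epoch, example_deltas


def _scaled(model):
    """Identity scaler so raw inputs reach the first layer unchanged."""
    model.scaler_mean = np.zeros(model.layer_sizes[0])
    model.scaler_sd = np.ones(model.layer_sizes[0])
    return model


def finite_difference_grads(model, x, target, eps=1e-6):
    """Centered finite differences of E = 1/2 (T - O)^2 wrt every weight/bias.

    Backprop's Delta w = l * Err_j * O_i equals -l * dE/dw, so the analytic
    deltas must match minus the numeric gradient times the learning rate.
    """

    def loss():
        out = forward(model, x, scaled=True)
        return 0.5 * (target - out) ** 2

    grads_w, grads_b = [], []
    for W in model.weights:
        g = np.zeros_like(W)
        for idx in np.ndindex(W.shape):
            orig = W[idx]
            W[idx] = orig + eps
            up = loss()
            W[idx] = orig - eps
            down = loss()
            W[idx] = orig
            g[idx] = (up - down) / (2 * eps)
        grads_w.append(g)
    for b in model.biases:
        g = np.zeros_like(b)
        for idx in np.ndindex(b.shape):
            orig = b[idx]
            b[idx] = orig + eps
            up = loss()
            b[idx] = orig - eps
            down = loss()
            b[idx] = orig
            g[idx] = (up - down) / (2 * eps)
        grads_b.append(g)
    return grads_w, grads_b


class TestForward:
    def test_zero_parameters_give_half(self):
        m = _scaled(MLPModel(layer_sizes=(4, 3, 2, 1), rng_seed=0))
        for W in m.weights:
            W[:] = 0
        for b in m.biases:
            b[:] = 0
        assert forward(m, np.ones(4)) == 0.5

    def test_output_is_logistic_of_net_input(self):
        # single linear chain 1-1: output = logistic(w*x + b)
        m = _scaled(MLPModel(layer_sizes=(1, 1), rng_seed=1))
        w = m.weights[0][0, 0]
        b = m.biases[0][0]
        x = 0.7
        expected = 1 / (1 + np.exp(-(w * x + b)))
        assert forward(m, np.array([x])) == pytest.approx(expected)

    def test_hand_computed_toy_network(self):
        m = _scaled(MLPModel(layer_sizes=(2, 2, 1), rng_seed=0))
        m.weights[0][:] = [[0.1, -0.2], [0.3, 0.4]]
        m.biases[0][:] = [0.05, -0.05]
        m.weights[1][:] = [[0.5], [-0.6]]
        m.biases[1][:] = [0.02]
        x = np.array([1.0, -1.0])

        def sig(v):
            return 1 / (1 + np.exp(-v))

        h1 = sig(0.1 * 1 + 0.3 * -1 + 0.05)
        h2 = sig(-0.2 * 1 + 0.4 * -1 - 0.05)
        out = sig(0.5 * h1 - 0.6 * h2 + 0.02)
        assert forward(m, x) == pytest.approx(out, rel=1e-12)

    def test_wrong_input_length_rejected(self):
        m = _scaled(MLPModel(rng_seed=0))
        with pytest.raises(ValueError):
            forward(m, np.ones(7))


class TestBackprop:
    @pytest.mark.parametrize("seed", range(10))
    def test_deltas_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        sizes = (
            int(rng.integers(2, 6)),
            int(rng.integers(2, 5)),
            int(rng.integers(1, 4)),
            1,
        )
        m = _scaled(MLPModel(layer_sizes=sizes, learning_rate=1.0, rng_seed=seed))
        x = rng.normal(size=sizes[0])
        target = float(rng.integers(0, 2))
        dWs, dbs, _ = example_deltas(m, x, target)
        gw, gb = finite_difference_grads(m, x, target)
        for dW, g in zip(dWs, gw):
            assert dW == pytest.approx(-g, rel=1e-5, abs=1e-10)
        for db, g in zip(dbs, gb):
            assert db == pytest.approx(-g, rel=1e-5, abs=1e-10)

    def test_perfect_prediction_changes_nothing(self):
        # target exactly equals the output -> Err = 0 -> all deltas 0
        m = _scaled(MLPModel(layer_sizes=(2, 2, 1), rng_seed=3))
        x = np.array([0.5, -0.5])
        out = forward(m, x)
        dWs, dbs, _ = example_deltas(m, x, out)
        assert all(np.all(d == 0) for d in dWs + dbs)

    def test_zero_learning_rate_is_a_no_op(self):
        m = _scaled(MLPModel(layer_sizes=(3, 2, 1), learning_rate=0.0, rng_seed=4))
        before = [W.copy() for W in m.weights]
        data = TrainingSet(np.ones((4, 3)), np.array([0, 1, 0, 1.0]))
        max_dw = backprop_epoch(m, data)
        assert max_dw == 0.0
        assert all(np.array_equal(a, b) for a, b in zip(before, m.weights))

    def test_epoch_equals_sequential_example_updates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 5))
        y = (rng.random(12) < 0.5).astype(float)
        m1 = _scaled(MLPModel(layer_sizes=(5, 4, 1), rng_seed=9))
        m2 = _scaled(MLPModel(layer_sizes=(5, 4, 1), rng_seed=9))
        backprop_epoch(m1, TrainingSet(X, y))
        for i in range(12):
            dWs, dbs, _ = example_deltas(m2, X[i], y[i])
            for layer, (dW, db) in enumerate(zip(dWs, dbs)):
                m2.weights[layer] += dW
                m2.biases[layer] += db
        for a, b in zip(m1.weights, m2.weights):
            assert a == pytest.approx(b, rel=1e-12)


def _embed43(points):
    """Place 2-D patterns in the first two of 43 features, rest zero."""
    X = np.zeros((len(points), 43))
    X[:, :2] = points
    return X


class TestTraining:
    def test_linearly_separable_reaches_full_accuracy(self):
        rng = np.random.default_rng(12)
        n = 40
        pts = np.concatenate([
            rng.normal([2, 2], 0.4, size=(n // 2, 2)),
            rng.normal([-2, -2], 0.4, size=(n // 2, 2)),
        ])
        y = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
        data = TrainingSet(_embed43(pts), y)
        m = train(MLPModel(rng_seed=0), data)
        preds = [forward(m, x) > 0.5 for x in data.features]
        assert np.mean(np.array(preds) == y.astype(bool)) == 1.0

    def test_xor_pattern_is_learnable(self):
        # plain gradient descent on XOR has well-known local minima; the
        # fixture seed is one from which it converges
        pts = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1.0]])
        y = np.array([0.0, 1.0, 1.0, 0.0])
        data = TrainingSet(_embed43(pts), y)
        m = train(MLPModel(rng_seed=1), data)
        preds = np.array([forward(m, x) > 0.5 for x in data.features])
        assert np.array_equal(preds, y.astype(bool))

    def test_same_seed_same_weights(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 43))
        y = (rng.random(10) < 0.5).astype(float)
        m1 = train(MLPModel(rng_seed=77), TrainingSet(X, y), max_epochs=50)
        m2 = train(MLPModel(rng_seed=77), TrainingSet(X, y), max_epochs=50)
        assert all(np.array_equal(a, b) for a, b in zip(m1.weights, m2.weights))
        assert all(np.array_equal(a, b) for a, b in zip(m1.biases, m2.biases))

    def test_mse_non_increasing_at_small_learning_rate(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 6))
        y = (X[:, 0] > 0).astype(float)
        m = _scaled(MLPModel(layer_sizes=(6, 4, 1), learning_rate=0.01, rng_seed=2))
        data = TrainingSet(X, y)

        def mse():
            return np.mean([(forward(m, x, scaled=True) - t) ** 2 for x, t in zip(X, y)])

        losses = [mse()]
        for _ in range(30):
            backprop_epoch(m, data)
            losses.append(mse())
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_single_class_rejected(self):
        data = TrainingSet(np.ones((3, 43)), np.ones(3))
        with pytest.raises(ValueError):
            train(MLPModel(rng_seed=0), data)


class TestPredictAndPersist:
    def _trained_on(self, net, positives, negatives, seed=0):
        ex = FeatureExtractor(net)
        X = np.array([ex.vector(m) for m in positives + negatives])
        y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
        return train(MLPModel(rng_seed=seed), TrainingSet(X, y), max_epochs=500), ex

    def test_untrained_model_refuses_to_predict(self, triangle_net):
        m = MLPModel(rng_seed=0)
        with pytest.raises(ValueError):
            predict_score(m, Subgraph(frozenset("abc"), triangle_net))

    def test_score_in_unit_interval_and_deterministic(self, small_synth):
        net, gt, _ = small_synth
        sets = gt.member_sets()
        model, ex = self._trained_on(net, sets[:3], [frozenset(list(net.nodes)[:5])])
        s = Subgraph(sets[0], net)
        score = predict_score(model, s)
        assert 0.0 < score < 1.0
        assert predict_score(model, s) == score

    def test_serialization_round_trip_bit_exact(self, tmp_path, small_synth):
        net, gt, _ = small_synth
        sets = gt.member_sets()
        model, ex = self._trained_on(net, sets[:3], [frozenset(list(net.nodes)[:5])])
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        scorer_a = make_scorer(model, ex)
        scorer_b = make_scorer(back, ex)
        for m in sets:
            assert scorer_a(m) == scorer_b(m)

    def test_ensemble_min_vote_bounded_by_members(self, small_synth):
        net, gt, _ = small_synth
        sets = gt.member_sets()
        neg = [frozenset(list(net.nodes)[:5])]
        ex = FeatureExtractor(net)
        models = []
        for k in range(3):
            m, _ = self._trained_on(net, sets[:3], neg, seed=k)
            models.append(m)
        single = [make_scorer(m, ex) for m in models]
        ens = make_ensemble_scorer(models, ex, vote="min")
        for target in sets:
            votes = [s(target) for s in single]
            assert ens(target) == pytest.approx(min(votes))
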