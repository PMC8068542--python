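import math

import numpy as np
import pytest

from fundustex.lstm import (LstmCellParams, LstmRegressor, LstmState,
                            build_sequences, cell_step, count_parameters,
                            train)


def zero_params(H=2, D=2):
    return LstmCellParams(np.zeros((4 * H, D)), np.zeros((4 * H, H)),
                          np.zeros(4 * H), H, D)


def zero_state(H=2):
    return LstmState(np.zeros(H), np.zeros(H))


def sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


class TestCellStep:
    def test_zero_network_stays_at_rest(self):
        s1 = cell_step(zero_params(), zero_state(), np.zeros(2))
        assert np.allclose(s1.h, 0.0)
        assert np.allclose(s1.c, 0.0)

    def test_scalar_cell_two_step_hand_trace(self):
        """H = D = 1 with hand-picked weights, traced independently."""
        wf, wi, wo, wc = 0.5, -0.3, 0.8, 1.1
        uf, ui, uo, uc = 0.2, 0.4, -0.6, 0.9
        bf, bi, bo, bc = 0.1, -0.2, 0.3, 0.0
        params = LstmCellParams(
            np.array([[wf], [wi], [wo], [wc]]),
            np.array([[uf], [ui], [uo], [uc]]),
            np.array([bf, bi, bo, bc]), 1, 1)
        h = c = 0.0
        for x in (0.7, -0.4):
            f = sigmoid(wf * x + uf * h + bf)
            i = sigmoid(wi * x + ui * h + bi)
            o = sigmoid(wo * x + uo * h + bo)
            cbar = math.tanh(wc * x + uc * h + bc)
            c = c * f + i * cbar
            h = math.tanh(c) * o
        state = zero_state(1)
        for x in (0.7, -0.4):
            state = cell_step(params, state, np.array([x]))
        assert state.c[0] == pytest.approx(c, abs=1e-12)
        assert state.h[0] == pytest.approx(h, abs=1e-12)

    def test_activation_bounds(self, rng):
        H, D = 4, 3
        params = LstmCellParams(rng.normal(size=(4 * H, D)),
                                rng.normal(size=(4 * H, H)),
                                rng.normal(size=4 * H), H, D)
        state = LstmState(rng.uniform(-0.9, 0.9, H), rng.normal(size=H))
        out = cell_step(params, state, rng.normal(size=D))
        assert (np.abs(out.h) < 1.0).all()

    def test_forced_gates_conserve_memory(self):
        """Saturated forget gate and closed input gate carry C unchanged."""
        H = 3
        b = np.zeros(4 * H)
        b[0:H] = 60.0       # forget ~ 1
        b[H:2 * H] = -60.0  # input ~ 0
        params = LstmCellParams(np.zeros((4 * H, 1)), np.zeros((4 * H, H)),
                                b, H, 1)
        c0 = np.array([0.3, -1.2, 2.0])
        out = cell_step(params, LstmState(np.zeros(H), c0), np.array([0.5]))
        assert np.allclose(out.c, c0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cell_step(zero_params(2, 2), zero_state(2), np.zeros(3))


class TestParameterCount:
    def test_reference_architecture(self):
        assert count_parameters(100, 3, 1) == 41701

    def test_minimal_architecture_by_hand(self):
        # 4*1*(1+1+1) + 1*(1+1) = 14
        assert count_parameters(1, 1, 1) == 14

    def test_invalid_sizes(self):
        for args in [(0, 1, 1), (1, 0, 1), (1, 1, 0)]:
            with pytest.raises(ValueError):
                count_parameters(*args)

    @pytest.mark.parametrize("hidden,input_dim", [(100, 3), (5, 7), (1, 1)])
    def test_formula_matches_enumerated_weights(self, hidden, input_dim):
        model = LstmRegressor(hidden=hidden, input_dim=input_dim, seed=0)
        assert model.num_parameters() == count_parameters(hidden, input_dim, 1)


class TestForward:
    def test_batched_forward_matches_cell_step(self, rng):
        """The trainer's vectorized forward equals the reference cell."""
        model = LstmRegressor(hidden=6, input_dim=3, look_back=4, seed=3)
        X = rng.normal(size=(5, 4, 3))
        y, h_T, _ = model._forward(X)
        for b in range(5):
            state = LstmState(np.zeros(6), np.zeros(6))
            for t in range(4):
                state = cell_step(model.cell_params, state, X[b, t])
            assert np.allclose(state.h, h_T[b], atol=1e-12)
            expected = state.h @ model.dense_w + model.dense_b
            assert y[b] == pytest.approx(expected, abs=1e-12)

    def test_predictions_clamped(self):
        model = LstmRegressor(hidden=4, input_dim=3, seed=0)
        model.dense_b = 50.0
        preds = model.predict(np.zeros((3, 3, 3)))
        assert (preds <= 1.0).all() and (preds >= -1.0).all()


class TestSequences:
    def test_training_sample_count(self):
        signals = np.linspace(0, 1, 10)
        X, targets, pos = build_sequences(signals, look_back=3)
        assert X.shape == (7, 3, 3)        # n - look_back samples
        assert list(pos) == list(range(3, 10))
        assert np.allclose(targets, signals[3:])

    def test_prediction_covers_every_position(self):
        X = build_sequences(np.arange(6, dtype=float), 3, for_training=False)
        assert X.shape == (6, 3, 3)

    def test_window_contents_and_zero_padding(self):
        s = np.array([10.0, 20.0, 30.0, 40.0])
        X, targets, pos = build_sequences(s, look_back=3)
        # sample for t=3: steps p=1,2,3 with [s_{p-2}, s_{p-1}, s_p]
        assert np.allclose(X[0], [[0, 10, 20], [10, 20, 30], [20, 30, 40]])
        assert targets[0] == 40.0


class TestTraining:
    def test_constant_target_converges(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(64, 3, 3))
        targets = np.full(64, 0.3)
        model = LstmRegressor(hidden=8, input_dim=3, seed=1)
        trace = train(model, X, targets, epochs=100, seed=1,
                      learning_rate=1e-2, batch_size=16)
        assert trace[-1] < 0.05
        assert model.trained

    def test_seeded_training_is_reproducible(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(32, 3, 3))
        targets = rng.uniform(-1, 1, 32)
        traces = []
        for _ in range(2):
            model = LstmRegressor(hidden=6, input_dim=3, seed=7)
            traces.append(train(model, X, targets, epochs=10, seed=7))
        assert traces[0] == traces[1]

    def test_recovery_of_deterministic_signal_map(self):
        """Held-out RMSE stays below 0.15 when targets are a noiseless
        function of the sequence (the identity on the last step signal)."""
        rng = np.random.default_rng(4)
        signals = rng.uniform(0.0, 1.0, 400)
        X, targets, _ = build_sequences(signals, 3)
        X_train, t_train = X[:300], targets[:300]
        X_test, t_test = X[300:], targets[300:]
        model = LstmRegressor(hidden=16, input_dim=3, seed=2)
        train(model, X_train, t_train, epochs=100, seed=2, learning_rate=1e-2)
        rmse = float(np.sqrt(np.mean((model.predict(X_test) - t_test) ** 2)))
        assert rmse < 0.15

    def test_empty_samples_rejected(self):
        model = LstmRegressor(hidden=4, input_dim=3, seed=0)
        with pytest.raises(ValueError):
            train(model, np.zeros((0, 3, 3)), np.zeros(0))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        model = LstmRegressor(hidden=5, input_dim=3, seed=9)
        X = rng.normal(size=(4, 3, 3))
        targets = rng.uniform(-1, 1, 4)
        train(model, X, targets, epochs=2, seed=9)
        model.benchmark = rng.random(20)
        from fundustex.segments import FeatureScaler
        model.scaler = FeatureScaler(rng.random(20), rng.random(20) + 0.5)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = LstmRegressor.load(path)
        assert loaded.trained
        assert np.array_equal(loaded.benchmark, model.benchmark)
        assert np.array_equal(loaded.scaler.mean, model.scaler.mean)
        assert np.allclose(loaded.predict(X), model.predict(X))
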