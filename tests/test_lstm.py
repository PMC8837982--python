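"""LSTM cell equations, gradients, training and sequence construction."""

from dataclasses import fields

import numpy as np
import pytest

from teagrow import lstm
from teagrow.lstm import (
    LstmModel,
    LSTMParams,
    TrainingError,
    cell_forward,
    forward,
    init_params,
    loss_and_grads,
    make_sequences,
    train,
)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def zero_params(input_size, hidden_size):
    params = init_params(input_size, hidden_size, seed=0)
    for arr in params.arrays():
        arr[...] = 0.0
    return params


class TestCellForward:
    def test_zero_weight_closed_form(self):
        """All-zero weights: gates 0.5, candidate 0, so c = 0.5·c_prev and
        h = 0.5·tanh(0.5·c_prev)."""
        params = zero_params(3, 4)
        c_prev = np.array([0.2, -0.4, 1.0, 0.0])
        h, c, _ = cell_forward(np.ones(3), np.zeros(4), c_prev, params)
        np.testing.assert_allclose(c[0], 0.5 * c_prev, atol=1e-15)
        np.testing.assert_allclose(h[0], 0.5 * np.tanh(0.5 * c_prev), atol=1e-15)

    def test_saturated_input_gate_keeps_cell_at_zero(self):
        """With c_prev = 0 and the input gate driven to 0, the new cell
        state stays at 0 regardless of the candidate value."""
        params = zero_params(2, 3)
        params.bi[...] = -30.0  # σ(-30) ≈ 0
        params.Wz[...] = 1.0
        h, c, _ = cell_forward(np.ones(2), np.zeros(3), np.zeros(3), params)
        np.testing.assert_allclose(c[0], 0.0, atol=1e-12)

    def test_hand_worked_two_unit_cell(self):
        """Forward pass reproduced by an explicit step-by-step evaluation
        of the gate equations with hand-set weights."""
        params = zero_params(1, 2)
        params.Wz[...] = [[0.5, 0.1, -0.2], [0.3, 0.0, 0.4]]
        params.Wi[...] = [[0.2, -0.1, 0.0], [0.1, 0.2, 0.3]]
        params.Wf[...] = [[-0.3, 0.2, 0.1], [0.0, 0.1, -0.1]]
        params.Wo[...] = [[0.4, 0.0, 0.2], [-0.2, 0.3, 0.1]]
        params.bz[...] = [0.1, -0.1]
        params.bi[...] = [0.05, 0.0]
        params.bf[...] = [0.0, 0.2]
        params.bo[...] = [-0.05, 0.1]
        x = np.array([0.7])
        h_prev = np.array([0.3, -0.2])
        c_prev = np.array([0.5, 0.4])
        concat = np.concatenate([x, h_prev])
        z = np.tanh(params.Wz @ concat + params.bz)
        zi = sigmoid(params.Wi @ concat + params.bi)
        zf = sigmoid(params.Wf @ concat + params.bf)
        zo = sigmoid(params.Wo @ concat + params.bo)
        c_expected = zf * c_prev + zi * z
        h_expected = zo * np.tanh(c_expected)
        h, c, _ = cell_forward(x, h_prev, c_prev, params)
        np.testing.assert_allclose(c[0], c_expected, atol=1e-12)
        np.testing.assert_allclose(h[0], h_expected, atol=1e-12)

    def test_gate_ranges(self, rng):
        params = init_params(3, 5, seed=4, scale=1.0)
        x = rng.normal(size=(10, 3))
        _, _, cache = cell_forward(x, rng.normal(size=(10, 5)), rng.normal(size=(10, 5)), params)
        _, z, zi, zf, zo, *_ = cache
        for gate in (zi, zf, zo):
            assert np.all(gate > 0) and np.all(gate < 1)
        assert np.all(z > -1) and np.all(z < 1)


class TestForward:
    def test_length_one_window_base_case(self, rng):
        params = init_params(3, 4, seed=5)
        x = rng.normal(size=(1, 3))
        h, _, _ = cell_forward(x, np.zeros((1, 4)), np.zeros((1, 4)), params)
        expected = float(sigmoid(h @ params.Wy + float(params.by))[0])
        assert forward(x.reshape(1, 1, 3), params)[0] == pytest.approx(expected)

    def test_output_in_unit_interval(self, rng):
        params = init_params(3, 6, seed=6, scale=2.0)
        X = rng.normal(size=(20, 4, 3))
        y = forward(X, params)
        assert np.all(y > 0) and np.all(y < 1)

    def test_constant_input_hidden_state_contracts(self, rng):
        """Repeated constant input drives the hidden state toward a fixed
        point: successive differences shrink."""
        params = init_params(2, 4, seed=7)
        x = np.array([[0.3, -0.1]])
        h = np.zeros((1, 4))
        c = np.zeros((1, 4))
        diffs = []
        prev_h = h
        for _ in range(40):
            h, c, _ = cell_forward(x, h, c, params)
            diffs.append(float(np.linalg.norm(h - prev_h)))
            prev_h = h
        assert diffs[-1] < 1e-6
        assert diffs[-1] < diffs[1]


class TestGradients:
    def test_analytic_matches_central_differences(self, rng):
        """BPTT gradients agree with finite differences on a 2-unit,
        3-step instance to ≤ 1e-5 relative."""
        X = rng.normal(size=(4, 3, 2))
        y = rng.random(4)
        params = init_params(2, 2, seed=1, scale=0.5)
        _, grads = loss_and_grads(params, X, y)
        eps = 1e-6
        worst = 0.0
        for f in fields(params):
            arr = getattr(params, f.name)
            ana = getattr(grads, f.name)
            for idx in (list(np.ndindex(arr.shape)) if arr.ndim else [()]):
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = loss_and_grads(params, X, y)
                arr[idx] = orig - eps
                lm, _ = loss_and_grads(params, X, y)
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(num) + abs(ana[idx]))
                worst = max(worst, abs(num - ana[idx]) / denom)
        assert worst <= 1e-5


class TestTrain:
    def test_noiseless_mapping_learned_below_1e3(self, rng):
        X = rng.random((20, 3, 3))
        target_params = init_params(3, 4, seed=2, scale=0.8)
        y = forward(X, target_params)
        _, history = train(X, y, hidden_size=8, lr=0.02, epochs=800, seed=0)
        assert history[-1] < 1e-3

    def test_same_seed_identical_loss_history(self, rng):
        X = rng.random((10, 2, 3))
        y = rng.random(10)
        _, h1 = train(X, y, hidden_size=4, lr=0.01, epochs=50, seed=9)
        _, h2 = train(X, y, hidden_size=4, lr=0.01, epochs=50, seed=9)
        np.testing.assert_array_equal(h1, h2)

    def test_loss_history_finite(self, rng):
        X = rng.random((10, 2, 3))
        y = rng.random(10)
        _, history = train(X, y, hidden_size=4, lr=0.05, epochs=100, seed=0)
        assert np.all(np.isfinite(history))

    @pytest.mark.parametrize("bad", [{"lr": 0.0}, {"hidden_size": 0}])
    def test_invalid_settings_rejected(self, rng, bad):
        X = rng.random((5, 2, 3))
        y = rng.random(5)
        kwargs = {"hidden_size": 4, "lr": 0.01, "epochs": 5, "seed": 0, **bad}
        with pytest.raises(ValueError):
            train(X, y, **kwargs)


class TestMakeSequences:
    def test_72_epochs_lookback_2_gives_71_windows_split_50_21(self, epoch_table):
        train_set, test_set = make_sequences(epoch_table)
        assert len(train_set) == 50 and len(test_set) == 21
        assert train_set.X.shape == (50, 2, 3)

    def test_lookback_one_windows_are_single_epochs(self, epoch_table):
        train_set, test_set = make_sequences(epoch_table, lookback=1, n_train=50)
        assert train_set.X.shape == (50, 1, 3)
        assert len(train_set) + len(test_set) == 72

    def test_no_test_target_inside_any_training_window(self, epoch_table):
        train_set, test_set = make_sequences(epoch_table)
        last_train_epoch = train_set.target_indices.max()
        assert test_set.target_indices.min() > last_train_epoch

    def test_normalization_fitted_on_training_rows_only(self, epoch_table):
        train_set, _ = make_sequences(epoch_table)
        # training targets exactly span [0, 1]; feature scaling ignores the
        # late-season rows only test windows see
        assert train_set.y.min() == pytest.approx(0.0)
        assert train_set.y.max() == pytest.approx(1.0)
        n_train_rows = 50 + 2 - 1
        raw = epoch_table["st"].to_numpy()[:n_train_rows]
        assert train_set.feature_params[0].vmin == pytest.approx(raw.min())
        assert train_set.feature_params[0].vmax == pytest.approx(raw.max())

    def test_windows_are_chronological_slices(self, epoch_table):
        train_set, _ = make_sequences(epoch_table)
        raw = epoch_table[["st", "smc", "sec"]].to_numpy(float)
        # window 3 covers epochs 3 and 4 after normalization
        from teagrow.preprocess import normalize

        expected = np.column_stack([
            normalize(raw[:51, j])[0][3:5] for j in range(3)
        ])
        np.testing.assert_allclose(train_set.X[3], expected, atol=1e-12)

    def test_oversized_lookback_rejected(self, epoch_table):
        with pytest.raises(ValueError, match="lookback"):
            make_sequences(epoch_table, lookback=72)


class TestModelResults:
    def test_fit_predict_score_round_trip(self, epoch_table):
        train_set, test_set = make_sequences(epoch_table)
        results = LstmModel(train_set, hidden_size=8).fit(lr=0.02, epochs=120, seed=0)
        preds = results.predict(test_set)
        assert preds.shape == (21,)
        report = results.score(test_set)
        assert np.isfinite(report.rmse)
        assert "H=8" in results.summary()

    def test_training_reduces_loss(self, epoch_table):
        train_set, _ = make_sequences(epoch_table)
        results = LstmModel(train_set, hidden_size=8).fit(lr=0.02, epochs=120, seed=0)
        assert results.loss_history[-1] < results.loss_history[0]
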