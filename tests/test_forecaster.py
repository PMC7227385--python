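"""The LSTM machinery: the reference peephole cell against analytic
zero-weight cases and an independently coded textbook LSTM, the production
encoder-decoder model's shapes, parameter count, training behaviour,
determinism and whole-stride forecasting."""

import numpy as np
import pytest

import gaitcast as g
from gaitcast.forecaster import _LSTMLayer, _ACTIVATIONS
from gaitcast.preprocess import NormalizationParams
from gaitcast.windowing import WindowConfig, make_windows


def textbook_lstm_sequence(Wx, Wh, xs, bias=None):
    """Independent loop-based standard (non-peephole) LSTM, gate order
    i, f, g, o; tanh cell activations, sigmoid gates."""
    sigmoid = lambda a: 1.0 / (1.0 + np.exp(-a))
    units = Wh.shape[0]
    b = np.zeros(4 * units) if bias is None else bias
    h = np.zeros(units)
    c = np.zeros(units)
    outs = []
    for x in xs:
        a = x @ Wx + h @ Wh + b
        i = sigmoid(a[:units])
        f = sigmoid(a[units:2 * units])
        gg = np.tanh(a[2 * units:3 * units])
        o = sigmoid(a[3 * units:])
        c = f * c + i * gg
        h = o * np.tanh(c)
        outs.append(h)
    return np.array(outs)


class TestReferenceCell:
    def test_all_zero_weights_zero_state(self):
        # sigmoid(0)=0.5 gates, tanh(0)=0 cell input -> state 0, output 0
        params = g.LSTMCellParams.zeros(2, 3)
        out, state = g.lstm_cell_step(params, np.zeros(2), np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(state, 0.0)
        np.testing.assert_allclose(out, 0.0)

    def test_all_zero_weights_state_halves(self):
        params = g.LSTMCellParams.zeros(2, 3)
        s_prev = np.array([1.0, -2.0, 0.5])
        out, state = g.lstm_cell_step(params, np.zeros(2), np.zeros(3), s_prev)
        np.testing.assert_allclose(state, 0.5 * s_prev)
        np.testing.assert_allclose(out, 0.5 * np.tanh(0.5 * s_prev))

    def test_peephole_free_cell_matches_textbook_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_in = int(rng.integers(1, 4))
            units = int(rng.integers(1, 5))
            params = g.LSTMCellParams.random(rng, n_in, units, peepholes=False)
            xs = rng.standard_normal((int(rng.integers(2, 12)), n_in))
            ours = g.lstm_cell_sequence(params, xs)
            Wx = np.concatenate([params.w_xi, params.w_xf, params.w_xc, params.w_xo], axis=1)
            Wh = np.concatenate([params.w_hi, params.w_hf, params.w_hc, params.w_ho], axis=1)
            theirs = textbook_lstm_sequence(Wx, Wh, xs)
            np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_peepholes_change_the_output(self):
        rng = np.random.default_rng(7)
        with_p = g.LSTMCellParams.random(rng, 2, 3, peepholes=True)
        without = g.LSTMCellParams(
            **{k: (np.zeros_like(v) if k.startswith("w_c") and k != "w_xc" else v.copy())
               for k, v in vars(with_p).items() if k.startswith("w_")}
        )
        xs = rng.standard_normal((8, 2))
        assert not np.allclose(
            g.lstm_cell_sequence(with_p, xs), g.lstm_cell_sequence(without, xs)
        )

    def test_output_gate_peeks_at_current_state(self):
        # only the output-gate peephole nonzero: with prev state 0 and a
        # nonzero input the updated state must influence the output gate
        params = g.LSTMCellParams.zeros(1, 1)
        params.w_xc[:] = 1.0
        params.w_co[:] = 10.0
        x = np.array([2.0])
        out, state = g.lstm_cell_step(params, x, np.zeros(1), np.zeros(1))
        expected_state = 0.5 * np.tanh(2.0)
        np.testing.assert_allclose(state, expected_state)
        gate = 1.0 / (1.0 + np.exp(-10.0 * expected_state))
        np.testing.assert_allclose(out, gate * np.tanh(expected_state))

    def test_dimension_mismatch_raises(self):
        params = g.LSTMCellParams.zeros(2, 3)
        with pytest.raises(g.ParameterError):
            g.lstm_cell_step(params, np.zeros(5), np.zeros(3), np.zeros(3))
        with pytest.raises(g.ParameterError):
            g.lstm_cell_step(params, np.zeros(2), np.zeros(4), np.zeros(3))


class TestProductionLayerAgainstOracle:
    def test_bias_free_tanh_layer_matches_textbook(self):
        rng = np.random.default_rng(3)
        layer = _LSTMLayer(3, 4, "tanh", rng)
        layer.b[:] = 0.0
        xs = rng.standard_normal((1, 10, 3))
        hs, _ = layer.forward(xs)
        theirs = textbook_lstm_sequence(layer.Wx, layer.Wh, xs[0])
        np.testing.assert_allclose(hs[0], theirs, atol=1e-10)

    def test_layer_with_bias_matches_textbook_with_bias(self):
        rng = np.random.default_rng(4)
        layer = _LSTMLayer(2, 3, "tanh", rng)
        xs = rng.standard_normal((1, 6, 2))
        hs, _ = layer.forward(xs)
        theirs = textbook_lstm_sequence(layer.Wx, layer.Wh, xs[0], bias=layer.b)
        np.testing.assert_allclose(hs[0], theirs, atol=1e-10)


class TestModel:
    def test_shape_contract_25_to_5(self):
        model = g.build_model(g.ForecasterConfig(encoder_units=8, decoder_units=8))
        y = model.predict(np.zeros((3, 25, 4)))
        assert y.shape == (3, 5, 4)

    def test_degenerate_horizon_w_out_1(self):
        cfg = g.ForecasterConfig(encoder_units=8, decoder_units=8, w_out=1)
        y = g.build_model(cfg).predict(np.zeros((2, 25, 4)))
        assert y.shape == (2, 1, 4)

    def test_parameter_count_closed_form(self):
        e, d, f = 13, 9, 4
        cfg = g.ForecasterConfig(encoder_units=e, decoder_units=d, w_in=25, w_out=5)
        model = g.build_model(cfg)
        expected = (
            4 * (f * e + e * e + e)       # encoder
            + 4 * (e * d + d * d + d)     # decoder (consumes the encoding)
            + d * f + f                   # per-step dense head
        )
        assert model.parameter_count() == expected

    def test_wrong_input_shape_raises(self):
        model = g.build_model(g.ForecasterConfig(encoder_units=4, decoder_units=4))
        with pytest.raises(g.ParameterError):
            model.predict(np.zeros((2, 10, 4)))

    def test_invalid_config(self):
        with pytest.raises(g.ConfigurationError):
            g.ForecasterConfig(encoder_units=0).validate()
        with pytest.raises(g.ConfigurationError):
            g.ForecasterConfig(activation="gelu").validate()

    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = g.ForecasterConfig(encoder_units=6, decoder_units=5, seed=2)
        model = g.build_model(cfg)
        norm = NormalizationParams(np.zeros(4), np.ones(4))
        model.save(tmp_path / "model", norm=norm)
        back, norm2 = g.EncoderDecoderLSTM.load(tmp_path / "model")
        x = rng.standard_normal((2, 25, 4))
        np.testing.assert_array_equal(model.predict(x), back.predict(x))
        np.testing.assert_allclose(norm2.mean, norm.mean)


def _toy_windows(rng, n_samples=300, w_in=10, w_out=5):
    t = np.arange(n_samples) / 50.0
    x = np.stack([np.sin(2 * np.pi * (1 + 0.2 * j) * t) for j in range(4)], axis=1)
    return make_windows(x, WindowConfig(w_in, w_out))


class TestTraining:
    def test_history_length_equals_epochs(self, rng):
        ds = _toy_windows(rng)
        cfg = g.ForecasterConfig(encoder_units=6, decoder_units=6, w_in=10,
                                 w_out=5, epochs=7, seed=0)
        _, hist = g.train(g.build_model(cfg), ds, cfg)
        assert len(hist) == 7

    def test_zero_windows_raises(self):
        cfg = g.ForecasterConfig(encoder_units=4, decoder_units=4, w_in=10, w_out=5)
        empty = g.WindowedDataset(np.zeros((0, 10, 4)), np.zeros((0, 5, 4)),
                                  np.zeros(0, dtype=int))
        with pytest.raises(g.InsufficientDataError):
            g.train(g.build_model(cfg), empty, cfg)

    def test_seed_determinism(self, rng):
        ds = _toy_windows(rng)
        cfg = g.ForecasterConfig(encoder_units=6, decoder_units=6, w_in=10,
                                 w_out=5, epochs=3, seed=5)
        _, h1 = g.train(g.build_model(cfg), ds, cfg)
        _, h2 = g.train(g.build_model(cfg), ds, cfg)
        assert h1.losses == h2.losses

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_learning_signal_on_noise_free_data(self, rng, seed):
        ds = _toy_windows(rng)
        cfg = g.ForecasterConfig(encoder_units=8, decoder_units=8, w_in=10,
                                 w_out=5, epochs=10, seed=seed)
        _, hist = g.train(g.build_model(cfg), ds, cfg)
        assert hist.losses[-1] < hist.losses[0]

    def test_memorises_a_tiny_window_set(self, rng):
        ds = _toy_windows(rng, n_samples=60)   # 10 windows exactly
        assert ds.n_windows == 10
        cfg = g.ForecasterConfig(encoder_units=16, decoder_units=16, w_in=10,
                                 w_out=5, epochs=500, seed=1)
        _, hist = g.train(g.build_model(cfg), ds, cfg)
        assert hist.losses[-1] < 0.05

    def test_mismatched_window_shape_raises(self, rng):
        ds = _toy_windows(rng, w_in=12)
        cfg = g.ForecasterConfig(encoder_units=4, decoder_units=4, w_in=10, w_out=5)
        with pytest.raises(g.ParameterError):
            g.train(g.build_model(cfg), ds, cfg)

    def test_divergence_raises_with_epoch(self, rng):
        ds = _toy_windows(rng)
        cfg = g.ForecasterConfig(encoder_units=6, decoder_units=6, w_in=10,
                                 w_out=5, epochs=5, seed=0, learning_rate=1e9)
        model = g.build_model(cfg)
        model.Wd += 1e300   # push the forward pass into overflow
        with pytest.raises(g.TrainingDivergedError):
            g.train(model, ds, cfg)


class _OracleModel:
    """Harness self-test double: 'predicts' the true future of the series it
    was built from."""

    def __init__(self, z, w_in, w_out):
        self.z, self.w_in, self.w_out = z, w_in, w_out

    def predict(self, x):
        n = x.shape[0]
        return np.stack(
            [self.z[self.w_in + i * self.w_out: self.w_in + (i + 1) * self.w_out]
             for i in range(n)]
        )


class TestForecastStride:
    def _series(self, rng, n):
        return g.KinematicSeries(rng.standard_normal((n, 4)), 100.0,
                                 np.array([0]), "S")

    def test_identity_oracle_reproduces_the_stride(self, rng):
        series = self._series(rng, 195)
        params = g.zscore_fit(series)
        z = np.asarray(g.zscore_apply(series.values, params))
        mock = _OracleModel(z, 25, 5)
        pred = g.forecast_stride(mock, series, params)
        np.testing.assert_allclose(pred, series.values[25:195], rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("w_out,n_windows", [(5, 34), (10, 17)])
    def test_170_sample_stride_window_counts(self, rng, w_out, n_windows):
        series = self._series(rng, 195)
        params = g.zscore_fit(series)
        z = np.asarray(g.zscore_apply(series.values, params))
        pred = g.forecast_stride(_OracleModel(z, 25, w_out), series, params)
        assert pred.shape == (n_windows * w_out, 4) == (170, 4)

    def test_too_short_series_raises(self, rng):
        series = self._series(rng, 28)
        params = g.zscore_fit(series)
        cfg = g.ForecasterConfig(encoder_units=4, decoder_units=4)
        with pytest.raises(g.InsufficientDataError):
            g.forecast_stride(g.build_model(cfg), series, params)

    def test_recursive_mode_runs_and_differs(self, rng):
        series = self._series(rng, 60)
        params = g.zscore_fit(series)
        cfg = g.ForecasterConfig(encoder_units=6, decoder_units=6, w_in=10, w_out=5, seed=0)
        model = g.build_model(cfg)
        sliding = g.forecast_stride(model, series, params)
        recursive = g.forecast_stride(model, series, params, recursive=True)
        assert sliding.shape == recursive.shape
        # first window primes identically in both modes
        np.testing.assert_allclose(sliding[:5], recursive[:5])
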