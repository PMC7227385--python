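"""Encoder-decoder LSTM forecaster, implemented in NumPy.

The model compresses an input window (W_in x 4 kinematic channels) into the
encoder's final hidden state, repeats that fixed-length encoding W_out times,
decodes it with a second LSTM returning a full sequence, and maps each
decoder step through a shared linear layer back to the 4 channels.  Training
minimises mean absolute error with Adam, in batches of windows; gradients are
computed by exact backpropagation through time.

Two LSTM cells live here:

* the production cell — the standard gated cell of mainstream deep-learning
  frameworks (no peepholes, with biases, forget-gate bias initialised to 1),
  used inside the trainable model; its cell activation is configurable and
  defaults to the rectified linear unit, sigmoid gates throughout;
* a from-scratch reference cell WITH peephole connections and no biases
  (:func:`lstm_cell_step`), kept as a verification oracle: with its peephole
  weights zeroed and tanh activations it must reproduce a bias-free standard
  cell step for step.

Everything is deterministic given the config seed: weight initialisation and
epoch shuffling draw from seed streams derived from it, and single-threaded
NumPy arithmetic is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    ParameterError,
    TrainingDivergedError,
)
from .preprocess import NormalizationParams, zscore_apply, zscore_invert
from .synth import KinematicSeries, N_FEATURES
from .windowing import WindowedDataset

# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    e = np.exp(a[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


#: name -> (activation, derivative as a function of the pre-activation)
_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - np.tanh(a) ** 2),
    "relu": (_relu, lambda a: (a > 0.0).astype(np.float64)),
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForecasterConfig:
    """Architecture and training hyperparameters.

    Layer widths were tuned by sparse grid search in the study this package
    follows but the winning values were not reported; 100/100 single-layer
    encoder/decoder is a comparable-capacity default and both are plain
    config fields.  Adam hyperparameters are the framework-standard defaults.
    """

    encoder_units: int = 100
    decoder_units: int = 100
    n_features: int = N_FEATURES
    w_in: int = 25
    w_out: int = 5
    epochs: int = 50
    batch_windows: int = 100
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    seed: int = 0
    activation: str = "relu"
    grad_clip: float | None = None          # global-norm clip; None disables

    def validate(self) -> None:
        for name in ("encoder_units", "decoder_units", "n_features", "w_in",
                     "w_out", "epochs", "batch_windows"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.learning_rate > 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(
                f"activation must be one of {sorted(_ACTIVATIONS)}, got {self.activation!r}"
            )


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss (MAE, normalized scale)."""

    losses: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.losses)


# ---------------------------------------------------------------------------
# production LSTM layer (standard cell, batched over windows)
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _LSTMLayer:
    """Standard LSTM over a batch of sequences; gate order i, f, g, o."""

    def __init__(self, n_in: int, units: int, activation: str, rng: np.random.Generator):
        self.n_in, self.units = n_in, units
        self.act, self.act_deriv = _ACTIVATIONS[activation]
        self.Wx = _glorot(rng, n_in, 4 * units)
        self.Wh = _glorot(rng, units, 4 * units)
        self.b = np.zeros(4 * units)
        self.b[units:2 * units] = 1.0        # forget-gate bias

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """x: (B, T, n_in) -> hidden sequence (B, T, units) plus cache."""
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        hs = np.zeros((B, T, U))
        cache = {"x": x, "i": [], "f": [], "g": [], "o": [],
                 "c": [], "c_prev": [], "h_prev": [], "ag": [], "ac_out": []}
        for t in range(T):
            a = x[:, t] @ self.Wx + h @ self.Wh + self.b
            ai, af, ag, ao = np.split(a, 4, axis=1)
            i, f, o = _sigmoid(ai), _sigmoid(af), _sigmoid(ao)
            g = self.act(ag)
            cache["h_prev"].append(h)
            cache["c_prev"].append(c)
            c = f * c + i * g
            hc = self.act(c)
            h = o * hc
            hs[:, t] = h
            for key, val in (("i", i), ("f", f), ("g", g), ("o", o),
                             ("c", c), ("ag", ag), ("ac_out", hc)):
                cache[key].append(val)
        return hs, cache

    def backward(self, dh_seq: np.ndarray, cache: dict) -> tuple[np.ndarray, list[np.ndarray]]:
        """dh_seq: (B, T, units) gradient w.r.t. the hidden sequence.

        Returns (dx, [dWx, dWh, db])."""
        x = cache["x"]
        B, T, _ = x.shape
        U = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            c, c_prev, h_prev = cache["c"][t], cache["c_prev"][t], cache["h_prev"][t]
            hc, ag = cache["ac_out"][t], cache["ag"][t]
            dh = dh_seq[:, t] + dh_next
            do = dh * hc
            dc = dh * o * self.act_deriv(c) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * self.act_deriv(ag),
                 do * o * (1 - o)], axis=1)
            dWx += x[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        return dx, [dWx, dWh, db]


class EncoderDecoderLSTM:
    """The trainable sequence-to-sequence forecaster (see module docstring)."""

    def __init__(self, config: ForecasterConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
        )
        self.encoder = _LSTMLayer(config.n_features, config.encoder_units,
                                  config.activation, rng)
        self.decoder = _LSTMLayer(config.encoder_units, config.decoder_units,
                                  config.activation, rng)
        self.Wd = _glorot(rng, config.decoder_units, config.n_features)
        self.bd = np.zeros(config.n_features)

    # -- bookkeeping --------------------------------------------------------

    @property
    def w_in(self) -> int:
        return self.config.w_in

    @property
    def w_out(self) -> int:
        return self.config.w_out

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.encoder.params, *self.decoder.params, self.Wd, self.bd]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != self.w_in or x.shape[2] != self.config.n_features:
            raise ParameterError(
                f"expected input of shape (batch, {self.w_in}, {self.config.n_features}), "
                f"got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        x = self._check_input(x)
        enc_seq, enc_cache = self.encoder.forward(x)
        encoding = enc_seq[:, -1]                                # fixed-length vector
        repeated = np.repeat(encoding[:, None, :], self.w_out, axis=1)
        dec_seq, dec_cache = self.decoder.forward(repeated)
        y = dec_seq @ self.Wd + self.bd
        return y, {"enc": enc_cache, "dec": dec_cache, "dec_seq": dec_seq,
                   "enc_T": x.shape[1], "B": x.shape[0]}

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Map (batch, W_in, n_features) -> (batch, W_out, n_features)."""
        y, _ = self.forward(x)
        return y

    def backward(self, dy: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Gradient of the scalar loss w.r.t. every parameter, given dL/dy."""
        dec_seq = cache["dec_seq"]
        B, T_out, U = dec_seq.shape
        dWd = dec_seq.reshape(-1, U).T @ dy.reshape(-1, self.config.n_features)
        dbd = dy.sum(axis=(0, 1))
        d_dec_seq = dy @ self.Wd.T
        d_repeated, dec_grads = self.decoder.backward(d_dec_seq, cache["dec"])
        d_encoding = d_repeated.sum(axis=1)
        dh_enc = np.zeros((B, cache["enc_T"], self.config.encoder_units))
        dh_enc[:, -1] = d_encoding
        _, enc_grads = self.encoder.backward(dh_enc, cache["enc"])
        return [*enc_grads, *dec_grads, dWd, dbd]

    # -- persistence --------------------------------------------------------

    _PARAM_NAMES = ("enc_Wx", "enc_Wh", "enc_b", "dec_Wx", "dec_Wh", "dec_b",
                    "out_W", "out_b")

    def save(self, path: str | Path, norm: NormalizationParams | None = None) -> None:
        """Checkpoint to ``<path>.npz`` with a YAML sidecar ``<path>.yaml``
        carrying the config (and normalisation parameters if given)."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"),
                            **dict(zip(self._PARAM_NAMES, self.params)))
        sidecar: dict = {"forecaster": asdict(self.config)}
        if norm is not None:
            sidecar["normalization"] = {
                name: {"mean": float(m), "std": float(s)}
                for name, m, s in zip(norm.feature_names, norm.mean, norm.std)
            }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> tuple["EncoderDecoderLSTM", NormalizationParams | None]:
        path = Path(path)
        sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
        cfg = sidecar["forecaster"]
        cfg["grad_clip"] = cfg.get("grad_clip", None)
        model = cls(ForecasterConfig(**cfg))
        with np.load(path.with_suffix(".npz")) as f:
            loaded = [f[name] for name in cls._PARAM_NAMES]
        for dst, src in zip(model.params, loaded):
            dst[...] = src
        norm = None
        if "normalization" in sidecar:
            doc = sidecar["normalization"]
            names = tuple(doc)
            norm = NormalizationParams(
                np.array([doc[n]["mean"] for n in names]),
                np.array([doc[n]["std"] for n in names]),
                names,
            )
        return model, norm


def build_model(config: ForecasterConfig) -> EncoderDecoderLSTM:
    """Construct the encoder-decoder forecaster with seeded initial weights."""
    return EncoderDecoderLSTM(config)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], config: ForecasterConfig):
        self.lr, self.b1, self.b2, self.eps = (
            config.learning_rate, config.beta1, config.beta2, config.epsilon)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def train(
    model: EncoderDecoderLSTM,
    train_windows: WindowedDataset,
    config: ForecasterConfig | None = None,
) -> tuple[EncoderDecoderLSTM, TrainingHistory]:
    """Train in place for ``config.epochs`` epochs of ``batch_windows``-sized
    batches under MAE loss with Adam; returns the model and its loss history.

    Window order is reshuffled every epoch from a stream derived from the
    config seed, so two runs with the same seed are identical.
    """
    config = config or model.config
    n = train_windows.n_windows
    if n == 0:
        raise InsufficientDataError("cannot train on 0 windows")
    if (train_windows.input_size != model.w_in
            or train_windows.output_size != model.w_out):
        raise ParameterError(
            f"windowed dataset is ({train_windows.input_size} -> "
            f"{train_windows.output_size}) but model is ({model.w_in} -> {model.w_out})"
        )
    x = np.asarray(train_windows.inputs, dtype=np.float64)
    t = np.asarray(train_windows.targets, dtype=np.float64)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    optimizer = _Adam(model.params, config)
    history = TrainingHistory()
    # divergence surfaces as TrainingDivergedError, not as overflow warnings
    with np.errstate(over="ignore", invalid="ignore"):
        return _train_loop(model, config, x, t, n, rng, optimizer, history)


def _train_loop(model, config, x, t, n, rng, optimizer, history):
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        loss_sum = 0.0
        for start in range(0, n, config.batch_windows):
            idx = perm[start:start + config.batch_windows]
            xb, tb = x[idx], t[idx]
            y, cache = model.forward(xb)
            err = y - tb
            loss = float(np.abs(err).mean())
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            loss_sum += loss * idx.size
            dy = np.sign(err) / err.size
            grads = model.backward(dy, cache)
            if config.grad_clip is not None:
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if norm > config.grad_clip:
                    grads = [g * (config.grad_clip / norm) for g in grads]
            optimizer.step(model.params, grads)
        history.losses.append(loss_sum / n)
    return model, history


# ---------------------------------------------------------------------------
# whole-stride forecasting
# ---------------------------------------------------------------------------

def forecast_stride(
    model,
    series: KinematicSeries,
    params: NormalizationParams,
    recursive: bool = False,
) -> np.ndarray:
    """Forecast everything after the first W_in (priming) samples of ``series``.

    ``series`` must start with the W_in measured priming samples followed by
    the stride to predict, all in original units.  By default each input
    window contains MEASURED samples (the windows slide over ground truth, as
    when forecasting over a recorded stride); with ``recursive=True`` the
    model's own predictions are fed back instead.  Returns the stitched,
    de-normalised forecast, aligned with ``series.values[w_in:]`` and
    truncated to a whole number of output windows.
    """
    w_in, w_out = model.w_in, model.w_out
    z = np.asarray(zscore_apply(series.values, params))
    n_windows = (z.shape[0] - w_in) // w_out
    if n_windows < 1:
        raise InsufficientDataError(
            f"series has {z.shape[0]} samples; need at least W_in + W_out = {w_in + w_out}"
        )
    if not recursive:
        offsets = np.arange(n_windows) * w_out
        inputs = z[offsets[:, None] + np.arange(w_in)]
        pred = model.predict(inputs)                 # (n_windows, w_out, F)
    else:
        buf = z[:w_in].copy()
        chunks = []
        for _ in range(n_windows):
            step = model.predict(buf[None, -w_in:])[0]
            chunks.append(step)
            buf = np.concatenate([buf, step], axis=0)
        pred = np.stack(chunks)
    stitched = pred.reshape(n_windows * w_out, -1)
    return np.asarray(zscore_invert(stitched, params))


# ---------------------------------------------------------------------------
# reference peephole LSTM cell (verification oracle)
# ---------------------------------------------------------------------------

@dataclass
class LSTMCellParams:
    """All weights of the bias-free peephole LSTM cell.

    Input weights ``w_x*`` are (n_in, units); recurrent weights ``w_h*`` are
    (units, units); peephole weights ``w_c*`` are (units,) — diagonal links
    from the memory state into the input, forget and output gates.  The gate
    activation ``f`` is the logistic sigmoid; the cell input/output
    activations ``g``/``h`` default to tanh.
    """

    w_xi: np.ndarray
    w_xf: np.ndarray
    w_xc: np.ndarray
    w_xo: np.ndarray
    w_hi: np.ndarray
    w_hf: np.ndarray
    w_hc: np.ndarray
    w_ho: np.ndarray
    w_ci: np.ndarray
    w_cf: np.ndarray
    w_co: np.ndarray
    g: str = "tanh"
    h: str = "tanh"

    def __post_init__(self) -> None:
        n_in, units = np.shape(self.w_xi)
        for name in ("w_xi", "w_xf", "w_xc", "w_xo"):
            if np.shape(getattr(self, name)) != (n_in, units):
                raise ParameterError(f"{name} must have shape ({n_in}, {units})")
        for name in ("w_hi", "w_hf", "w_hc", "w_ho"):
            if np.shape(getattr(self, name)) != (units, units):
                raise ParameterError(f"{name} must have shape ({units}, {units})")
        for name in ("w_ci", "w_cf", "w_co"):
            if np.shape(getattr(self, name)) != (units,):
                raise ParameterError(f"{name} must have shape ({units},)")

    @property
    def n_in(self) -> int:
        return np.shape(self.w_xi)[0]

    @property
    def units(self) -> int:
        return np.shape(self.w_xi)[1]

    @classmethod
    def zeros(cls, n_in: int, units: int, **kw) -> "LSTMCellParams":
        z = np.zeros
        return cls(z((n_in, units)), z((n_in, units)), z((n_in, units)), z((n_in, units)),
                   z((units, units)), z((units, units)), z((units, units)), z((units, units)),
                   z(units), z(units), z(units), **kw)

    @classmethod
    def random(cls, rng: np.random.Generator, n_in: int, units: int,
               scale: float = 0.5, peepholes: bool = True, **kw) -> "LSTMCellParams":
        def w(*shape):
            return rng.uniform(-scale, scale, size=shape)
        p = cls(w(n_in, units), w(n_in, units), w(n_in, units), w(n_in, units),
                w(units, units), w(units, units), w(units, units), w(units, units),
                w(units), w(units), w(units), **kw)
        if not peepholes:
            p.w_ci[:] = 0.0
            p.w_cf[:] = 0.0
            p.w_co[:] = 0.0
        return p


def lstm_cell_step(
    params: LSTMCellParams,
    x_t: np.ndarray,
    prev_output: np.ndarray,
    prev_state: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the peephole cell; returns (cell output b_c, state s).

    Input and forget gates peek at the PREVIOUS state; the output gate peeks
    at the state already updated this step.  No bias terms.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    prev_output = np.asarray(prev_output, dtype=np.float64)
    prev_state = np.asarray(prev_state, dtype=np.float64)
    if x_t.shape[-1] != params.n_in:
        raise ParameterError(f"x_t last dimension must be {params.n_in}, got {x_t.shape}")
    if prev_output.shape[-1] != params.units or prev_state.shape[-1] != params.units:
        raise ParameterError(f"prev_output/prev_state last dimension must be {params.units}")
    g_act = _ACTIVATIONS[params.g][0]
    h_act = _ACTIVATIONS[params.h][0]
    b_i = _sigmoid(x_t @ params.w_xi + prev_output @ params.w_hi + prev_state * params.w_ci)
    b_f = _sigmoid(x_t @ params.w_xf + prev_output @ params.w_hf + prev_state * params.w_cf)
    a_c = x_t @ params.w_xc + prev_output @ params.w_hc
    state = b_f * prev_state + b_i * g_act(a_c)
    b_o = _sigmoid(x_t @ params.w_xo + prev_output @ params.w_ho + state * params.w_co)
    output = b_o * h_act(state)
    return output, state


def lstm_cell_sequence(params: LSTMCellParams, xs: np.ndarray) -> np.ndarray:
    """Run the reference cell over a (T, n_in) sequence from zero state;
    returns the (T, units) output sequence."""
    xs = np.asarray(xs, dtype=np.float64)
    h = np.zeros(params.units)
    s = np.zeros(params.units)
    outs = np.zeros((xs.shape[0], params.units))
    for t in range(xs.shape[0]):
        h, s = lstm_cell_step(params, xs[t], h, s)
        outs[t] = h
    return outs
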