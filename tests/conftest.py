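import numpy as np
import pytest

import gaitcast as g

#: noise at 0.5% of each channel's amplitude scale — the "low noise" setting
#: used for learning checks on synthetic data
LOW_NOISE = (0.015, 0.025, 0.75, 1.5)


def low_noise_synth(seed: int, strides: int = 30, n_subjects: int = 6) -> g.SynthConfig:
    return g.SynthConfig(
        n_subjects=n_subjects,
        strides_per_subject=strides,
        noise_sd=LOW_NOISE,
        seed=seed,
    )


def small_forecaster(seed: int, w_in: int = 25, w_out: int = 5,
                     epochs: int = 20, units: int = 32) -> g.ForecasterConfig:
    return g.ForecasterConfig(
        encoder_units=units, decoder_units=units,
        w_in=w_in, w_out=w_out, epochs=epochs, seed=seed,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_series(rng) -> g.KinematicSeries:
    """A short 4-channel series with two annotated strides."""
    values = rng.standard_normal((100, 4))
    return g.KinematicSeries(values, sample_rate=100.0,
                             stride_boundaries=np.array([0, 50]), subject_id="T")
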