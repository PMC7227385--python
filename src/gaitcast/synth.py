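"""Synthetic multi-subject treadmill-gait kinematics.

Generates the four channels used throughout the package — thigh and shank
linear acceleration (LA, m/s^2, progression axis) and thigh and shank angular
velocity (AV, deg/s, sagittal axis) — as quasi-periodic stride-locked
waveforms.  Each channel is a low-order Fourier series over the stride cycle;
subjects differ by multiplicative amplitude factors and additive phase
offsets drawn once per subject, strides differ by duration jitter, and i.i.d.
Gaussian sensor noise is added on top.  The generator is fully deterministic
given (seed, subject index): every subject draws from its own seed stream, so
adding a subject never perturbs the others.

The train/test split is structural leave-one-subject-out: the last subject is
always the held-out one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError

#: Fixed channel order used everywhere in the package.
FEATURES = ("thigh_la", "shank_la", "thigh_av", "shank_av")
#: Short labels conventionally used for the same four channels in reports.
FEATURE_LABELS = ("Y1", "Y2", "X3", "X4")
N_FEATURES = 4

_CSV_COLUMNS = ("time_s", *FEATURES, "stride_start")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic gait generator.

    Defaults reproduce the scale of the study setting this package targets:
    six subjects, 100 Hz sampling, 1.7 s strides (170 samples) and 533
    strides per subject, i.e. 5 x 533 = 2,665 training strides under the
    leave-one-subject-out split.

    Amplitude scales are rough peak magnitudes of treadmill walking at
    ~5 km/h: a few m/s^2 of segment linear acceleration and O(100) deg/s of
    sagittal angular velocity, shank larger than thigh.  ``noise_sd`` defaults
    to 2% of each channel's amplitude scale.
    """

    n_subjects: int = 6
    strides_per_subject: int = 533
    sample_rate: float = 100.0
    stride_duration_mean: float = 1.7
    stride_duration_sd: float = 0.03
    n_harmonics: int = 4
    amplitude_scales: tuple[float, float, float, float] = (3.0, 5.0, 150.0, 300.0)
    subject_variation_sd: float = 0.1
    noise_sd: tuple[float, float, float, float] = (0.06, 0.10, 3.0, 6.0)
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_subjects) < 2:
            raise ConfigurationError("n_subjects must be >= 2 (train + held-out subject)")
        if int(self.strides_per_subject) < 1:
            raise ConfigurationError("strides_per_subject must be >= 1")
        if not self.sample_rate > 0:
            raise ConfigurationError("sample_rate must be > 0")
        if not self.stride_duration_mean > 0:
            raise ConfigurationError("stride_duration_mean must be > 0")
        if self.stride_duration_sd < 0:
            raise ConfigurationError("stride_duration_sd must be >= 0")
        if int(self.n_harmonics) < 1:
            raise ConfigurationError("n_harmonics must be >= 1")
        if len(self.amplitude_scales) != N_FEATURES or any(a <= 0 for a in self.amplitude_scales):
            raise ConfigurationError("amplitude_scales must be 4 positive reals")
        if len(self.noise_sd) != N_FEATURES or any(s < 0 for s in self.noise_sd):
            raise ConfigurationError("noise_sd must be 4 non-negative reals")
        if self.subject_variation_sd < 0:
            raise ConfigurationError("subject_variation_sd must be >= 0")


# ---------------------------------------------------------------------------
# the core container
# ---------------------------------------------------------------------------

@dataclass
class KinematicSeries:
    """An n_samples x 4 kinematic time series with stride annotations.

    ``stride_boundaries`` holds the sample indices of successive heel strikes
    of the same foot, i.e. stride onsets; stride ``j`` spans
    ``[boundaries[j], boundaries[j+1])`` and the last stride ends at
    ``n_samples``.
    """

    values: np.ndarray
    sample_rate: float
    stride_boundaries: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ParameterError(
                f"values must be n_samples x {N_FEATURES}, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values must be finite")
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be > 0")
        b = np.asarray(self.stride_boundaries, dtype=np.int64)
        if b.size:
            if np.any(b < 0) or np.any(b > self.n_samples):
                raise ParameterError("stride_boundaries must lie within [0, n_samples]")
            gaps = np.diff(np.append(b, self.n_samples))
            if np.any(gaps < 2):
                raise ParameterError("consecutive stride boundaries must be >= 2 samples apart")
        self.stride_boundaries = b

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_strides(self) -> int:
        return int(self.stride_boundaries.size)

    def stride_slices(self) -> list[slice]:
        """Half-open [onset, next onset) slice per annotated stride."""
        edges = np.append(self.stride_boundaries, self.n_samples)
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def slice(self, start: int, stop: int) -> "KinematicSeries":
        """Sub-series [start, stop) with boundaries re-indexed."""
        if not 0 <= start < stop <= self.n_samples:
            raise ParameterError(f"invalid slice [{start}, {stop}) of {self.n_samples} samples")
        b = self.stride_boundaries
        b = b[(b >= start) & (b < stop)] - start
        return KinematicSeries(self.values[start:stop].copy(), self.sample_rate, b, self.subject_id)

    # -- serialisation ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: time_s, four channels, and a 0/1 stride_start flag."""
        flag = np.zeros(self.n_samples, dtype=np.int64)
        flag[self.stride_boundaries] = 1
        df = pd.DataFrame(
            {
                "time_s": np.arange(self.n_samples) / self.sample_rate,
                **{name: self.values[:, i] for i, name in enumerate(FEATURES)},
                "stride_start": flag,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, subject_id: str = "") -> "KinematicSeries":
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError(f"CSV missing columns: {missing}")
        t = df["time_s"].to_numpy()
        rate = (len(t) - 1) / (t[-1] - t[0]) if len(t) > 1 else 1.0
        values = df[list(FEATURES)].to_numpy(dtype=np.float64)
        boundaries = np.flatnonzero(df["stride_start"].to_numpy() != 0)
        return cls(values, float(rate), boundaries, subject_id)

    def to_npz(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            values=self.values,
            sample_rate=np.float64(self.sample_rate),
            stride_boundaries=self.stride_boundaries,
            subject_id=np.str_(self.subject_id),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "KinematicSeries":
        with np.load(path) as f:
            return cls(
                f["values"],
                float(f["sample_rate"]),
                f["stride_boundaries"],
                str(f["subject_id"]),
            )


# ---------------------------------------------------------------------------
# waveform machinery
# ---------------------------------------------------------------------------

def _base_waveform(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Population-level Fourier coefficients shared by all subjects.

    Returns (amplitudes, phases), each (4 channels x n_harmonics).  Relative
    harmonic amplitudes fall off as 1/k so the fundamental dominates, as in
    segment kinematics over a stride; they are drawn once from a stream
    keyed only on the config seed, so they are identical across subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    k = np.arange(1, config.n_harmonics + 1, dtype=np.float64)
    rel = rng.uniform(0.5, 1.0, size=(N_FEATURES, config.n_harmonics)) / k
    amps = np.asarray(config.amplitude_scales, dtype=np.float64)[:, None] * rel
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(N_FEATURES, config.n_harmonics))
    return amps, phases


def generate_subject(config: SynthConfig, subject_index: int) -> KinematicSeries:
    """Generate one subject's stride-locked series.

    Per subject: multiplicative amplitude factors ~ N(1, subject_variation_sd)
    and additive phase offsets ~ N(0, pi * subject_variation_sd) radians, per
    channel per harmonic, drawn once; per stride: duration ~ N(mean, sd)
    rounded to whole samples; per sample: additive Gaussian noise.
    """
    config.validate()
    if not 0 <= subject_index < config.n_subjects:
        raise ParameterError(
            f"subject_index {subject_index} outside [0, {config.n_subjects})"
        )
    amps, phases = _base_waveform(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1, subject_index))
    )
    shape = (N_FEATURES, config.n_harmonics)
    amp_factor = np.maximum(
        1.0 + config.subject_variation_sd * rng.standard_normal(shape), 0.05
    )
    phase_offset = np.pi * config.subject_variation_sd * rng.standard_normal(shape)

    durations = config.stride_duration_mean + config.stride_duration_sd * rng.standard_normal(
        config.strides_per_subject
    )
    lengths = np.maximum(np.rint(durations * config.sample_rate).astype(np.int64), 2)

    k = np.arange(1, config.n_harmonics + 1, dtype=np.float64)
    a = amps * amp_factor                      # (4, K)
    phi = phases + phase_offset                # (4, K)
    chunks = []
    for n in lengths:
        cycle = 2.0 * np.pi * np.arange(n)[:, None] / n   # (n, 1)
        # (n, 4): sum over harmonics of a * sin(k * cycle + phi)
        chunks.append(np.einsum("fk,nfk->nf", a, np.sin(cycle[:, :, None] * k + phi)))
    values = np.concatenate(chunks, axis=0)
    noise = rng.standard_normal(values.shape) * np.asarray(config.noise_sd)
    values = values + noise
    boundaries = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return KinematicSeries(values, config.sample_rate, boundaries, subject_id=f"S{subject_index}")


def generate_dataset(
    config: SynthConfig, n_test_strides: int = 1
) -> tuple[list[KinematicSeries], KinematicSeries]:
    """Leave-one-subject-out dataset: subjects 0..n-2 train, subject n-1 tests.

    The test series is truncated to its final ``n_test_strides`` strides plus
    the stride immediately preceding them, which supplies the priming samples
    used to launch forecasting.  The split is structural, never random.
    """
    config.validate()
    if n_test_strides < 1:
        raise ParameterError("n_test_strides must be >= 1")
    if config.strides_per_subject < n_test_strides + 1:
        raise ConfigurationError(
            "strides_per_subject must be >= n_test_strides + 1 to supply a priming stride"
        )
    train = [generate_subject(config, i) for i in range(config.n_subjects - 1)]
    full = generate_subject(config, config.n_subjects - 1)
    start = int(full.stride_boundaries[full.n_strides - n_test_strides - 1])
    test = full.slice(start, full.n_samples)
    return train, test
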