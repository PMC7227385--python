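"""Signal conditioning: zero-phase low-pass filtering, z-score normalisation
with an exact inverse, and numerical differentiation.

The low-pass is a 2nd-order Butterworth run forward and backward
(``scipy.signal.filtfilt``), the biomechanics convention: zero phase lag (so
gait events keep their timing) and a 4th-order magnitude response overall.

Normalisation parameters are fit on the training set only and re-applied to
test data, avoiding train/test leakage; the population (n) standard-deviation
convention is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import yaml
from scipy import signal as _signal

from .errors import DegenerateDataError, ParameterError
from .synth import FEATURES, KinematicSeries

ArrayOrSeries = Union[np.ndarray, KinematicSeries]


def _values(x: ArrayOrSeries) -> np.ndarray:
    v = x.values if isinstance(x, KinematicSeries) else np.asarray(x, dtype=np.float64)
    if v.ndim != 2:
        raise ParameterError(f"expected an n_samples x n_features matrix, got shape {v.shape}")
    return v


def _like(x: ArrayOrSeries, values: np.ndarray) -> ArrayOrSeries:
    if isinstance(x, KinematicSeries):
        return KinematicSeries(values, x.sample_rate, x.stride_boundaries, x.subject_id)
    return values


# ---------------------------------------------------------------------------
# low-pass filter
# ---------------------------------------------------------------------------

def lowpass(series: KinematicSeries, cutoff: float = 15.0, order: int = 2) -> KinematicSeries:
    """Zero-phase low-pass filter each channel; stride boundaries unchanged.

    ``order`` is the per-pass Butterworth order; forward-backward filtering
    doubles it, so the default is 4th-order zero-phase overall.
    """
    nyquist = series.sample_rate / 2.0
    if not 0.0 < cutoff < nyquist:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist) = (0, {nyquist}) Hz, got {cutoff}"
        )
    b, a = _signal.butter(order, cutoff, btype="low", fs=series.sample_rate)
    filtered = _signal.filtfilt(b, a, series.values, axis=0)
    return KinematicSeries(filtered, series.sample_rate, series.stride_boundaries, series.subject_id)


# ---------------------------------------------------------------------------
# z-score normalisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature mean and standard deviation in original units."""

    mean: np.ndarray
    std: np.ndarray
    feature_names: tuple[str, ...] = FEATURES

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=np.float64))
        if self.mean.shape != self.std.shape or self.mean.ndim != 1:
            raise ParameterError("mean and std must be 1-D arrays of equal length")
        if len(self.feature_names) != self.mean.size:
            raise ParameterError("feature_names length must match mean/std")
        if np.any(self.std <= 0):
            raise ParameterError("std must be > 0 for every feature")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            name: {"mean": float(m), "std": float(s)}
            for name, m, s in zip(self.feature_names, self.mean, self.std)
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationParams":
        doc = yaml.safe_load(Path(path).read_text())
        names = tuple(doc)
        return cls(
            np.array([doc[n]["mean"] for n in names]),
            np.array([doc[n]["std"] for n in names]),
            names,
        )


def zscore_fit(data: ArrayOrSeries | Iterable[ArrayOrSeries]) -> NormalizationParams:
    """Fit per-feature mean/std (population convention) over pooled samples."""
    if isinstance(data, (np.ndarray, KinematicSeries)):
        data = [data]
    pooled = np.concatenate([_values(x) for x in data], axis=0)
    if pooled.shape[0] < 2:
        raise ParameterError("need at least 2 pooled samples per feature")
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)          # ddof=0
    for i, s in enumerate(std):
        if s == 0.0:
            name = FEATURES[i] if pooled.shape[1] == len(FEATURES) else f"feature {i}"
            raise DegenerateDataError(f"zero variance in feature '{name}'")
    names = FEATURES if pooled.shape[1] == len(FEATURES) else tuple(
        f"f{i}" for i in range(pooled.shape[1])
    )
    return NormalizationParams(mean, std, names)


def _check_shape(v: np.ndarray, params: NormalizationParams) -> None:
    if v.shape[1] != params.mean.size:
        raise ParameterError(
            f"series has {v.shape[1]} features but params have {params.mean.size}"
        )


def zscore_apply(x: ArrayOrSeries, params: NormalizationParams) -> ArrayOrSeries:
    """(x - mean) / std per feature."""
    v = _values(x)
    _check_shape(v, params)
    return _like(x, (v - params.mean) / params.std)


def zscore_invert(x: ArrayOrSeries, params: NormalizationParams) -> ArrayOrSeries:
    """Exact inverse of :func:`zscore_apply`."""
    v = _values(x)
    _check_shape(v, params)
    return _like(x, v * params.std + params.mean)


# ---------------------------------------------------------------------------
# numerical differentiation
# ---------------------------------------------------------------------------

def differentiate(x: np.ndarray, order: int, dt: float) -> np.ndarray:
    """First or second time derivative of a sampled signal.

    Order 1 uses central differences with one-sided stencils at the ends
    (angular velocity from segment angles); order 2 uses the second central
    difference with end values replicated from the nearest interior point
    (linear acceleration from segment displacement).  Output length equals
    input length.
    """
    x = np.asarray(x, dtype=np.float64)
    if not dt > 0:
        raise ParameterError("dt must be > 0")
    if x.shape[0] < 3:
        raise ParameterError(f"signal must have >= 3 samples, got {x.shape[0]}")
    if order == 1:
        return np.gradient(x, dt, axis=0)
    if order == 2:
        d = np.empty_like(x)
        d[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt**2
        d[0] = d[1]
        d[-1] = d[-2]
        return d
    raise ParameterError(f"order must be 1 or 2, got {order}")
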