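"""Sliding-window transformation of an M x N series into a supervised
sequence-to-sequence dataset.

Each window pairs ``W_in`` input samples with the ``W_out`` samples that
immediately follow them; successive windows advance by a slide equal to
``W_out``, so the target windows tile their covered range without gap or
overlap and can be stitched back into a contiguous trajectory.  Indexing is
0-based and half-open throughout.  Trailing samples that do not fill a
complete input+target pair are dropped, never padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .synth import KinematicSeries


@dataclass(frozen=True)
class WindowConfig:
    """Input/output window sizes in samples; the slide is locked to output_size."""

    input_size: int
    output_size: int
    slide: int | None = None

    def __post_init__(self) -> None:
        if self.input_size < 1:
            raise ConfigurationError("input_size must be >= 1")
        if self.output_size < 1:
            raise ConfigurationError("output_size must be >= 1")
        if self.slide is None:
            object.__setattr__(self, "slide", self.output_size)
        elif self.slide != self.output_size:
            raise ConfigurationError(
                f"slide must equal output_size ({self.output_size}), got {self.slide}"
            )


@dataclass
class WindowedDataset:
    """Aligned 3-D input and target windows plus their source offsets."""

    inputs: np.ndarray        # n_windows x W_in x n_features
    targets: np.ndarray       # n_windows x W_out x n_features
    source_offsets: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.inputs.shape[0]

    @property
    def input_size(self) -> int:
        return self.inputs.shape[1]

    @property
    def output_size(self) -> int:
        return self.targets.shape[1]

    def to_npz(self, path: str | Path) -> None:
        np.savez_compressed(
            path, inputs=self.inputs, targets=self.targets, offsets=self.source_offsets
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "WindowedDataset":
        with np.load(path) as f:
            return cls(f["inputs"], f["targets"], f["offsets"])


def make_windows(
    series: Union[KinematicSeries, np.ndarray], config: WindowConfig
) -> WindowedDataset:
    """Window one series; window i has input [i*s, i*s+W_in) and target
    [i*s+W_in, i*s+W_in+W_out) with s = W_out.

    Apply per series only — windows must never straddle a subject boundary.
    """
    values = series.values if isinstance(series, KinematicSeries) else np.asarray(series)
    if values.ndim != 2:
        raise InsufficientDataError(f"expected a 2-D series, got shape {values.shape}")
    m = values.shape[0]
    w_in, w_out, slide = config.input_size, config.output_size, config.slide
    minimum = w_in + w_out
    if m < minimum:
        raise InsufficientDataError(
            f"series has M={m} samples; windowing needs at least W_in + W_out = {minimum}"
        )
    n_windows = (m - w_in - w_out) // slide + 1
    offsets = np.arange(n_windows, dtype=np.int64) * slide
    inputs = values[offsets[:, None] + np.arange(w_in)]
    targets = values[offsets[:, None] + w_in + np.arange(w_out)]
    return WindowedDataset(inputs.copy(), targets.copy(), offsets)


def stitch_targets(dataset: WindowedDataset) -> np.ndarray:
    """Concatenate target windows in order; because slide = W_out this equals
    the source segment [W_in, W_in + n_windows * W_out) exactly."""
    n, w_out, f = dataset.targets.shape
    return dataset.targets.reshape(n * w_out, f)


def concatenate(datasets: list[WindowedDataset]) -> WindowedDataset:
    """Pool windows from several (per-subject) datasets into one training set."""
    if not datasets:
        raise InsufficientDataError("no windowed datasets to concatenate")
    return WindowedDataset(
        np.concatenate([d.inputs for d in datasets]),
        np.concatenate([d.targets for d in datasets]),
        np.concatenate([d.source_offsets for d in datasets]),
    )
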