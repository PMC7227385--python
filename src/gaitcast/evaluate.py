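"""Forecast evaluation: MAE, MSE and Pearson correlation per kinematic
channel, first-window vs whole-stride reporting, the input-window-size sweep
and the 5- vs 10-sample horizon comparison.

Whole-stride ("all windows combined") metrics are computed over the stitched
trajectory with all predicted samples pooled per channel, not averaged over
per-window scores.  Metrics are reported on the de-normalised (original
units) scale by default.  A constant series makes the correlation undefined;
that raises rather than silently returning 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateDataError, InsufficientDataError, ParameterError
from .forecaster import (
    EncoderDecoderLSTM,
    ForecasterConfig,
    TrainingHistory,
    build_model,
    forecast_stride,
    train,
)
from .preprocess import NormalizationParams, zscore_apply, zscore_fit
from .synth import FEATURE_LABELS, FEATURES, KinematicSeries
from .windowing import WindowConfig, concatenate, make_windows

logger = logging.getLogger(__name__)

ArrayLike = Union[np.ndarray, KinematicSeries]


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def _pair(y: ArrayLike, y_hat: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y.values if isinstance(y, KinematicSeries) else y, dtype=np.float64).ravel()
    b = np.asarray(
        y_hat.values if isinstance(y_hat, KinematicSeries) else y_hat, dtype=np.float64
    ).ravel()
    if a.shape != b.shape:
        raise ParameterError(f"series lengths differ: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ParameterError("empty series")
    return a, b


def mae(y: ArrayLike, y_hat: ArrayLike) -> float:
    """Mean absolute error (1/n) * sum |y_j - y_hat_j|."""
    a, b = _pair(y, y_hat)
    return float(np.mean(np.abs(a - b)))


def mse(y: ArrayLike, y_hat: ArrayLike) -> float:
    """Mean squared error (1/n) * sum (y_j - y_hat_j)^2."""
    a, b = _pair(y, y_hat)
    return float(np.mean((a - b) ** 2))


def cc(y: ArrayLike, y_hat: ArrayLike) -> float:
    """Pearson correlation cov(y, y_hat) / (std(y) * std(y_hat)).

    Population (n) divisor in numerator and denominator, so the convention
    cancels.  Raises :class:`DegenerateDataError` on constant input.
    """
    a, b = _pair(y, y_hat)
    if a.size < 2:
        raise ParameterError("correlation needs n >= 2")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        which = "y" if sa == 0.0 else "y_hat"
        raise DegenerateDataError(f"correlation undefined: {which} is constant")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


# ---------------------------------------------------------------------------
# per-feature reports
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-channel MAE/MSE/CC for one evaluation scope.

    ``scope`` is 'first_window' (the first W_out predicted samples only) or
    'full_stride' (all predicted samples pooled).  Channel order is fixed:
    Y1 thigh LA, Y2 shank LA, X3 thigh AV, X4 shank AV.
    """

    scope: str
    mae: np.ndarray
    mse: np.ndarray
    cc: np.ndarray
    n: int
    feature_names: tuple[str, ...] = FEATURES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(FEATURE_LABELS[: len(self.feature_names)]),
                "feature": list(self.feature_names),
                "scope": self.scope,
                "mae": self.mae,
                "mse": self.mse,
                "cc": self.cc,
                "n": self.n,
            }
        )

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "n": int(self.n),
            "features": {
                name: {"mae": float(m), "mse": float(s), "cc": float(c)}
                for name, m, s, c in zip(self.feature_names, self.mae, self.mse, self.cc)
            },
        }


def evaluate_forecast(
    predicted: ArrayLike,
    actual: ArrayLike,
    scope: str = "full_stride",
    w_out: int | None = None,
) -> MetricsReport:
    """Per-channel metrics for aligned predicted/actual trajectories.

    ``scope='first_window'`` restricts both series to their first ``w_out``
    samples (``w_out`` required); ``scope='full_stride'`` uses everything.
    """
    p = np.asarray(predicted.values if isinstance(predicted, KinematicSeries) else predicted)
    a = np.asarray(actual.values if isinstance(actual, KinematicSeries) else actual)
    if p.shape != a.shape or p.ndim != 2:
        raise ParameterError(f"misaligned series: predicted {p.shape} vs actual {a.shape}")
    if scope == "first_window":
        if w_out is None:
            raise ParameterError("scope='first_window' requires w_out")
        if p.shape[0] < w_out:
            raise ParameterError(f"series shorter ({p.shape[0]}) than w_out ({w_out})")
        p, a = p[:w_out], a[:w_out]
    elif scope != "full_stride":
        raise ParameterError(f"unknown scope {scope!r}")
    n_feat = p.shape[1]
    return MetricsReport(
        scope=scope,
        mae=np.array([mae(a[:, j], p[:, j]) for j in range(n_feat)]),
        mse=np.array([mse(a[:, j], p[:, j]) for j in range(n_feat)]),
        cc=np.array([cc(a[:, j], p[:, j]) for j in range(n_feat)]),
        n=p.shape[0],
        feature_names=FEATURES[:n_feat] if n_feat <= len(FEATURES) else tuple(
            f"f{i}" for i in range(n_feat)),
    )


def abs_error_trace(predicted: ArrayLike, actual: ArrayLike) -> pd.DataFrame:
    """Per-sample absolute error per channel, for error-trace plots."""
    p = np.asarray(predicted.values if isinstance(predicted, KinematicSeries) else predicted)
    a = np.asarray(actual.values if isinstance(actual, KinematicSeries) else actual)
    if p.shape != a.shape:
        raise ParameterError(f"misaligned series: {p.shape} vs {a.shape}")
    df = pd.DataFrame(np.abs(p - a), columns=list(FEATURES[: p.shape[1]]))
    df.insert(0, "sample", np.arange(p.shape[0]))
    return df


def write_report_csv(reports: Sequence[MetricsReport], path: str | Path) -> None:
    pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(path, index=False)


def write_report_yaml(reports: Sequence[MetricsReport], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump([r.to_dict() for r in reports], sort_keys=False))


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

@dataclass
class ForecastRun:
    """Everything produced by one train-and-forecast experiment."""

    model: EncoderDecoderLSTM
    history: TrainingHistory
    norm: NormalizationParams
    predicted: np.ndarray     # de-normalised, aligned with ``actual``
    actual: np.ndarray
    baseline_predicted: np.ndarray | None = None


def _test_segment(test: KinematicSeries, w_in: int) -> tuple[KinematicSeries, int]:
    """The evaluated stride is the LAST annotated stride of the test series;
    the W_in samples before its onset are the priming window."""
    if test.n_strides < 1:
        raise InsufficientDataError("test series has no stride annotations")
    onset = int(test.stride_boundaries[-1])
    if onset < w_in:
        raise InsufficientDataError(
            f"need {w_in} priming samples before the test stride, have {onset}"
        )
    return test.slice(onset - w_in, test.n_samples), onset


def train_and_forecast(
    train_series: Sequence[KinematicSeries],
    test_series: KinematicSeries,
    config: ForecasterConfig,
    with_baseline: bool = False,
) -> ForecastRun:
    """Run the full experiment: fit z-scores on the training subjects, window
    per subject, train, then forecast the test subject's final stride from
    W_in measured priming samples.

    With ``with_baseline=True`` an untrained copy of the model (same seeded
    initial weights) also forecasts the stride, as a floor reference.
    """
    config.validate()
    norm = zscore_fit(list(train_series))
    wcfg = WindowConfig(config.w_in, config.w_out)
    windowed = concatenate(
        [make_windows(np.asarray(zscore_apply(s.values, norm)), wcfg) for s in train_series]
    )
    logger.info("training on %d windows from %d subjects", windowed.n_windows, len(train_series))
    model = build_model(config)
    baseline_pred = None
    if with_baseline:
        segment, _ = _test_segment(test_series, config.w_in)
        baseline_pred = forecast_stride(build_model(config), segment, norm)
    model, history = train(model, windowed, config)
    segment, onset = _test_segment(test_series, config.w_in)
    predicted = forecast_stride(model, segment, norm)
    actual = test_series.values[onset:onset + predicted.shape[0]]
    return ForecastRun(model, history, norm, predicted, actual, baseline_pred)


@dataclass
class SweepResult:
    """Test-set MAE/MSE per channel for each input-window size at a fixed
    output size."""

    sizes: tuple[int, ...]
    mae: np.ndarray           # n_sizes x n_features
    mse: np.ndarray
    output_size: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, size in enumerate(self.sizes):
            for j, name in enumerate(FEATURES):
                rows.append(
                    {
                        "input_window_size": size,
                        "label": FEATURE_LABELS[j],
                        "feature": name,
                        "mae": self.mae[i, j],
                        "mse": self.mse[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def input_window_sweep(
    train_series: Sequence[KinematicSeries],
    test_series: KinematicSeries,
    config: ForecasterConfig,
    sizes: Sequence[int] = (5, 10, 15, 20, 25, 30, 35, 40),
    output_size: int = 5,
) -> SweepResult:
    """Retrain and evaluate one model per input-window size (whole-stride
    scope), with the same config seed for every size so sizes differ only by
    architecture."""
    if not sizes:
        raise ParameterError("sizes must be non-empty")
    sizes = tuple(int(s) for s in sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ParameterError("sizes must be strictly increasing")
    maes, mses = [], []
    for size in sizes:
        cfg = replace(config, w_in=size, w_out=output_size)
        try:
            run = train_and_forecast(train_series, test_series, cfg)
            report = evaluate_forecast(run.predicted, run.actual, "full_stride")
        except Exception as exc:
            raise type(exc)(f"input window size {size}: {exc}") from exc
        maes.append(report.mae)
        mses.append(report.mse)
        logger.info("sweep W_in=%d: mean MAE %.4g", size, float(np.mean(report.mae)))
    return SweepResult(sizes, np.vstack(maes), np.vstack(mses), output_size)


def horizon_comparison(
    train_series: Sequence[KinematicSeries],
    test_series: KinematicSeries,
    config: ForecasterConfig,
    w_in: int = 25,
    horizons: Sequence[int] = (5, 10),
) -> dict[int, dict[str, MetricsReport]]:
    """First-window and whole-stride reports per forecast horizon at a fixed
    input window; returns {horizon: {scope: report}}."""
    if not horizons or any(int(h) < 1 for h in horizons):
        raise ParameterError("horizons must be positive")
    out: dict[int, dict[str, MetricsReport]] = {}
    for h in horizons:
        cfg = replace(config, w_in=w_in, w_out=int(h))
        run = train_and_forecast(train_series, test_series, cfg)
        out[int(h)] = {
            "first_window": evaluate_forecast(run.predicted, run.actual,
                                              "first_window", w_out=int(h)),
            "full_stride": evaluate_forecast(run.predicted, run.actual, "full_stride"),
        }
    return out
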