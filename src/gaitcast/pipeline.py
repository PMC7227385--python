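"""Config-driven end-to-end runs: generate -> preprocess -> window -> train
-> evaluate, writing a self-describing run directory.

A run directory contains the generated data (CSV), fitted normalisation
parameters (YAML), the model checkpoint (NPZ + YAML sidecar), the training
history, metrics for both evaluation scopes, optional sweep/horizon outputs
and a manifest (config, config hash, seed, library versions, stride/window
counts) sufficient to reproduce the run bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError, GaitcastError
from .evaluate import (
    abs_error_trace,
    evaluate_forecast,
    horizon_comparison,
    input_window_sweep,
    train_and_forecast,
    write_report_csv,
    write_report_yaml,
)
from .forecaster import ForecasterConfig
from .synth import KinematicSeries, SynthConfig, generate_dataset
from .windowing import WindowConfig

logger = logging.getLogger(__name__)


@dataclass
class EvalOptions:
    n_test_strides: int = 1
    lowpass_cutoff: float | None = None   # synthetic data are band-limited already
    run_sweep: bool = False
    sweep_sizes: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40)
    run_horizons: bool = False
    horizons: tuple[int, ...] = (5, 10)


@dataclass
class RunConfig:
    """Nested configuration for one full pipeline run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    window: WindowConfig = field(default_factory=lambda: WindowConfig(25, 5))
    forecaster: ForecasterConfig = field(default_factory=ForecasterConfig)
    evaluation: EvalOptions = field(default_factory=EvalOptions)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.window.input_size != self.forecaster.w_in
                or self.window.output_size != self.forecaster.w_out):
            raise ConfigurationError(
                "window (input_size, output_size) must match forecaster (w_in, w_out): "
                f"({self.window.input_size}, {self.window.output_size}) vs "
                f"({self.forecaster.w_in}, {self.forecaster.w_out})"
            )

    def reseeded(self, seed: int) -> "RunConfig":
        """Propagate one global seed into every stage."""
        return RunConfig(
            synth=dataclasses.replace(self.synth, seed=seed),
            window=self.window,
            forecaster=dataclasses.replace(self.forecaster, seed=seed),
            evaluation=self.evaluation,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {
            "synth": dataclasses.asdict(self.synth),
            "window": {"input_size": self.window.input_size,
                       "output_size": self.window.output_size},
            "forecaster": dataclasses.asdict(self.forecaster),
            "evaluation": dataclasses.asdict(self.evaluation),
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=False))

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        def build(klass, section):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(section) - fields
            if unknown:
                raise ConfigurationError(f"unknown {klass.__name__} fields: {sorted(unknown)}")
            section = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            return klass(**section)

        return cls(
            synth=build(SynthConfig, doc.get("synth", {})),
            window=build(WindowConfig, doc.get("window", {"input_size": 25, "output_size": 5})),
            forecaster=build(ForecasterConfig, doc.get("forecaster", {})),
            evaluation=build(EvalOptions, doc.get("evaluation", {})),
            seed=int(doc.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config file {path} is not a YAML mapping")
        return cls.from_dict(doc)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(_listify(config.to_dict()), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


class _Stage:
    """Context manager logging wall time per pipeline stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            logger.info("stage %s: done in %.2f s", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.2f s: %s", self.name, dt, exc)
        return False


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full experiment and write a self-describing run directory.

    Returns the run directory path.  Any stage failure propagates with the
    stage name in the log; partial outputs are left in place for debugging.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    with _Stage("synth"):
        train_series, test_series = generate_dataset(
            config.synth, config.evaluation.n_test_strides
        )
        data_dir = out / "data"
        data_dir.mkdir(exist_ok=True)
        for s in train_series:
            s.to_csv(data_dir / f"train_{s.subject_id}.csv")
        test_series.to_csv(data_dir / "test.csv")
        n_train_strides = sum(s.n_strides for s in train_series)

    if config.evaluation.lowpass_cutoff is not None:
        from .preprocess import lowpass

        with _Stage("preprocess"):
            cut = config.evaluation.lowpass_cutoff
            train_series = [lowpass(s, cut) for s in train_series]
            test_series = lowpass(test_series, cut)

    with _Stage("train+forecast"):
        run = train_and_forecast(train_series, test_series, config.forecaster,
                                 with_baseline=True)
        run.norm.to_yaml(out / "normalization.yaml")
        run.model.save(out / "model", norm=run.norm)
        np.savetxt(out / "training_history.csv",
                   np.column_stack([np.arange(len(run.history)), run.history.losses]),
                   delimiter=",", header="epoch,mae_loss", comments="")

    with _Stage("evaluate"):
        w_out = config.forecaster.w_out
        reports = [
            evaluate_forecast(run.predicted, run.actual, "first_window", w_out=w_out),
            evaluate_forecast(run.predicted, run.actual, "full_stride"),
        ]
        write_report_csv(reports, out / "metrics.csv")
        write_report_yaml(reports, out / "metrics.yaml")
        abs_error_trace(run.predicted, run.actual).to_csv(
            out / "abs_error_trace.csv", index=False
        )
        np.savetxt(out / "predicted_stride.csv", run.predicted, delimiter=",")
        np.savetxt(out / "actual_stride.csv", run.actual, delimiter=",")

    if config.evaluation.run_sweep:
        with _Stage("sweep"):
            sweep = input_window_sweep(
                train_series, test_series, config.forecaster,
                sizes=config.evaluation.sweep_sizes,
                output_size=config.forecaster.w_out,
            )
            sweep.to_csv(out / "sweep.csv")

    if config.evaluation.run_horizons:
        with _Stage("horizons"):
            results = horizon_comparison(
                train_series, test_series, config.forecaster,
                w_in=config.forecaster.w_in,
                horizons=config.evaluation.horizons,
            )
            flat = [rep for per_scope in results.values() for rep in per_scope.values()]
            write_report_csv(flat, out / "horizon_metrics.csv")

    manifest = {
        "config": _listify(config.to_dict()),
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "versions": {
            "gaitcast": __version__,
            "numpy": np.__version__,
        },
        "n_training_strides": int(n_train_strides),
        "n_training_subjects": len(train_series),
        "test_subject": test_series.subject_id,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", out)
    return out
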