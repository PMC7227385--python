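"""Exception hierarchy shared by all gaitcast stages."""


class GaitcastError(Exception):
    """Base class for all gaitcast errors (CLI maps these to exit code 1)."""


class ConfigurationError(GaitcastError):
    """A configuration object is invalid; the message names the offending field."""


class ParameterError(GaitcastError):
    """An operation was called with inconsistent or out-of-range arguments."""


class InsufficientDataError(GaitcastError):
    """Not enough samples/strides/windows to perform the requested operation."""


class DegenerateDataError(GaitcastError):
    """Data are degenerate for the requested statistic (e.g. zero variance)."""


class TrainingDivergedError(GaitcastError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged (non-finite loss) at epoch {epoch}")
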