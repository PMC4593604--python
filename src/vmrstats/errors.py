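"""Exception hierarchy.

Statistical/numerical problems and malformed inputs are kept distinct so the
command-line layer can map them to different exit codes (1 vs 2).
"""


class VmrError(Exception):
    """Base class for all package errors."""


class MalformedInputError(VmrError):
    """Input table violates a structural invariant (duplicates, bad flags)."""


class SchemaError(MalformedInputError):
    """A file is missing required columns or breaks a schedule invariant."""


class ValidationError(MalformedInputError):
    """A value is outside its legal domain (e.g. activity not in [0, 1])."""


class WindowOutOfRangeError(VmrError):
    """A stimulus event sits too close to the recording boundary."""

    def __init__(self, event_time_s: int, message: str):
        self.event_time_s = event_time_s
        super().__init__(message)


class InsufficientDataError(VmrError):
    """Too few observations for the requested statistic."""


class SingularCovarianceError(VmrError):
    """Pooled covariance is singular (zero-variance or collinear columns)."""

    def __init__(self, message: str, bad_columns=None):
        self.bad_columns = list(bad_columns) if bad_columns is not None else []
        super().__init__(message)


class DimensionError(VmrError):
    """Response dimension exceeds what the sample sizes support."""


class DegenerateFactorError(VmrError):
    """A model factor is constant in the data."""


class AliasingError(VmrError):
    """A model term is fully aliased with terms entered before it."""


class NoSolutionError(VmrError):
    """A sample-size search exhausted its range without meeting the target."""


class ConfigError(VmrError):
    """Invalid simulation or workflow configuration."""
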