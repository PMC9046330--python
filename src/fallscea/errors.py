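"""Exception hierarchy for configuration and model validation."""

from __future__ import annotations


class FallsCEAError(Exception):
    """Base class for package errors."""


class ConfigError(FallsCEAError):
    """A configuration document is malformed or incomplete."""


class ValidationError(FallsCEAError):
    """A parameter set violates a model invariant; names the field."""


class InfeasibleVarianceError(FallsCEAError):
    """A beta fit is impossible: the implied variance exceeds mean(1-mean)."""


class InfeasibleDecompositionError(FallsCEAError):
    """A conditional event probability exceeds 1 under the supplied inputs."""


class IncompatibleTraceError(FallsCEAError):
    """Two cohort traces cannot be compared (different horizons/settings)."""


class MissingRangeError(FallsCEAError):
    """A sensitivity-analysis parameter has no uncertainty range."""
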