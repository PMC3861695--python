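"""Exception hierarchy shared across the pipeline stages."""


class NirstateError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NirstateError, ValueError):
    """Invalid user-supplied parameter (durations, rates, grids, windows)."""


class DataError(NirstateError, ValueError):
    """Malformed or physically impossible data (non-positive intensity,
    length mismatch, zero-variance trace)."""


class ConfigurationError(NirstateError, ValueError):
    """Inconsistent analysis configuration (singular extinction matrix,
    unmonitorable region, missing pipeline stage input)."""
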