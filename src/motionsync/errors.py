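"""Exception types shared across the package."""


class MotionSyncError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MotionSyncError, ValueError):
    """Raised when numeric input violates a precondition (non-finite values,
    too-short series, shape mismatches)."""


class CompletenessError(MotionSyncError, ValueError):
    """Raised when a cohort is missing a series for an index triple."""


class SchemaError(MotionSyncError, ValueError):
    """Raised when on-disk metadata contains unknown tokens or malformed
    records."""


class ConvergenceError(MotionSyncError, RuntimeError):
    """Raised when the graph-learning solver fails to reach its stopping
    tolerance within the iteration budget."""


class ConfigError(MotionSyncError, ValueError):
    """Raised for inconsistent synthetic-cohort or filter configurations."""
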