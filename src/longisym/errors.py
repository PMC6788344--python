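"""Exception hierarchy shared across the package."""


class LongisymError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LongisymError, ValueError):
    """A configuration value is invalid or inconsistent (e.g. grid too small)."""


class DegenerateInputError(LongisymError, ValueError):
    """An input is degenerate for the requested operation (constant volume, empty mask)."""


class InputError(LongisymError, ValueError):
    """Runtime inputs violate an operation's preconditions (shape/grid mismatch)."""


class TrainingError(LongisymError, RuntimeError):
    """Training cannot proceed (e.g. a single-class training set)."""


class UndefinedMetricError(LongisymError, ValueError):
    """A metric is undefined for the given labels (e.g. one class only)."""


class UnsupportedLayerError(LongisymError, TypeError):
    """Relevance propagation hit a layer type it has no rule for."""


class SeparationError(LongisymError, RuntimeError):
    """Logistic fit diverged due to complete or quasi-complete separation."""


class NumericalDegeneracyError(LongisymError, ArithmeticError):
    """A statistic's variance estimate collapsed where it should not."""


class MissingArtifactError(LongisymError, FileNotFoundError):
    """A pipeline stage requires an upstream artifact that does not exist."""
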