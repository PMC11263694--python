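"""Exception hierarchy shared across the package."""


class NeurostatesError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NeurostatesError, ValueError):
    """A supplied parameter violates its contract (non-stochastic matrix,
    unstable VAR, bad band edges, ...)."""


class InvalidInputError(NeurostatesError, ValueError):
    """Input data violates a precondition (length mismatch, empty band, ...)."""


class FormatError(NeurostatesError, ValueError):
    """A file does not conform to the expected on-disk dialect."""


class EstimationError(NeurostatesError, RuntimeError):
    """A model could not be estimated from the data provided."""


class DecodingError(NeurostatesError, RuntimeError):
    """Viterbi decoding failed (zero-probability symbol)."""


class ConfigError(NeurostatesError, ValueError):
    """Configuration validation failed; ``errors`` lists every violation."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class DependencyError(NeurostatesError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
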