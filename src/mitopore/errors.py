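"""Exception hierarchy shared across the package."""


class MitoporeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MitoporeError, ValueError):
    """Invalid arguments, parameters or malformed domain objects."""


class ModelError(MitoporeError, ValueError):
    """A channel gating model violates its invariants (e.g. bad rate matrix)."""


class FittingError(MitoporeError, RuntimeError):
    """Mixture fitting failed to converge at every candidate model order."""


class ExclusionError(MitoporeError):
    """A statistic was requested for a trace excluded by the inclusion rule
    (no events outside the noise range)."""


class PairingError(ValidationError):
    """Pre/post vectors for a paired comparison cannot be paired."""


class DegenerateVarianceError(MitoporeError):
    """A t-test was requested on groups with zero variance and unequal means."""


class ParseError(MitoporeError, ValueError):
    """A trace or assay file violates the expected dialect.

    Carries the 1-based line number where parsing failed, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PresetError(MitoporeError, KeyError):
    """Unknown preset name."""
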