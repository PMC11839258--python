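"""Exception hierarchy shared across the pipeline."""


class PmgaitError(Exception):
    """Base class for all pmgait errors."""


class ValidationError(PmgaitError):
    """A parameter object or table violated one of its invariants."""


class DegenerateInputError(PmgaitError):
    """Input carries no usable variance (constant trial, zero-entropy series, ...)."""


class IntegrationError(PmgaitError):
    """Numerical integration produced a non-finite state."""


class MissingMarkerError(ValidationError):
    """A requested marker label is absent from the source file."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"markers absent from file: {', '.join(self.missing)}")


class MarkerGapError(ValidationError):
    """A selected marker contains NaN frames; trial rejected (no gap filling)."""
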