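"""Exception hierarchy for multichaos."""


class MultichaosError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MultichaosError, ValueError):
    """An argument is outside its admissible range."""


class OrbitDivergenceError(MultichaosError):
    """A simulated orbit escaped its attractor or produced non-finite state.

    Attributes
    ----------
    step : int or None
        Index of the first offending integration/iteration step.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class EmbeddingError(MultichaosError, ValueError):
    """The series is too short (or otherwise unfit) for the requested embedding."""


class DegenerateSeriesError(MultichaosError, ValueError):
    """The series carries no usable structure (constant, single-bin, all-duplicate...)."""


class FormatError(MultichaosError, ValueError):
    """An input file does not conform to the expected plain-text format."""
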