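"""Exception taxonomy shared across the package."""


class ConfigurationError(ValueError):
    """Unknown model id, missing config key, or invalid parameter."""


class ShapeError(ValueError):
    """Array / atom-count mismatch."""


class DegenerateGeometryError(ValueError):
    """Coincident atoms or other degenerate nuclear arrangement."""


class StationarityError(RuntimeError):
    """Geometry is not a proper minimum (imaginary retained frequency)."""


class SamplingError(RuntimeError):
    """Initial-condition sampling cannot proceed."""


class TrainingDivergenceError(RuntimeError):
    """Non-finite loss during surrogate training."""


class UntrainedModelError(RuntimeError):
    """Prediction requested from an untrained committee."""


class PropagationError(RuntimeError):
    """Non-finite forces or a numerically invalid electronic update."""


class DegenerateStateError(RuntimeError):
    """Hop probability requested for a state with zero population."""


class FitFailureError(RuntimeError):
    """Kinetics fit could not be performed (e.g. non-decaying series)."""


class EnsembleError(RuntimeError):
    """Every trajectory of an ensemble failed."""


class ParseError(ValueError):
    """Malformed input file; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
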