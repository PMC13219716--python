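"""Exception hierarchy for contour handling and analysis."""


class PuzzlecellError(Exception):
    """Base class for all package errors."""


class ContourParseError(PuzzlecellError):
    """A contour file contained a token that does not parse to a number."""


class MalformedContourError(PuzzlecellError):
    """Fewer than 3 usable vertices, or otherwise degenerate input."""


class MultiPieceError(PuzzlecellError):
    """One label covers several disconnected loops; such cells are rejected."""


class UnrepairableContourError(PuzzlecellError):
    """Self-intersections survived the repair iteration budget."""

    def __init__(self, message: str, flagged: list[int] | None = None):
        super().__init__(message)
        self.flagged = flagged or []


class DegenerateContourError(PuzzlecellError):
    """An operation collapsed the contour below 3 distinct vertices."""


class MetricError(PuzzlecellError):
    """A shape descriptor could not be computed."""


class FitError(PuzzlecellError):
    """A regression has too few or degenerate observations."""


class FuncFormatError(PuzzlecellError):
    """A growth-curve (.func) file is malformed."""


class SimulationError(PuzzlecellError):
    """A simulation run failed (e.g., widespread relaxation failure)."""
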