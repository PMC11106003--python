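"""Exception hierarchy for peptrack.

All exceptions derive from :class:`PeptrackError` so callers can catch the
package's failures with a single handler; most also derive from ``ValueError``
because they signal invalid inputs rather than internal faults.
"""


class PeptrackError(Exception):
    """Base class for all peptrack errors."""


class GeometryBoundsError(PeptrackError, ValueError):
    """A crystal index lies outside the scanner geometry; names the field."""


class OutOfFieldError(PeptrackError, ValueError):
    """A physical point lies outside the detector's axial field of view."""


class DegenerateLoRError(PeptrackError, ValueError):
    """A line of response with coincident endpoints (zero direction)."""


class ListModeParseError(PeptrackError, ValueError):
    """A list-mode file could not be parsed.

    Carries ``line`` (1-based, header included) when the offending row is
    known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ListModeValidationError(PeptrackError, ValueError):
    """Parsed list-mode content violates an invariant (bounds, finiteness)."""


class DegenerateGeometryError(PeptrackError, ValueError):
    """An LoR bundle too close to rank-deficient for a unique MDP."""


class InsufficientDataError(PeptrackError, ValueError):
    """Too few LoRs or tracked points for the requested computation."""


class EmptyTrajectoryError(PeptrackError, ValueError):
    """Tracking produced no valid points at all."""
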