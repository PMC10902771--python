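"""Exception hierarchy for the head-circumference toolkit.

Every error raised by the library derives from :class:`HeadCircError`, split
into three families that the command-line interface maps onto distinct exit
codes: validation problems (bad specs, bad arguments, malformed tables),
detection failures (nothing head- or reference-like in the image, ellipse fit
impossible), and insufficient data for a statistic.
"""


class HeadCircError(Exception):
    """Base class for all toolkit errors."""


# --- validation (CLI exit code 2) -------------------------------------------

class ValidationError(HeadCircError):
    """Input violates a documented precondition or invariant."""


class InvalidSpecError(ValidationError):
    """A phantom or rater-study specification violates its invariants."""


class InvalidArgumentError(ValidationError):
    """A scalar argument is out of its documented domain."""


class InvalidLandmarksError(ValidationError):
    """Landmark points violate their ordering/distinctness invariants."""


class PairingError(ValidationError):
    """Paired vectors have mismatched lengths."""


class ComparisonSpecError(ValidationError):
    """A comparison names an arm absent from the measurement table."""


class TableSchemaError(ValidationError):
    """A measurement table violates its schema (columns, keys, positivity)."""


# --- detection failures (CLI exit code 3) -----------------------------------

class DetectionError(HeadCircError):
    """The vision pipeline could not find a required object."""


class NoHeadFoundError(DetectionError):
    """No connected component passed the oval (ellipse-residual) gate."""


class NoReferenceFoundError(DetectionError):
    """No color-matched component was circular enough to be the reference."""


class FitFailureError(DetectionError):
    """Ellipse fitting failed (too few points or degenerate geometry)."""


# --- insufficient data (CLI exit code 4) ------------------------------------

class InsufficientDataError(HeadCircError):
    """Too few observations for the requested statistic."""


class MissingCellError(InsufficientDataError):
    """A crossed subject x rater design has empty cells."""

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(f"missing cells in crossed design: {self.cells}")


class DegenerateVarianceError(InsufficientDataError):
    """A variance in a denominator is exactly zero."""


class UndefinedKappaError(InsufficientDataError):
    """Chance agreement is 1 with imperfect observed agreement."""
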