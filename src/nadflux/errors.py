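"""Exception hierarchy for the nadflux pipeline.

``InputError`` and its subclasses map to CLI exit code 2 (malformed or
impossible input); ``ValidationFailure`` maps to exit code 1 (the data were
readable but failed an assay-validity gate).
"""


class NadFluxError(Exception):
    """Base class for all nadflux errors."""


class InputError(NadFluxError, ValueError):
    """A value violates a precondition (negative amount, zero time, ...)."""


class SchemaError(InputError):
    """A table carries an unknown analyte or an impossible column layout."""


class AmbiguityError(InputError):
    """Duplicate (sample, time, analyte) rows make quantification ambiguous."""


class DegenerateDesignError(InputError):
    """Calibration standards cannot identify a line (too few, or no spread)."""


class CalibrationError(NadFluxError):
    """A fitted calibration curve is unusable (non-positive slope, poor fit)."""


class InsufficientDataError(InputError):
    """Too few observations for the requested check or fit."""


class ValidationFailure(NadFluxError):
    """An assay-validity criterion failed on otherwise well-formed data."""
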