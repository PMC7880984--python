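"""Exception hierarchy.

``SaccfitError`` is the common base so callers can catch everything from
this package with one clause; the subclasses distinguish malformed files,
bad data, bad parameters, model-domain violations and degenerate fits.
"""


class SaccfitError(Exception):
    """Base class for all saccfit errors."""


class FormatError(SaccfitError):
    """Input file does not follow the expected layout (e.g. missing columns)."""


class DataError(SaccfitError):
    """Input data violate a precondition (too short, non-monotone time, ...)."""


class ParameterError(SaccfitError):
    """Invalid argument value (e.g. decimation factor < 1)."""


class DomainError(SaccfitError):
    """A model was evaluated outside its mathematical domain."""


class DegenerateSegmentError(SaccfitError):
    """A saccade segment cannot be analyzed (e.g. coincident fixations)."""


class FitError(SaccfitError):
    """A fit could not be carried out (flat input, no interior peak, ...)."""
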