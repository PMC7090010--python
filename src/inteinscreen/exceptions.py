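"""Exception hierarchy for inteinscreen.

All package errors derive from :class:`InteinScreenError` so callers can
catch everything from a pipeline run with a single ``except`` clause.
"""


class InteinScreenError(Exception):
    """Base class for all inteinscreen errors."""


class FormatError(InteinScreenError):
    """A file or table does not conform to the expected format."""


class LayoutError(InteinScreenError):
    """A sample is missing from, or inconsistent with, the plate layout."""


class ConfigurationError(InteinScreenError):
    """Required blanks/controls or generator settings are absent or invalid."""


class PairingError(InteinScreenError):
    """A fluorescence reading lacks its OD600 partner (or vice versa)."""


class InputError(InteinScreenError):
    """An operation received degenerate input (empty series, single point...)."""


class ShapeError(InteinScreenError):
    """A cross-reactivity matrix is not square / has missing cells."""


class AmbiguityError(InteinScreenError):
    """More than one signal maps to the same matrix cell."""


class UndefinedNormalizationError(InteinScreenError):
    """Cognate signal is non-positive, so relative values are undefined."""


class SubsetSizeError(InteinScreenError):
    """Exact subset search requested for a matrix too large to enumerate."""


class UndefinedReferenceError(InteinScreenError):
    """Cohort maximum is zero; fraction-of-max is undefined."""


class FitError(InteinScreenError):
    """A kinetic fit failed to converge or the model is unidentifiable."""


class CapacityError(InteinScreenError):
    """The intein library is too small for the requested assembly."""


class OrthogonalityError(InteinScreenError):
    """Assembly junctions would reuse non-orthogonal (or identical) inteins."""


class MissingSequenceError(InteinScreenError):
    """A computation requiring amino-acid sequences was asked of units without them."""


class ParameterError(InteinScreenError):
    """A numeric parameter is outside its valid range."""


class StateError(InteinScreenError):
    """A logic-gate evaluation is missing one of its inputs."""
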