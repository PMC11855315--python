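"""Exception hierarchy for poremorph.

Every error raised deliberately by the library derives from
:class:`PoremorphError`, so callers (and the CLI) can distinguish
contract violations from genuine bugs.
"""


class PoremorphError(Exception):
    """Base class for all poremorph errors."""


class InvalidScaleError(PoremorphError):
    """Scalebar length or reading is not a positive number."""


class ContractError(PoremorphError):
    """An argument violated an operation's precondition."""


class DegenerateTileError(ContractError):
    """CLAHE tile grid does not fit inside the image."""


class FitImpossibleError(PoremorphError):
    """Too few distinct points to fit an ellipse (need >= 5)."""


class UndefinedIPRError(PoremorphError):
    """Isoperimetric ratio requested for a zero-perimeter contour."""


class NotFoundError(PoremorphError):
    """A pore id is unknown or no longer in the detected set."""


class EmptySummaryError(PoremorphError):
    """Summary statistics requested for an empty pore list."""


class StateError(PoremorphError):
    """Operation requires session state that does not exist yet."""


class FormatError(PoremorphError):
    """Unsupported image file format."""


class InfeasibleSpecError(PoremorphError):
    """Phantom pores cannot be packed under the requested constraints."""


class ExportError(PoremorphError):
    """CSV or image export failed."""
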