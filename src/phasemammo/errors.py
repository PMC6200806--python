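"""Exception hierarchy.

All input-validation failures raise :class:`InvalidInputError`; lookups
outside a coefficient-table grid raise :class:`TableRangeError` (never a
silent extrapolation); estimators that cannot produce a defensible number
raise a dedicated signal instead of fabricating one.
"""


class PhasemammoError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PhasemammoError, ValueError):
    """A precondition on user input was violated."""


class TableRangeError(PhasemammoError, ValueError):
    """A query fell outside a coefficient table's tabulated grid."""


class UndefinedCnrError(PhasemammoError, ValueError):
    """CNR is undefined (zero-variance background ROI)."""


class UndeterminedResolutionError(PhasemammoError, RuntimeError):
    """The power-spectrum criterion found no threshold crossing."""
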