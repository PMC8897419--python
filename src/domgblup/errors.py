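"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors are handled by click (2),
:class:`DataError` maps to 3 and :class:`NumericalError` to 4.
"""


class DomGblupError(Exception):
    """Base class for all package errors."""


class DataError(DomGblupError):
    """Invalid, inconsistent or insufficient input data."""


class FormatError(DataError):
    """A file could not be parsed in the declared dialect."""


class EmptyDataError(DataError):
    """No usable records remain after parsing or filtering."""


class DimensionError(DataError):
    """Misaligned identifiers or array shapes between objects."""


class ConfoundingError(DataError):
    """Rank-deficient fixed-effect design (aliased factor levels)."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(
            message or f"confounded fixed-effect design; aliased columns: {self.aliased}"
        )


class NumericalError(DomGblupError):
    """Numerical failure (conditioning, non-positive-definiteness, ...)."""


class ConditioningError(NumericalError):
    """A matrix could not be factorised even after ridge stabilisation."""
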