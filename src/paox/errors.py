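"""Exception hierarchy shared across the package."""


class PaoxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PaoxError, ValueError):
    """A file or array does not have the expected layout (missing column,
    wrong dtype, wrong channel count)."""


class ValidationError(PaoxError, ValueError):
    """Inputs are well-formed but violate a contract (non-positive fluence,
    empty mask, mismatched shapes)."""


class RangeError(PaoxError, ValueError):
    """A query falls outside the tabulated or permitted range."""


class GeometryError(PaoxError, ValueError):
    """Requested geometry does not fit the image."""


class ConditioningError(PaoxError, ValueError):
    """A linear system is rank-deficient or too ill-conditioned to invert."""


class DegenerateInputError(PaoxError, ValueError):
    """The computation is mathematically undefined for this input
    (e.g. oxygen saturation of an all-zero region)."""


class InsufficientDataError(PaoxError, ValueError):
    """Too few observations to run the requested statistical procedure."""
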