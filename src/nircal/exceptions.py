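"""Exception hierarchy shared across the package."""


class NircalError(Exception):
    """Base class for all package-specific errors."""


class GridError(NircalError):
    """Wavelength grid is invalid (non-increasing, mismatched, uneven, empty range)."""


class DataError(NircalError):
    """Spectral or reference data failed validation (NaN, wrong shape, bad values)."""


class AlignmentError(NircalError):
    """Sample ids or wavelength subsets do not line up between two objects."""


class DegenerateDataError(NircalError):
    """An operation hit data with no usable spread (constant row, constant target)."""


class SizeError(NircalError):
    """A split or fit was requested on too few samples."""


class ConfigError(NircalError):
    """Invalid configuration parameters."""


class FeasibilityError(NircalError):
    """The constrained optimizer was given an infeasible starting point."""
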