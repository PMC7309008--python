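"""Exception hierarchy shared across the package."""


class OxishiftError(Exception):
    """Base class for all package-specific errors."""


class InputError(OxishiftError, ValueError):
    """Malformed or out-of-contract input (bad grid, short file, ...)."""


class DegenerateInputError(OxishiftError, ValueError):
    """Input that is formally valid but carries no usable signal
    (all-zero spectrum, disjoint source/detector supports, zero perfusion)."""


class ExtractionError(OxishiftError, ValueError):
    """Peak/FWHM extraction failed, e.g. no half-maximum crossing."""


class RangeError(OxishiftError, ValueError):
    """Wavelength outside a tabulated range; extrapolation is refused."""


class SingularityError(OxishiftError, ArithmeticError):
    """Ratio-of-ratios value at which the Beer-Lambert saturation formula
    has a vanishing denominator."""
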