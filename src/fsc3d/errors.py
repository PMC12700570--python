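"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors are handled by click (2),
:class:`ValidationError` and subclasses map to 3, I/O failures to 4 and
:class:`NumericalError` subclasses to 5.
"""


class FSC3DError(Exception):
    """Base class for all package errors."""


class ValidationError(FSC3DError, ValueError):
    """Invalid parameter, configuration or input data."""


class RangeError(ValidationError):
    """A query fell outside a tabulated/measured range."""


class PackingError(ValidationError):
    """Rejection sampling could not satisfy a separation constraint."""


class TransitError(ValidationError):
    """Acquisition too short for the object to transit the beam."""


class InsufficientDataError(ValidationError):
    """A record does not contain enough complete scans."""


class ExtentError(ValidationError):
    """Physical extents of two gridded objects do not match."""


class EstimationError(FSC3DError):
    """A metric could not be computed (e.g. empty mask)."""


class NumericalError(FSC3DError):
    """Numerically infeasible operation."""


class InstabilityError(NumericalError):
    """Unregularized inverse filtering was refused as unstable."""


class SingularityError(NumericalError):
    """A crosstalk spectrum matrix is singular at some spatial frequency."""


class ResourceError(FSC3DError):
    """A guarded size limit would be exceeded."""
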