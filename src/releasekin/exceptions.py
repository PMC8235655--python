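"""Exception hierarchy shared across the package."""


class ReleaseKinError(Exception):
    """Base class for all errors raised by releasekin."""


class DomainError(ReleaseKinError, ValueError):
    """An input lies outside the physical/mathematical domain of an operation."""


class ParameterError(ReleaseKinError, ValueError):
    """A model parameter set is incomplete or malformed."""


class DataError(ReleaseKinError, ValueError):
    """Observed data are unusable for the requested computation."""


class DegenerateDataError(DataError):
    """Data admit no meaningful fit (e.g. zero total variance, zero error SS)."""


class ParseError(DataError):
    """A file could not be parsed into a valid domain object."""


class DesignError(ReleaseKinError, ValueError):
    """A factorial design is incomplete or rank deficient for the analysis."""


class PartitionError(ReleaseKinError, ValueError):
    """No admissible segmentation of a release profile exists."""
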