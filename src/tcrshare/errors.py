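"""Exception hierarchy shared across the package."""


class TcrShareError(Exception):
    """Base class for all package errors."""


class FormatError(TcrShareError):
    """A required column or field is missing or malformed."""


class EmptyInputError(TcrShareError):
    """Input file or sample list is empty."""


class AlphabetError(TcrShareError):
    """Sequence contains characters outside its declared alphabet."""


class ConsistencyError(TcrShareError):
    """Inputs that must agree (chain, subject) do not."""


class DepthError(TcrShareError):
    """Requested subsampling depth exceeds available reads."""


class DesignError(TcrShareError):
    """Study design cannot support the requested analysis."""


class ConfigError(TcrShareError):
    """Invalid configuration or infeasible parameter combination."""


class DataError(TcrShareError):
    """Input data lack a field the operation requires."""


class PresenceError(TcrShareError):
    """A focal sequence is absent from data where it is required."""


class CoverageError(TcrShareError):
    """A cross-species set member is missing from a sample that must cover it."""
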