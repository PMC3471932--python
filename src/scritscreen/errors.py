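"""Exception hierarchy shared across the package."""


class ScritScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ScritScreenError):
    """A plate layout or run configuration is internally inconsistent."""


class DomainError(ScritScreenError, ValueError):
    """An argument lies outside the mathematically valid domain."""


class FormatError(ScritScreenError):
    """A delimited input file does not conform to the expected schema."""


class ContractError(ScritScreenError):
    """Objects passed to an operation violate its preconditions."""


class QCError(ScritScreenError):
    """A plate fails quality control hard enough to be rejected."""
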