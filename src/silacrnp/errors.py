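"""Exception hierarchy shared across the pipeline stages."""


class SilacRnpError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SilacRnpError, ValueError):
    """An input file does not conform to the expected dialect."""


class DomainError(SilacRnpError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class DesignError(SilacRnpError, ValueError):
    """Experimental-design mismatch, e.g. two mixtures with identical label orientation."""


class InsufficientDataError(SilacRnpError, ValueError):
    """Too few observations to carry out the requested computation."""


class DegenerateError(SilacRnpError, ValueError):
    """The data are degenerate for the requested operation (zero variance, anchor at the median, ...)."""


class ConfigError(SilacRnpError, ValueError):
    """A pipeline configuration file is invalid."""
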