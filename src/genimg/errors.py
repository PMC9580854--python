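"""Exception hierarchy shared across the package."""


class GenimgError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GenimgError):
    """A simulation or training parameter is outside its valid range."""


class ParseError(GenimgError):
    """A genotype file could not be parsed; the message names the offending
    record, row or column."""


class DataError(GenimgError):
    """Input data violates a precondition (empty stratum, shape mismatch,
    zero surviving SNPs, ...)."""
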