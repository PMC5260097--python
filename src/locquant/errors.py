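"""Exception hierarchy."""


class LocquantError(Exception):
    """Base class for all package errors."""


class GtfParseError(LocquantError):
    """A GTF line could not be parsed; message names the line number."""


class ValidationError(LocquantError):
    """A domain object violates its invariants."""


class IndexFormatError(LocquantError):
    """A bundle-index file is missing, corrupted, or of the wrong version."""


class DepthError(LocquantError):
    """Sequencing depth is zero where a depth denominator is required."""


class ConfigError(LocquantError):
    """A simulation or run configuration is internally inconsistent."""
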