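"""Exception hierarchy shared across the package."""


class MixQsarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MixQsarError):
    """A requested column, parameter, or option is invalid or missing."""


class DataError(MixQsarError):
    """Input data violates a precondition (non-numeric cell, bad shape...)."""


class IntegrityError(DataError):
    """Packaged reference data failed its checksum or shape validation."""


class ConvergenceError(MixQsarError):
    """An iterative solver exhausted its iteration budget."""
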