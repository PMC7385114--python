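"""Exception hierarchy shared by all analysis stages."""


class MeaTrainerError(Exception):
    """Base class for all package errors."""


class ValidationError(MeaTrainerError, ValueError):
    """Input violates a documented contract (bad values, bad geometry)."""


class FormatError(ValidationError):
    """A file on disk does not match the expected layout."""


class ConfigurationError(MeaTrainerError):
    """A configuration cannot be satisfied (e.g. threshold search exhausted)."""


class DependencyError(MeaTrainerError):
    """A pipeline stage is missing an upstream output."""
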