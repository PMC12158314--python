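"""Exception hierarchy for the gaitdemog pipeline."""


class GaitError(Exception):
    """Base class for all errors raised by gaitdemog."""


class ConfigurationError(GaitError):
    """Invalid configuration: bad parameter values, malformed config files."""


class FormatError(GaitError):
    """A file does not follow the expected on-disk format."""


class DataError(GaitError):
    """Input data violates a precondition (too short, non-monotone, missing column...)."""
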