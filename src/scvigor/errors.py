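"""Exception hierarchy shared across the pipeline stages."""


class ScvigorError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScvigorError):
    """Invalid generator, bootstrap or pipeline configuration."""


class DataFormatError(ScvigorError):
    """A session file or in-memory structure violates the data contract."""


class TooFewTrialsError(ScvigorError):
    """An analysis received fewer trials than its minimum."""


class UndefinedCorrelationError(ScvigorError):
    """A correlation was requested on a constant rate or behavior series."""
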