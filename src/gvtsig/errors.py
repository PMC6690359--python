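"""Exception hierarchy shared across the pipeline."""


class GvtsigError(Exception):
    """Base class for all package errors."""


class FormatError(GvtsigError, ValueError):
    """An input file violates the expected format."""


class ConfigError(GvtsigError, ValueError):
    """A parameter is outside its legal domain."""


class UsageError(GvtsigError, ValueError):
    """An operation was called on inputs it cannot meaningfully process."""
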