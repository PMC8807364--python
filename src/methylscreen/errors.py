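"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; everything else is a plain crash (exit 1).
"""


class MethylScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MethylScreenError):
    """Invalid configuration value; the message names the offending field."""


class DataError(MethylScreenError):
    """Malformed or inconsistent input data."""
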