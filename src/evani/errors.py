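"""Exception hierarchy.

``ConfigError`` signals an invalid configuration (bad rates, sizes,
unknown keys); ``DataError`` signals malformed or inconsistent input data
(unparseable files, duplicate ids, non-symmetric matrices). The CLI maps
``ConfigError``/``DataError`` to exit code 3 and usage errors to 2.
"""


class EvaniError(Exception):
    """Base class for all package errors."""


class ConfigError(EvaniError):
    """Invalid configuration value or combination."""


class DataError(EvaniError):
    """Malformed, inconsistent, or out-of-contract input data."""
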