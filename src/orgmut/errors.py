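"""Exception hierarchy.

Exit-code mapping in the CLI: ConfigError -> 2, DataError -> 3.
"""


class OrgmutError(Exception):
    """Base class for all package errors."""


class ConfigError(OrgmutError):
    """Invalid configuration or parameter value."""


class DataError(OrgmutError):
    """Malformed or inconsistent input data."""
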