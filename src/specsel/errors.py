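"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes, so keep the split between
configuration problems, malformed input data, and runtime failures.
"""


class SpecselError(Exception):
    """Base class for all package errors."""


class ConfigError(SpecselError):
    """Invalid configuration value or combination."""


class DataError(SpecselError):
    """Malformed or inconsistent input data."""


class ConvergenceError(SpecselError):
    """An iterative solver exhausted its iteration budget."""
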