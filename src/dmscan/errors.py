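"""Exception hierarchy.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3, statistical degeneracies exit 4.
"""


class DmscanError(Exception):
    """Base class for all package errors."""


class ConfigError(DmscanError):
    """Invalid run configuration or invalid parameter combination."""


class DataError(DmscanError):
    """Malformed or inconsistent input data."""


class DegenerateStatisticError(DmscanError):
    """A statistic is undefined on the given table (e.g. empty classes)."""
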