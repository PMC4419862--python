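"""Exception hierarchy shared across middascan.

Two error families map onto distinct CLI exit codes: malformed or
inconsistent inputs (exit 2) and statistically degenerate situations
such as a zero-variance profile (exit 3).
"""


class MiddascanError(Exception):
    """Base class for all middascan errors."""


class InputError(MiddascanError):
    """Malformed, inconsistent, or missing input data (CLI exit code 2)."""


class DegenerateStatisticsError(MiddascanError):
    """A statistic is undefined on the given data, e.g. zero standard
    deviation in a Z-score or fewer than two windows genome-wide
    (CLI exit code 3)."""
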