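"""Package exception hierarchy with CLI exit codes.

Exit-code convention: 0 success, 2 configuration/parameter error,
3 data error, 4 capacity error.
"""


class CoaSurrogateError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(CoaSurrogateError):
    """Invalid parameter or configuration value."""

    exit_code = 2


class DataError(CoaSurrogateError):
    """Malformed, missing or inconsistent data."""

    exit_code = 3


class CapacityError(CoaSurrogateError):
    """A case exceeds a fixed model capacity (padded length, plane count)."""

    exit_code = 4
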