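"""Exception hierarchy mapped to CLI exit codes."""


class DDNetMapError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ParameterError(DDNetMapError):
    """Invalid parameter or configuration value."""

    exit_code = 2


class FormatError(DDNetMapError):
    """Malformed input file."""

    exit_code = 3


class StageError(DDNetMapError):
    """A pipeline stage failed."""

    exit_code = 4
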