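"""Exception hierarchy mapped to CLI exit codes."""


class ContextCutError(Exception):
    """Base class; carries the process exit code used by the CLI."""

    exit_code = 1


class ValidationError(ContextCutError):
    """Invalid inputs or parameter values."""

    exit_code = 2


class FormatError(ValidationError):
    """Inconsistent or malformed volume data (shape/spacing mismatch)."""

    exit_code = 2


class IOFailure(ContextCutError):
    """Unreadable or unwritable files."""

    exit_code = 3


class ResourceError(ContextCutError):
    """Problem too large for the requested operation."""

    exit_code = 4
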