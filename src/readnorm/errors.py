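"""Exception hierarchy for readnorm.

All package errors derive from :class:`ReadNormError` so callers (and the
CLI) can distinguish expected failure categories from bugs.
"""


class ReadNormError(Exception):
    """Base class for all readnorm errors."""


class FastqParseError(ReadNormError):
    """A FASTQ/FASTA record could not be parsed (truncation, length mismatch)."""


class PairingError(ReadNormError):
    """Paired input files have unequal record counts."""


class PhredEncodingError(ReadNormError):
    """A quality character decodes below zero for the configured offset."""


class ModeError(ReadNormError):
    """The requested mode is incompatible with the input (e.g. quality mode on FASTA)."""


class ParameterError(ReadNormError):
    """A numeric parameter is out of its valid domain (k < 1, b <= 1, ...)."""


class ConfigError(ReadNormError):
    """A simulation or run configuration is degenerate or self-contradictory."""


class InputError(ReadNormError):
    """Input data violates an operation's precondition (empty set, unknown id)."""


class StateError(ReadNormError):
    """Internal objects passed together are mutually inconsistent."""
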