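"""Exception hierarchy.

All errors raised deliberately by this package derive from
:class:`SeqSanitizeError`, so callers can catch one base class at the
sample-processing boundary and report the failure without masking
programming errors.
"""


class SeqSanitizeError(Exception):
    """Base class for all errors raised by seqsanitize."""


class FormatError(SeqSanitizeError):
    """A file is not in the format it was declared or detected to be."""


class ParseError(SeqSanitizeError):
    """A file in a recognized format is malformed or truncated."""


class RecordError(SeqSanitizeError):
    """A single record violates its own invariants (e.g. length mismatch)."""


class PairingError(SeqSanitizeError):
    """Two streams that must stay in lockstep have diverged."""


class ContractError(SeqSanitizeError):
    """An operation was invoked on input that does not satisfy its
    preconditions (the caller should skip or fix the call)."""


class OptionsError(SeqSanitizeError):
    """The options / target / adapter configuration files are invalid."""
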