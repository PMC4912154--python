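"""Typed exceptions used across the pipeline.

Every stage failure maps onto one of these, and the command-line layer
translates them into documented exit codes.
"""


class ViroseekError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(ViroseekError):
    """An invalid configuration value; the message names the offending field."""

    exit_code = 2


class ParameterError(ViroseekError):
    """An operation was called with arguments outside its domain."""

    exit_code = 3


class AlphabetError(ViroseekError):
    """A sequence had the wrong alphabet for the requested operation."""

    exit_code = 4


class FormatError(ViroseekError):
    """A file could not be parsed as the declared format."""

    exit_code = 5


class NoBlockError(ViroseekError):
    """No alignment window satisfied the gap constraint."""

    exit_code = 6


class MappingError(ViroseekError):
    """A conserved block could not be mapped onto the chosen reference row."""

    exit_code = 7


class EncodingError(ViroseekError):
    """A peptide could not be reverse-translated without an in-frame stop."""

    exit_code = 8


class AmbiguityError(ViroseekError):
    """The contig link graph branches; no unique chain exists."""

    exit_code = 9


class MergeError(ViroseekError):
    """Linking reads disagree at a junction with no majority."""

    exit_code = 10


class ConsistencyError(ViroseekError):
    """Internal data structures disagree (e.g. a hit outside its contig)."""

    exit_code = 11


class NoVirophageSignal(ViroseekError):
    """No marker-encoding contig was found; a clean negative result."""

    exit_code = 0
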