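"""Exception hierarchy.

All library errors derive from :class:`ImprodynError` so callers can catch
package failures with a single except clause. Parameter misuse additionally
derives from :class:`ValueError` to stay idiomatic.
"""


class ImprodynError(Exception):
    """Base class for all improdyn errors."""


class ParameterError(ImprodynError, ValueError):
    """An argument is outside its documented domain."""


class DataError(ImprodynError, ValueError):
    """Input data violates a structural precondition (e.g. non-positive duration)."""


class AlphabetError(ImprodynError, KeyError):
    """A symbol or context is not a member of the model's alphabet."""


class MonophonyError(DataError):
    """A MIDI stream contains overlapping notes beyond the legato tolerance."""


class MidiFormatError(ImprodynError, ValueError):
    """A file is not a parseable Standard MIDI File."""


class DegenerateSignalError(DataError):
    """A signal is constant or empty where variation is required."""


class ManifestError(DataError):
    """Corpus manifest and per-piece data disagree."""
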