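"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`EpiselectError`, so callers can catch one type at pipeline level
while still distinguishing configuration problems from malformed input.
"""


class EpiselectError(Exception):
    """Base class for all errors raised by episelect."""


class FormatError(EpiselectError):
    """An input file does not have the expected structure (e.g. a missing column)."""


class AlphabetError(EpiselectError, ValueError):
    """A peptide string contains a character outside the 20-letter amino-acid alphabet."""


class ScoringError(EpiselectError):
    """A peptide cannot be scored against a matrix (typically a length mismatch)."""


class ConfigurationError(EpiselectError):
    """A run or cascade configuration is inconsistent or incomplete."""


class GenerationError(EpiselectError):
    """A synthetic-data spec cannot be realised (e.g. effect below calling thresholds)."""


class UnextendableError(EpiselectError):
    """A binder window cannot be extended to a 15-mer (source protein too short)."""


class ClassificationError(EpiselectError):
    """A longitudinal response cannot be classified (e.g. no pre-treatment timepoint)."""
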