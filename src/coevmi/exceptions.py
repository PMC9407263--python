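"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`CoevMIError`
so the CLI can catch one type and translate it into a message + nonzero exit.
"""


class CoevMIError(Exception):
    """Base class for all coevmi errors."""


class AlignmentFormatError(CoevMIError):
    """Input is not a well-formed aligned FASTA (empty, ragged, bad characters)."""


class MissingReferenceError(CoevMIError):
    """The requested reference species is absent from one of the alignments."""


class InsufficientSpeciesError(CoevMIError):
    """Fewer common species than the required minimum (default 100)."""


class CalibrationError(CoevMIError):
    """Probability-table construction received unusable score sets."""


class SelectionError(CoevMIError):
    """No hyperparameter combination satisfies the selection constraint."""
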