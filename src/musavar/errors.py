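"""Exception hierarchy for the musavar pipeline.

Every anticipated failure mode gets its own class so callers can distinguish
"bad input" from "method refused to call" — refusals (aneuploid counts,
unresolved flow peaks) are data, and cohort summaries report them rather than
silently dropping them.
"""


class MusavarError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MusavarError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(MusavarError, ValueError):
    """A file violates the expected text format; message names the record."""


class ConfigError(MusavarError, ValueError):
    """Run configuration is invalid (unknown key, missing required value)."""


class UndefinedConcordanceError(MusavarError):
    """No ratoon observations: the concordance coefficient has no value."""


class MissingSampleError(MusavarError, KeyError):
    """A requested sample label is absent from the alignment."""


class InvalidAlignmentError(MusavarError, ValueError):
    """Alignment rows differ in length or use a forbidden alphabet."""


class OutOfFrameError(MusavarError):
    """A position falls in an incomplete codon for the given reading frame."""


class InvalidProfileError(MusavarError, ValueError):
    """A substitution profile is internally inconsistent."""


class PlacementFailureError(MusavarError):
    """The reference lacks enough suitable positions to realize a profile."""


class AneuploidCountError(MusavarError):
    """Modal chromosome count is not near a multiple of the basic number."""


class NoPeaksError(MusavarError):
    """No peak rises above the prominence floor in a flow histogram."""


class UnresolvedPloidyError(MusavarError):
    """Dominant peak deviates too far from any integer-ploidy position."""
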