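"""Exception hierarchy for lampmask.

Every user-facing failure mode has a dedicated class so the CLI can map
module errors onto exit messages without string matching.
"""


class LampmaskError(Exception):
    """Base class for all lampmask errors."""


class MalformedHeaderError(LampmaskError):
    """A record header does not split into 2 or 3 delimiter-separated fields."""


class AlignmentShapeError(LampmaskError):
    """Sequences in the alignment do not all have the same length."""


class InsufficientGroupsError(LampmaskError):
    """Fewer than two taxon groups present; group comparison is undefined."""


class AlphabetError(LampmaskError):
    """A sequence contains characters outside the nucleotide alphabet."""


class UnknownGroupError(LampmaskError):
    """A taxon label was requested that is not present in the alignment."""


class ParameterError(LampmaskError):
    """An algorithm parameter violates its contract (e.g. even window)."""


class TooShortAlignmentError(LampmaskError):
    """Alignment has too few full fragments for a single sliding window."""


class RegionSizeError(LampmaskError):
    """A target region exceeds the downstream size limit after degapping."""


class PlanError(LampmaskError):
    """A synthetic-alignment plan is internally inconsistent or infeasible."""


class OutputCollisionError(LampmaskError):
    """An output directory or archive for this project id already exists."""


class WriteError(LampmaskError):
    """An output file could not be written."""
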