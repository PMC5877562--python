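"""Exception hierarchy.

Every reader rejects malformed input with a distinct, catchable error
instead of silently truncating or coercing.
"""


class PlastomicsError(Exception):
    """Base class for all package errors."""


class FormatError(PlastomicsError):
    """A file does not conform to its declared format."""


class EmptyRecordError(FormatError):
    """A FASTA record with an empty sequence."""


class DuplicateIdError(FormatError):
    """Two records in one file share an identifier."""


class RaggedAlignmentError(FormatError):
    """Alignment rows differ in length."""


class GroupingError(FormatError):
    """Grouping file malformed, or an alignment id has no tier."""


class LocationError(FormatError):
    """A feature location is malformed or outside the sequence."""


class SaturationError(PlastomicsError):
    """Observed p-distance at or beyond the Jukes-Cantor ceiling of 3/4."""


class NoComparableSitesError(PlastomicsError):
    """No alignment column usable for a pairwise distance."""


class SimulationError(PlastomicsError):
    """Invalid simulation configuration or planting request."""


class AlignmentSizeError(PlastomicsError):
    """Input exceeds the documented scale limit of the progressive aligner."""
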