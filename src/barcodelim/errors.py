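"""Exception hierarchy for the barcode delimitation pipeline."""


class BarcodeError(Exception):
    """Base class for all pipeline errors."""


class AlignmentError(BarcodeError):
    """Sequences violate alignment invariants (ragged lengths, bad characters)."""


class TaxonomyError(BarcodeError):
    """Taxonomy table is missing ids or columns required by the sequence data."""


class FormatError(BarcodeError):
    """A file does not conform to the expected on-disk dialect."""


class QCError(BarcodeError):
    """A sequence cannot be quality-screened (e.g. too short to translate)."""


class DistanceError(BarcodeError):
    """A distance operation was attempted on undefined or invalid input."""


class TreeError(BarcodeError):
    """Tree construction or annotation failed."""


class PartitionError(BarcodeError):
    """Group-assignment inputs are inconsistent (id sets differ, bad thresholds)."""
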