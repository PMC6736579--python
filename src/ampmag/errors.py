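"""Exception hierarchy for the toolkit.

The CLI maps these onto exit codes: input/format problems exit 2,
configuration/spec problems exit 3.
"""


class AmpmagError(Exception):
    """Base class for all toolkit errors."""


class FormatError(AmpmagError):
    """Malformed input file (bad counts, bad GFF3 row, duplicate ids...)."""


class ManifestError(FormatError):
    """Sample-role manifest inconsistent with the count table."""


class InputError(AmpmagError):
    """Invalid in-memory input (empty sequence, empty depth track...)."""


class DepthError(InputError):
    """A sample library is too shallow to normalize."""


class AnnotationError(AmpmagError):
    """A flagged OTU lacks a representative sequence."""


class ReviewError(AmpmagError):
    """A culling decision refers to an OTU that was never flagged."""


class ConsistencyError(AmpmagError):
    """Cross-references between result objects do not line up."""


class ConfigurationError(AmpmagError):
    """Invalid configuration (no blanks designated, bad thresholds...)."""


class SeedIndexError(AmpmagError):
    """The k-mer word size is incompatible with the database."""


class SpecError(ConfigurationError):
    """Infeasible synthetic-fixture specification."""


class PanelError(AmpmagError):
    """Malformed marker panel (empty symbol set)."""
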