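"""Exception hierarchy for pathpairs.

Every error raised on a contract violation derives from :class:`PathpairsError`
so callers (and the CLI) can catch the package's own failures distinctly from
library bugs.
"""


class PathpairsError(Exception):
    """Base class for all pathpairs errors."""


class ConfigError(PathpairsError):
    """Invalid configuration value (ratio out of range, unknown backend, ...)."""


class SchemaError(PathpairsError):
    """Mismatch between a matrix/model and the columns or ids it expects."""


class MembershipError(PathpairsError):
    """A pathway catalog references a metabolite id absent from the matrix."""


class DegeneratePathwayError(PathpairsError):
    """A pathway category with an empty membership set."""


class MetadataError(PathpairsError):
    """Required per-column metadata (bond level) is missing."""


class EmptyInputError(PathpairsError):
    """An operation received an empty dataset or matrix."""


class StratificationError(PathpairsError):
    """A stratum is too small to split."""


class DegenerateTrainingSetError(PathpairsError):
    """A training set with a single class (no positives or no negatives)."""


class UnsupportedOperationError(PathpairsError):
    """Operation not defined for the requested backend (e.g. MLP importance)."""
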