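"""Exception hierarchy shared across the package.

All errors derive from :class:`MirshiftError` so callers (and the CLI)
can catch pipeline failures without swallowing programming errors.
"""


class MirshiftError(Exception):
    """Base class for all mirshift errors."""


class FormatError(MirshiftError):
    """A file does not match the expected dialect (e.g. a missing column)."""


class ValidationError(MirshiftError):
    """A file parsed but violates a content invariant (duplicates, negatives...)."""


class ConfigError(MirshiftError):
    """A configuration value is out of its documented range."""


class ContractError(MirshiftError):
    """An operation was called on inputs missing a required annotation."""


class ZeroExpressionError(MirshiftError):
    """Fold change requested for a miRNA with zero RPM at a timepoint."""


class NoMappedReadsError(MirshiftError):
    """RPM normalization requested but no read mapped to the reference."""


class EnumerationBoundError(MirshiftError):
    """Exact p-value enumeration refused: too many label combinations."""
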