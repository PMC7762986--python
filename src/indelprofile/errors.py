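"""Exception hierarchy for the indelprofile package.

Every error raised by the library derives from :class:`IndelProfileError`
so callers (and the CLI) can distinguish data/validation failures from
programming errors.
"""


class IndelProfileError(Exception):
    """Base class for all indelprofile errors."""


class EmptyInputError(IndelProfileError):
    """An input file or table contained no usable records."""


class AlignmentWidthError(IndelProfileError):
    """Alignment records do not all share the same number of columns."""


class GapDialectError(IndelProfileError):
    """A gap character other than '-' was encountered."""


class SchemaError(IndelProfileError):
    """A tabular input is missing required columns or is malformed."""


class DuplicateKeyError(IndelProfileError):
    """A key that must be unique occurred more than once."""


class GeometryError(IndelProfileError):
    """Region coordinates are out of order, overlapping, or inverted."""


class ParameterError(IndelProfileError):
    """A parameter value is outside its valid domain."""


class LabelingError(IndelProfileError):
    """A sequence has no matching metadata record."""


class MetadataConflictError(IndelProfileError):
    """Conflicting labels were supplied for the same accession."""


class UndefinedStatisticError(IndelProfileError):
    """A statistic is undefined for the given input (e.g. no complete profiles)."""


class PanelSizeError(IndelProfileError):
    """The region panel is too large for exhaustive enumeration."""


class ConfigError(IndelProfileError):
    """A simulation configuration violates its invariants."""
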