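"""Exception hierarchy shared across the package.

All errors derive from :class:`UevNormError` so callers can catch the
package's failures with a single ``except`` clause; the concrete classes
distinguish bad numeric inputs, bad configuration, too-small samples and
malformed files.
"""


class UevNormError(Exception):
    """Base class for every error raised by uevnorm."""


class DomainError(UevNormError, ValueError):
    """A numeric argument is outside the domain of an operation
    (e.g. a non-positive concentration or a fraction outside (0, 1])."""


class ConfigurationError(UevNormError, ValueError):
    """A simulation or pipeline configuration field is invalid.

    The message always names the offending field.
    """


class InsufficientDataError(UevNormError, ValueError):
    """Too few observations for the requested statistic
    (e.g. a dispersion summary of a single pair)."""


class SchemaError(UevNormError, ValueError):
    """A table is missing a required column or has an uncoercible dtype.

    The message names the first offending column.
    """


class UnitError(UevNormError, ValueError):
    """A ``# units:`` header declares a unit that differs from the schema."""
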