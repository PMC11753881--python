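"""Exception hierarchy shared across the package.

All exceptions derive from :class:`EVQuantError` so callers can catch the
package's failures with a single ``except``; each subclass also derives from
``ValueError`` to keep plain-Python idioms working.
"""


class EVQuantError(Exception):
    """Base class for all errors raised by evquant."""


class ConfigurationError(EVQuantError, ValueError):
    """A configuration object or option is invalid."""


class SchemaError(EVQuantError, ValueError):
    """An input table violates its documented schema (columns, ids, groups)."""


class ParseError(EVQuantError, ValueError):
    """A cell that must be numeric could not be parsed."""


class ValidationError(EVQuantError, ValueError):
    """Values are structurally well-formed but violate a contract."""


class EmptyInputError(EVQuantError, ValueError):
    """An operation that needs at least one record received none."""


class DegenerateVarianceError(EVQuantError, ValueError):
    """Every residual variance is zero; no variance model can be fit."""


class InsufficientReplicatesError(EVQuantError, ValueError):
    """Fewer replicates than the statistical procedure requires."""
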