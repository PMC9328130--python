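"""Exception hierarchy for ccmeta.

All package errors derive from :class:`MetaError` so callers can catch one
base class; subclasses distinguish schema problems (bad input files) from
domain errors (invalid values fed to a statistic) and analysis
preconditions (a moderator that cannot legally be analysed).
"""


class MetaError(Exception):
    """Base class for all ccmeta errors."""


class SchemaError(MetaError):
    """An input table does not conform to the observation schema."""


class DomainError(MetaError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class PreconditionError(MetaError):
    """An analysis precondition (e.g. minimum level support) is violated."""


class ConfigError(MetaError):
    """A simulation or run configuration is invalid."""
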