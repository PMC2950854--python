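"""Exception hierarchy for the cmca package.

All package-specific failures derive from :class:`CmcaError` so callers can
catch one base class at the pipeline boundary.
"""


class CmcaError(Exception):
    """Base class for all cmca errors."""


class EmptyInputError(CmcaError):
    """An input file contained no usable records."""


class AlignmentShapeError(CmcaError):
    """Sequences in an alignment do not all share the same length."""


class ValidationError(CmcaError):
    """An object violates a structural invariant (duplicate ids, bad symbol...)."""


class DomainError(CmcaError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class ReductionError(CmcaError):
    """Gap-column reduction removed every column of the alignment."""


class ConsistencyError(CmcaError):
    """Objects passed together do not describe the same analysis run."""


class FamilySpecError(CmcaError):
    """A synthetic family specification is internally inconsistent."""


class ConfigError(CmcaError):
    """A pipeline configuration value is out of range or inconsistent."""
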