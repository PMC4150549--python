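"""Exception types shared across the pipeline."""


class AdeconcordError(Exception):
    """Base class for all package errors."""


class UnmappedDrugError(AdeconcordError):
    """A raw drug name has no entry in the synonym map (strict policy)."""


class UnmappedTermError(AdeconcordError):
    """A PT has no entry in the MedDRA PT→HLT map (strict policy)."""


class TermLevelError(AdeconcordError):
    """An operation received a snapshot at the wrong MedDRA term level."""


class ConfigError(AdeconcordError):
    """Invalid or inconsistent configuration."""


class DegenerateInputError(AdeconcordError):
    """Input too small or too uniform for the requested statistic."""


class ConvergenceError(AdeconcordError):
    """Model fitting failed to converge."""


class SchemaError(AdeconcordError):
    """Column/coverage mismatch between fitted model and scoring input."""


class CoverageError(AdeconcordError):
    """A score table does not cover the requested pairs."""


class DependencyError(AdeconcordError):
    """A pipeline stage is missing a required upstream artifact."""
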