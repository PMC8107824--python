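"""Exception hierarchy shared across the toolkit."""


class ClinauditError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(ClinauditError):
    """A required column or feature is missing or malformed."""


class ParseError(ClinauditError):
    """A cell value could not be interpreted (reported with its row index)."""


class EmptyClassError(ClinauditError):
    """A training subset ended up with zero positives or zero negatives."""


class ConfigurationError(ClinauditError):
    """A generator or audit configuration is invalid or infeasible."""


class SamplingError(ClinauditError):
    """A resampling quota cannot be satisfied by the available records."""


class AuditError(ClinauditError):
    """A bias-audit iteration cannot be carried out (e.g. a one-class group)."""


class DegenerateCurveError(ClinauditError):
    """ROC construction was attempted on single-class labels."""
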