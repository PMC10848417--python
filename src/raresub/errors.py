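"""Exception hierarchy shared across the pipeline."""


class RaresubError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RaresubError):
    """A table is missing a required column or has an unusable header."""


class ValidationError(RaresubError):
    """A record violates a domain invariant (row number included when known)."""


class AnnotationError(RaresubError):
    """Trinucleotide-context annotation failed (e.g. reference mismatch)."""


class DetectionImpossibleError(RaresubError):
    """Site depth is below the minimum alternate-observation requirement."""


class AmbiguousMultiplicityError(RaresubError):
    """An operation requiring an unambiguous multiplicity factor was given
    a locus where more than one allele could carry the mutation."""


class UndefinedEstimateError(RaresubError):
    """An estimator's preconditions hold but the quantity is undefined on the
    given data (e.g. no demonstrable artifact burden in untreated samples)."""


class ConfigError(RaresubError):
    """A simulation or run configuration is internally inconsistent."""
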