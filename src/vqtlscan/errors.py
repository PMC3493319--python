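"""Exception hierarchy shared across the package."""


class VQTLError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VQTLError):
    """A file does not conform to the expected layout (header, columns)."""


class ParseError(VQTLError):
    """A cell or field could not be parsed as the expected type."""


class ValidationError(VQTLError):
    """Parsed data violate a domain invariant (e.g. dosage outside [0, 2])."""


class AlignmentError(VQTLError):
    """Genotype and phenotype sample sets cannot be reconciled."""


class MonomorphicError(VQTLError):
    """A marker has fewer than two distinct genotype classes/dosage values."""


class ConfigurationError(VQTLError):
    """A method/option combination is invalid for the given data."""


class DegenerateFitError(VQTLError):
    """A regression fit is degenerate (saturated, rank-deficient response)."""


class DivergenceError(VQTLError):
    """An iterative fit diverged (e.g. dispersion linear predictor overflow)."""


class DomainError(VQTLError):
    """Input values are outside the mathematical domain of an operation."""
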