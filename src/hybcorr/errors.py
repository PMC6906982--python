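"""Exception hierarchy shared across the package."""


class HybcorrError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HybcorrError):
    """Input data violate a structural invariant (duplicates, bad counts, ...)."""


class VocabularyError(ValidationError):
    """A categorical trait state is not in the trait's vocabulary."""


class UndefinedMetricError(HybcorrError):
    """A hybridization metric is requested for a group where its denominator vanishes."""


class TreeError(HybcorrError):
    """Malformed Newick, duplicate tips, missing branch lengths, or pruning problems."""


class ModelAssumptionError(HybcorrError):
    """A covariance model's structural assumption (e.g. ultrametricity for OU) fails."""


class NumericalError(HybcorrError):
    """Singular designs, failed factorizations, or optimizer non-convergence."""


class AlignmentError(HybcorrError):
    """Data rows cannot be aligned to the covariance's taxon ordering."""
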