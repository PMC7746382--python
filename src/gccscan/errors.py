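"""Exception hierarchy shared across gccscan modules."""


class GccScanError(Exception):
    """Base class for all gccscan errors."""


class ParseError(GccScanError):
    """A file could not be parsed (names the offending line/cell)."""


class SchemaError(GccScanError):
    """A required column or field is missing."""


class IntegrityError(GccScanError):
    """Data violate a structural invariant (duplicate ids, inconsistent zygosity)."""


class DegenerateInputError(GccScanError):
    """Zero-variance or otherwise degenerate input to a density estimate."""


class SampleSizeError(GccScanError):
    """Too few observations for the requested operation."""


class ResolutionError(GccScanError):
    """Requested p-value or quantile is below permutation resolution."""


class StructureError(GccScanError):
    """Family/zygosity structure incompatible with the twin design."""


class MatrixError(GccScanError):
    """Covariance/kinship matrix fails symmetry or positive-semidefiniteness."""


class ConvergenceError(GccScanError):
    """An iterative fit failed to converge."""


class RankError(GccScanError):
    """Design matrix is rank deficient (collinear covariates)."""


class ConfigError(GccScanError):
    """Invalid configuration value."""


class MisuseError(GccScanError):
    """An operation was called outside its intended study design."""


class JoinError(GccScanError):
    """Sample ids of genotype and phenotype tables do not intersect."""
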