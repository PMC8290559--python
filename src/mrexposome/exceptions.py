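"""Exception hierarchy for the MR screening pipeline."""


class MRExposomeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRExposomeError):
    """Invalid run configuration: missing columns, bad thresholds, bad dialects."""


class EmptyInputError(MRExposomeError):
    """An input file or collection contained no usable rows."""


class DomainError(MRExposomeError, ValueError):
    """A numeric argument lies outside its mathematically valid domain."""


class InsufficientInstrumentsError(MRExposomeError):
    """Too few SNPs for the requested estimator."""


class CollinearityError(MRExposomeError):
    """Design matrix is rank deficient (e.g. all exposure betas equal)."""


class HarmonizationError(MRExposomeError):
    """No instruments survived exposure/outcome allele harmonization."""
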