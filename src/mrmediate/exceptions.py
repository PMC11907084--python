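"""Exception hierarchy shared across the package."""


class MRToolError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRToolError):
    """A setting, column mapping or option grid is invalid."""


class RowError(MRToolError):
    """A single summary-statistics row could not be parsed or violates an invariant."""


class EmptyInstrumentError(MRToolError):
    """No SNP survived instrument selection or exclusion filtering."""


class HarmonizationError(MRToolError):
    """Studies share no SNPs, or harmonisation produced an empty set."""


class EstimationError(MRToolError):
    """An estimator's preconditions are violated or it failed to converge."""


class UndefinedRatioError(EstimationError):
    """A Wald ratio or proportion with a zero denominator was requested."""
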