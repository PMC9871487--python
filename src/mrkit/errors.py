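"""Exception hierarchy for mrkit.

Every error raised by the package derives from :class:`MRKitError` so callers
can catch the whole family; pipeline code additionally distinguishes
configuration problems (bad inputs, unresolvable columns) from data problems
(row-level validation) and from estimator-level failures that should be
recorded per-cell rather than abort a study.
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """Invalid configuration: missing column, bad threshold, unknown SNP."""


class ValidationError(MRKitError):
    """A record violates a domain invariant (bad allele, se <= 0, ...)."""


class EmptyInputError(MRKitError):
    """An input table contained no data rows."""


class DomainError(MRKitError, ValueError):
    """An argument lies outside the mathematical domain of a formula."""


class DegenerateInstrumentError(MRKitError):
    """A SNP-exposure effect of exactly zero makes the Wald ratio undefined."""


class InsufficientInstrumentsError(MRKitError):
    """Fewer SNPs than the estimator's minimum."""


class CollinearityError(MRKitError):
    """A regression design with no spread in the predictor."""


class ConvergenceError(MRKitError):
    """An iterative solver failed to converge within its budget."""
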