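"""Exception types shared across the package."""


class CandgeneError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CandgeneError):
    """Input data violates a structural or allelic constraint."""


class MonomorphicLocusError(CandgeneError):
    """A statistic is undefined because the locus carries a single allele."""


class UndefinedStatisticError(CandgeneError):
    """A statistic cannot be computed (e.g. all calls missing at a locus)."""


class ConvergenceError(CandgeneError):
    """An iterative estimator failed in a way that cannot be reported as a flag."""
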