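"""Exception and warning types used across the package."""


class HetmrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HetmrError, ValueError):
    """A configuration value violates its documented constraint.

    The message always names the offending field.
    """


class EstimabilityError(HetmrError):
    """A required exposure-by-genotype cell is empty, naming the cell."""


class CollinearityError(HetmrError):
    """A design column is constant or linearly dependent, naming the column."""


class FitFailureError(HetmrError):
    """A regression fit failed (e.g. perfect separation, non-convergence)."""


class WeakInstrumentError(HetmrError):
    """The instrument-exposure association is too weak to form a ratio."""


class MonotonicityViolationError(HetmrError):
    """Defiers are present: some potential exposure is lower with the risk allele."""


class UndefinedEstimandError(HetmrError):
    """The requested estimand has an empty defining stratum (e.g. no compliers)."""


class WeakInstrumentWarning(UserWarning):
    """First-stage F statistic below the configured threshold."""


class GSAssociationWarning(UserWarning):
    """The moderator variant G is associated with the exposure S.

    Method 2 requires G to be independent of S; a detected association is
    reported but never silently enforced.
    """
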