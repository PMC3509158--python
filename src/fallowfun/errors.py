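"""Exception types shared across the pipeline stages."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class MissingTraitError(KeyError):
    """A surveyed species has no row in the trait table."""


class MissingDataError(ValueError):
    """A required measurement is absent (e.g. no usable subplot)."""


class InsufficientSampleError(ValueError):
    """Too few observations for the requested statistic."""


class UndefinedRatioError(ZeroDivisionError):
    """A ratio with a zero denominator (e.g. CP:lignin with lignin = 0)."""


class CollinearityError(ValueError):
    """Rank-deficient design matrix in a linear model."""


class ValidationError(ValueError):
    """Input tables violate the documented schema; message lists offenders."""
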