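"""Exception hierarchy.

Undefined statistics (zero-variance Pearson, zero-mean CV) are *signaled*
conditions, never silently coerced to a number.
"""


class PupalyzeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PupalyzeError, ValueError):
    """A configuration value violates its contract."""


class ValidationError(PupalyzeError, ValueError):
    """Input data violate a structural invariant (bad intervals, missing columns...)."""


class DataError(PupalyzeError, ValueError):
    """Numeric data are unusable (non-finite values...)."""


class InsufficientDataError(PupalyzeError, ValueError):
    """Not enough observations for the requested computation."""


class DegenerateBaselineError(PupalyzeError, ZeroDivisionError):
    """Normalization baseline (F0) is zero."""


class UndefinedStatisticError(PupalyzeError, ArithmeticError):
    """The requested statistic is mathematically undefined on this input
    (e.g. Pearson r of a constant indicator, CV of zero-mean values)."""


class DegenerateTrainingError(PupalyzeError, ValueError):
    """Classifier training is impossible (e.g. a single class present)."""
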