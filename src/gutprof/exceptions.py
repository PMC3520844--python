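"""Exception types shared across the pipeline."""


class GutprofError(Exception):
    """Base class for all package-specific errors."""


class UndefinedCorrelationError(GutprofError, ValueError):
    """Pearson correlation requested for a constant vector.

    Raised explicitly instead of letting NaN propagate through a
    distance matrix.
    """


class UndefinedRatioError(GutprofError, ZeroDivisionError):
    """Fold difference requested against a zero (below-detection) activity."""


class InconsistencyError(GutprofError, RuntimeError):
    """Internal bookkeeping mismatch, e.g. a cluster reference without an
    assignment record, or tree leaves that are not a subset of the samples."""
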