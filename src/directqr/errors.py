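"""Exception and warning types shared across the package."""


class DirectQRError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DirectQRError, ValueError):
    """Arguments outside an operation's domain (non-finite, wrong shape, bad tau...)."""


class DegenerateScaleError(DirectQRError, ValueError):
    """A data column has no spread, so a scale-based bandwidth rule is undefined."""


class DegenerateCovarianceError(DirectQRError, ValueError):
    """Sample covariance is singular; the whitened estimator cannot be formed.

    Callers should fall back to the product-kernel estimator.
    """


class DegenerateDesignError(DirectQRError, ValueError):
    """Design matrix is rank deficient; the quantile-regression LP is unbounded in some direction."""


class UnsupportedPointError(DirectQRError, ValueError):
    """Evaluation point has (numerically) zero marginal density; conditioning is undefined there."""


class GridCoverageError(DirectQRError, RuntimeError):
    """The inversion grid misses too much probability mass; widen the grid."""


class ExtrapolationError(DirectQRError, RuntimeError):
    """All kernel weights underflowed at an evaluation point."""


class InsufficientLocalDataError(DirectQRError, RuntimeError):
    """Fewer than two observations carry non-negligible kernel weight in a local fit."""


class SolverError(DirectQRError, RuntimeError):
    """The LP solver failed to return an optimal solution."""


class PerfectReferenceError(DirectQRError, ZeroDivisionError):
    """The reference fit interpolates every observation, so the relative index is undefined."""


class SchemaError(DirectQRError, ValueError):
    """An input table is missing a required column or holds non-numeric values."""


class InsufficientDataError(DirectQRError, ValueError):
    """Too few complete rows to estimate anything."""


class StudyAbortedError(DirectQRError, RuntimeError):
    """Too many Monte-Carlo replicates failed; results would be unreliable."""


class ExtrapolationWarning(UserWarning):
    """Emitted when an evaluation point falls outside kernel support and a fallback is used."""


class GridWidenedWarning(UserWarning):
    """Emitted when the inversion grid had to be widened automatically."""


class RelativeROutOfRangeWarning(UserWarning):
    """Emitted when the relative goodness-of-fit index falls outside [-1, 1]."""
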