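"""Direct nonparametric quantile regression.

The estimator works in five steps:

1. estimate the conditional density f(y|x) as the ratio of a kernel joint
   density estimate to a kernel marginal estimate;
2. integrate it to a conditional CDF on a y-grid;
3. invert the CDF at each sample covariate point x_i, giving n local
   conditional quantiles xi_i(tau | x_i);
4. smooth the n points (x_i, xi_i) with a Nadaraya-Watson weighted average,
   yielding the quantile curve Q_D(tau | x);
5. run diagnostics (coverage, crossing, grid width).

Because the smoothing weights are nonnegative and sum to one, and the local
quantiles are monotone in tau by construction, the resulting curves for
different tau never cross.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateCovarianceError,
    DegenerateScaleError,
    ExtrapolationError,
    ExtrapolationWarning,
    GridCoverageError,
    GridWidenedWarning,
    InvalidInputError,
    UnsupportedPointError,
)
from .kernels import (
    BandwidthSpec,
    normal_reference_bandwidth,
    per_dimension_bandwidth,
)

__all__ = [
    "RegressionSample",
    "GridPolicy",
    "LocalQuantileSet",
    "QuantileCurve",
    "DiagnosticReport",
    "conditional_density",
    "conditional_cdf",
    "local_quantile",
    "compute_local_quantiles",
    "nw_weights",
    "direct_quantile_curve",
    "direct_quantile_curves",
    "diagnose",
]

_DENSITY_FLOOR = 1e-300
_LOG_UNDERFLOW = -690.0  # log of smallest normal double, with margin


@dataclass(frozen=True)
class RegressionSample:
    """A response vector y and covariate matrix X (n rows, d columns)."""

    y: np.ndarray
    X: np.ndarray
    column_names: tuple | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).ravel()
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise InvalidInputError("X must be an (n, d) matrix")
        if y.size != X.shape[0]:
            raise InvalidInputError("y and X must have the same number of rows")
        if y.size < 5:
            raise InvalidInputError("need at least 5 observations")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
            raise InvalidInputError("all entries must be finite")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class GridPolicy:
    """How the y-grid for CDF inversion is built and widened.

    The grid spans [min(y) - lower_mult * h_y, max(y) + upper_mult * h_y];
    extra right-tail headroom because the targets are high quantiles.  If the
    raw CDF mass on the grid falls below ``min_coverage`` the margins are
    doubled, up to ``max_widenings`` times.
    """

    n_nodes: int = 1024
    lower_mult: float = 4.0
    upper_mult: float = 8.0
    min_coverage: float = 0.95
    max_widenings: int = 5

    def build(self, y: np.ndarray, h_y: float,
              widenings: int = 0) -> np.ndarray:
        factor = 2.0 ** widenings
        lo = float(np.min(y)) - self.lower_mult * h_y * factor
        hi = float(np.max(y)) + self.upper_mult * h_y * factor
        return np.linspace(lo, hi, self.n_nodes)


@dataclass(frozen=True)
class LocalQuantileSet:
    """The n local quantiles (x_i, xi_i(tau|x_i)) from the CDF-inversion step."""

    tau: float
    X: np.ndarray
    xi: np.ndarray
    bandwidths: BandwidthSpec
    grid_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise InvalidInputError("tau must lie in (0, 1)")
        xi = np.asarray(self.xi, dtype=float)
        if xi.shape[0] != np.asarray(self.X).shape[0]:
            raise InvalidInputError("one local quantile per sample row required")
        if not np.all(np.isfinite(xi)):
            raise InvalidInputError("local quantiles must be finite")


@dataclass(frozen=True)
class QuantileCurve:
    """A conditional quantile function evaluated on a covariate grid."""

    tau: float
    x_eval: np.ndarray
    q_values: np.ndarray
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x_eval, dtype=float)
        q = np.asarray(self.q_values, dtype=float).ravel()
        if x.ndim == 1:
            x = x[:, None]
        if q.size != x.shape[0]:
            raise InvalidInputError("q_values must match x_eval length")
        if not np.all(np.isfinite(q)):
            raise InvalidInputError("quantile values must be finite")
        object.__setattr__(self, "x_eval", x)
        object.__setattr__(self, "q_values", q)


# ---------------------------------------------------------------------------
# density machinery


def _resolve_density_bandwidth(bw: BandwidthSpec | None, n: int, dim: int) -> float:
    """Scalar bandwidth for a `dim`-dimensional whitened density estimate."""
    if bw is None or bw.rule == "normal_reference_multivariate":
        return normal_reference_bandwidth(n, dim)
    if bw.rule == "user_fixed":
        vals = np.asarray(bw.values)
        if vals.size != 1:
            raise InvalidInputError("whitened estimator takes a scalar bandwidth")
        return float(vals[0])
    raise InvalidInputError(
        f"bandwidth rule {bw.rule!r} not applicable to the whitened density stage"
    )


class _WhitenedKDE:
    """Equal-weight Gaussian mixture in whitened coordinates, reusable across grids."""

    kind = "whitened"

    def __init__(self, data: np.ndarray, h: float):
        self.h = float(h)
        data = np.atleast_2d(np.asarray(data, dtype=float))
        n, p = data.shape
        if n <= p:
            raise DegenerateCovarianceError("need n > dim for the whitened estimator")
        S = np.atleast_2d(np.cov(data, rowvar=False, ddof=1))
        if not np.all(np.isfinite(S)) or np.linalg.cond(S) > 1e12:
            raise DegenerateCovarianceError("near-singular sample covariance")
        try:
            L = cholesky(S, lower=True)
        except Exception as exc:
            raise DegenerateCovarianceError("singular sample covariance") from exc
        Linv = solve_triangular(L, np.eye(p), lower=True)
        self.transform = Linv / h
        self.log_norm = (float(np.sum(np.log(np.diag(Linv)))) - p * np.log(h)
                         - (p / 2.0) * np.log(2.0 * np.pi) - np.log(n))
        self.scaled_data = data @ self.transform.T
        self.h_per_dim = h * np.sqrt(np.diag(S))

    def __call__(self, pts: np.ndarray, chunk: int = 16384) -> np.ndarray:
        scaled = np.atleast_2d(pts) @ self.transform.T
        out = np.empty(scaled.shape[0])
        norm = np.exp(self.log_norm)
        for s in range(0, scaled.shape[0], chunk):
            d2 = cdist(scaled[s:s + chunk], self.scaled_data, metric="sqeuclidean")
            out[s:s + chunk] = norm * np.sum(np.exp(-0.5 * d2), axis=1)
        return out


class _ProductKDE:
    """Product-kernel mixture with per-dimension bandwidths (whitened fallback)."""

    kind = "product"

    def __init__(self, data: np.ndarray, h: np.ndarray):
        data = np.atleast_2d(np.asarray(data, dtype=float))
        n, p = data.shape
        h = np.atleast_1d(np.asarray(h, dtype=float))
        if h.size == 1:
            h = np.full(p, float(h[0]))
        self.transform = np.diag(1.0 / h)
        self.log_norm = (-float(np.sum(np.log(h)))
                         - (p / 2.0) * np.log(2.0 * np.pi) - np.log(n))
        self.scaled_data = data @ self.transform.T
        self.h_per_dim = h

    __call__ = _WhitenedKDE.__call__


def _per_dim_bandwidths_with_fallback(Z: np.ndarray) -> np.ndarray:
    """Per-column plug-in bandwidths; constant columns get bandwidth 1 (any
    positive value gives identical kernel weights there)."""
    n = Z.shape[0]
    hs = []
    for j in range(Z.shape[1]):
        try:
            hs.append(per_dimension_bandwidth(Z[:, j], n))
        except DegenerateScaleError:
            hs.append(1.0)
    return np.asarray(hs)


def _build_kde(data: np.ndarray, bw: BandwidthSpec | None, estimator: str):
    """Joint/marginal KDE factory honouring the estimator choice with fallback."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, p = data.shape
    if estimator == "whitened":
        try:
            return _WhitenedKDE(data, _resolve_density_bandwidth(bw, n, p))
        except DegenerateCovarianceError:
            estimator = "product"
    if estimator == "product":
        if bw is not None and bw.rule == "user_fixed":
            h = bw.per_dim(p)
        else:
            h = _per_dim_bandwidths_with_fallback(data)
        return _ProductKDE(data, h)
    raise InvalidInputError(f"unknown density estimator {estimator!r}")


def _coverage_marginal(joint_kde, X: np.ndarray):
    """The covariate marginal of the *joint* estimator.

    Integrating the joint kernel estimate over y marginalizes each Gaussian
    component, which for the whitened kernel equals the whitened KDE of X at
    the same scalar h (the covariance submatrix of S is cov(X)), and for the
    product kernel the product KDE of X with the joint's x-bandwidths.  This
    is the correct normalizer when checking how much conditional mass the
    y-grid captures.
    """
    if joint_kde.kind == "whitened":
        try:
            return _WhitenedKDE(X, joint_kde.h)
        except DegenerateCovarianceError:
            return _ProductKDE(X, joint_kde.h_per_dim[1:])
    return _ProductKDE(X, joint_kde.h_per_dim[1:])


def conditional_density(sample: RegressionSample, x0, y_grid,
                        bw: BandwidthSpec | None = None,
                        estimator: str = "whitened") -> np.ndarray:
    """Conditional density f(y|x0) on ``y_grid`` as joint KDE / marginal KDE."""
    y_grid = np.asarray(y_grid, dtype=float)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.size != sample.d:
        raise InvalidInputError(
            f"x0 has dimension {x0.size}, expected {sample.d}"
        )
    if y_grid.ndim != 1 or np.any(np.diff(y_grid) <= 0):
        raise InvalidInputError("y_grid must be strictly increasing 1-d")
    Z = np.column_stack([sample.y, sample.X])
    joint = _build_kde(Z, bw, estimator)
    marg = _build_kde(sample.X, bw, estimator)
    g0 = float(marg(x0[None, :])[0])
    if g0 < _DENSITY_FLOOR:
        raise UnsupportedPointError(
            f"marginal density underflow at x0={x0}; point outside kernel support"
        )
    pts = np.column_stack([y_grid, np.broadcast_to(x0, (y_grid.size, sample.d))])
    return joint(pts) / g0


def conditional_cdf(sample: RegressionSample, x0, y_grid,
                    bw: BandwidthSpec | None = None,
                    estimator: str = "whitened",
                    min_coverage: float = 0.95,
                    return_raw_total: bool = False):
    """Conditional CDF of y given x0 on ``y_grid``.

    The running trapezoid integral of :func:`conditional_density` is
    renormalized by its final value so the inversion step is well defined up
    to tau -> 1.  If the raw mass on the grid is below ``min_coverage`` the
    grid is too narrow and a :class:`GridCoverageError` is raised.
    """
    dens = conditional_density(sample, x0, y_grid, bw=bw, estimator=estimator)
    raw = cumulative_trapezoid(dens, np.asarray(y_grid, dtype=float), initial=0.0)
    # coverage is judged against the joint estimator's own covariate marginal,
    # so it measures grid width only (not the joint/marginal bandwidth mismatch)
    Z = np.column_stack([sample.y, sample.X])
    joint = _build_kde(Z, bw, estimator)
    marg_cov = _coverage_marginal(joint, sample.X)
    x0v = np.atleast_1d(np.asarray(x0, dtype=float))
    g_rule = _build_kde(sample.X, bw, estimator)(x0v[None, :])[0]
    total = float(raw[-1] * g_rule / marg_cov(x0v[None, :])[0])
    if total < min_coverage:
        raise GridCoverageError(
            f"grid captures only {total:.3f} of conditional mass at x0; widen it"
        )
    cdf = np.clip(raw / total, 0.0, 1.0)
    cdf = np.maximum.accumulate(cdf)
    if return_raw_total:
        return cdf, total
    return cdf


def _invert_cdf(y_grid: np.ndarray, cdf: np.ndarray, tau: float) -> float:
    """Smallest grid-interpolated y with F(y) >= tau (monotone interpolation)."""
    if not (0.0 < tau < 1.0):
        raise InvalidInputError("tau must lie in (0, 1)")
    k = int(np.searchsorted(cdf, tau, side="left"))
    if k <= 0:
        return float(y_grid[0])
    if k >= cdf.size:
        return float(y_grid[-1])
    f0, f1 = cdf[k - 1], cdf[k]
    if f1 <= f0:
        return float(y_grid[k])
    w = (tau - f0) / (f1 - f0)
    return float(y_grid[k - 1] + w * (y_grid[k] - y_grid[k - 1]))


def _conditional_cdf_matrix(sample: RegressionSample,
                            bw: BandwidthSpec | None,
                            grid_policy: GridPolicy,
                            estimator: str):
    """Conditional CDF at every sample row on a shared y-grid.

    Returns (y_grid, F) where F[i, :] is the renormalized conditional CDF of
    y given x_i.  The marginal density cancels in the per-row normalization,
    but it is still evaluated to validate grid coverage.
    """
    Z = np.column_stack([sample.y, sample.X])
    joint = _build_kde(Z, bw, estimator)
    marg_cov = _coverage_marginal(joint, sample.X)
    g = marg_cov(sample.X)
    if np.min(g) < _DENSITY_FLOOR:
        i = int(np.argmin(g))
        raise UnsupportedPointError(f"marginal density underflow at row {i}")
    h_y = float(joint.h_per_dim[0])
    widenings = 0
    while True:
        y_grid = grid_policy.build(sample.y, h_y, widenings)
        pts = np.column_stack([
            np.repeat(y_grid[None, :], sample.n, axis=0).ravel(),
            np.repeat(sample.X, y_grid.size, axis=0),
        ])
        dens = joint(pts).reshape(sample.n, y_grid.size)
        raw = cumulative_trapezoid(dens, y_grid, axis=1, initial=0.0)
        totals = raw[:, -1] / g
        if float(np.min(totals)) >= grid_policy.min_coverage:
            break
        widenings += 1
        if widenings > grid_policy.max_widenings:
            raise GridCoverageError(
                "conditional mass still below the coverage floor after "
                f"{grid_policy.max_widenings} grid widenings"
            )
        warnings.warn("inversion grid widened to capture tail mass",
                      GridWidenedWarning, stacklevel=3)
    denom = raw[:, -1][:, None]
    F = np.maximum.accumulate(np.clip(raw / denom, 0.0, 1.0), axis=1)
    meta = {"y_min": float(y_grid[0]), "y_max": float(y_grid[-1]),
            "n_nodes": y_grid.size, "widenings": widenings,
            "h_y": h_y}
    return y_grid, F, meta


def compute_local_quantiles(sample: RegressionSample, taus,
                            bw: BandwidthSpec | None = None,
                            grid_policy: GridPolicy | None = None,
                            estimator: str = "whitened") -> dict:
    """Local conditional quantiles xi_i(tau|x_i) for every sample row and tau.

    The conditional CDF at each row is computed once and inverted at every
    tau, so multi-tau fits share all kernel work.
    """
    taus = [float(t) for t in np.atleast_1d(taus)]
    for t in taus:
        if not (0.0 < t < 1.0):
            raise InvalidInputError("all tau values must lie in (0, 1)")
    policy = grid_policy or GridPolicy()
    y_grid, F, meta = _conditional_cdf_matrix(sample, bw, policy, estimator)
    used_bw = bw if bw is not None else BandwidthSpec.normal_reference(
        sample.n, sample.d + 1)
    out = {}
    for tau in taus:
        xi = np.array([_invert_cdf(y_grid, F[i], tau) for i in range(sample.n)])
        out[tau] = LocalQuantileSet(tau=tau, X=sample.X, xi=xi,
                                    bandwidths=used_bw, grid_meta=dict(meta))
    return out


def local_quantile(sample: RegressionSample, row_index: int, tau: float,
                   bw: BandwidthSpec | None = None,
                   grid_policy: GridPolicy | None = None,
                   estimator: str = "whitened") -> float:
    """xi_i(tau | x_i): invert the conditional CDF at one sample row."""
    if not (0.0 < float(tau) < 1.0):
        raise InvalidInputError("tau must lie in (0, 1)")
    if not (0 <= int(row_index) < sample.n):
        raise InvalidInputError(f"row_index {row_index} out of range")
    lqs = compute_local_quantiles(sample, [tau], bw=bw,
                                  grid_policy=grid_policy, estimator=estimator)
    return float(lqs[float(tau)].xi[int(row_index)])


# ---------------------------------------------------------------------------
# Nadaraya-Watson smoothing


def _log_kernel_matrix(x_eval: np.ndarray, X: np.ndarray,
                       h: np.ndarray) -> np.ndarray:
    """log of the (unnormalized) product-Gaussian kernel, shape (n_eval, n)."""
    scaled_eval = x_eval / h
    scaled_data = X / h
    return -0.5 * cdist(scaled_eval, scaled_data, metric="sqeuclidean")


def nw_weights(x0, X, bw: BandwidthSpec) -> np.ndarray:
    """Equivalent-kernel weights W(x0, X_i): nonnegative, summing to one."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == 1 and np.asarray(x0).ndim == 0:
        x0 = [x0]
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.size != X.shape[1]:
        raise InvalidInputError("x0 dimension does not match X")
    h = bw.per_dim(X.shape[1])
    logk = _log_kernel_matrix(x0[None, :], X, h)[0]
    m = float(np.max(logk))
    if m < _LOG_UNDERFLOW:
        raise ExtrapolationError(
            "all kernel weights underflow at x0; evaluation point is far "
            "outside the data"
        )
    w = np.exp(logk - m)
    return w / np.sum(w)


def _smooth(local_sets: dict, x_eval: np.ndarray, bw_smooth: BandwidthSpec):
    """NW-smooth each LocalQuantileSet onto x_eval, with nearest-point fallback."""
    some = next(iter(local_sets.values()))
    X = np.atleast_2d(some.X)
    x_eval = np.asarray(x_eval, dtype=float)
    if x_eval.ndim == 1:
        x_eval = x_eval[:, None]
    h = bw_smooth.per_dim(X.shape[1])
    logk = _log_kernel_matrix(x_eval, X, h)
    row_max = np.max(logk, axis=1)
    ok = row_max >= _LOG_UNDERFLOW
    W = np.zeros_like(logk)
    W[ok] = np.exp(logk[ok] - row_max[ok][:, None])
    W[ok] /= np.sum(W[ok], axis=1, keepdims=True)
    nearest = None
    if not np.all(ok):
        warnings.warn(
            f"{int(np.sum(~ok))} evaluation points lie outside kernel support; "
            "using the nearest data point's local quantile",
            ExtrapolationWarning, stacklevel=3)
        d2 = cdist(x_eval[~ok] / h, X / h, metric="sqeuclidean")
        nearest = np.argmin(d2, axis=1)
    curves = {}
    for tau, lqs in local_sets.items():
        q = W @ lqs.xi
        if nearest is not None:
            q[~ok] = lqs.xi[nearest]
        curves[tau] = (x_eval, q)
    return curves


def direct_quantile_curves(sample: RegressionSample, taus, x_eval,
                           bw_density: BandwidthSpec | None = None,
                           bw_smooth: BandwidthSpec | None = None,
                           grid_policy: GridPolicy | None = None,
                           estimator: str = "whitened") -> list:
    """Direct quantile curves for several tau, sharing the kernel-CDF work."""
    local_sets = compute_local_quantiles(sample, taus, bw=bw_density,
                                         grid_policy=grid_policy,
                                         estimator=estimator)
    if bw_smooth is None:
        try:
            bw_smooth = BandwidthSpec.per_dimension(sample.X)
        except DegenerateScaleError:
            bw_smooth = BandwidthSpec.fixed(np.ones(sample.d), sample.n)
    smoothed = _smooth(local_sets, x_eval, bw_smooth)
    curves = []
    for tau in sorted(smoothed):
        xg, q = smoothed[tau]
        prov = {
            "bw_density": local_sets[tau].bandwidths,
            "bw_smooth": bw_smooth,
            "grid_meta": local_sets[tau].grid_meta,
            "estimator": estimator,
        }
        curves.append(QuantileCurve(tau=tau, x_eval=xg, q_values=q,
                                    method="direct", provenance=prov))
    return curves


def direct_quantile_curve(sample: RegressionSample, tau: float, x_eval,
                          bw_density: BandwidthSpec | None = None,
                          bw_smooth: BandwidthSpec | None = None,
                          grid_policy: GridPolicy | None = None,
                          estimator: str = "whitened") -> QuantileCurve:
    """Direct quantile curve Q_D(tau | x) on an evaluation grid."""
    return direct_quantile_curves(sample, [tau], x_eval,
                                  bw_density=bw_density, bw_smooth=bw_smooth,
                                  grid_policy=grid_policy,
                                  estimator=estimator)[0]


# ---------------------------------------------------------------------------
# diagnostics


@dataclass(frozen=True)
class DiagnosticReport:
    """Read-only summary of crossing, coverage and grid-width checks."""

    crossings: tuple
    coverage: dict
    notes: tuple

    @property
    def ok(self) -> bool:
        return not self.crossings


def _curve_at(curve: QuantileCurve, X: np.ndarray) -> np.ndarray | None:
    x_eval = curve.x_eval
    if x_eval.shape == X.shape and np.allclose(x_eval, X):
        return curve.q_values
    if X.shape[1] == 1 and x_eval.shape[1] == 1:
        order = np.argsort(x_eval[:, 0])
        return np.interp(X[:, 0], x_eval[order, 0], curve.q_values[order])
    return None


def diagnose(curves, sample: RegressionSample,
             crossing_tol: float = 1e-9) -> DiagnosticReport:
    """Check a set of fitted curves for tau-crossings and empirical coverage."""
    curves = list(curves)
    if not curves:
        raise InvalidInputError("need at least one curve to diagnose")
    curves.sort(key=lambda c: c.tau)
    crossings = []
    for lo, hi in zip(curves, curves[1:]):
        if lo.tau == hi.tau or lo.x_eval.shape != hi.x_eval.shape:
            continue
        viol = int(np.sum(lo.q_values > hi.q_values + crossing_tol))
        if viol:
            crossings.append((lo.tau, hi.tau, viol))
    coverage = {}
    notes = []
    for c in curves:
        fitted = _curve_at(c, sample.X)
        if fitted is None:
            notes.append(f"coverage skipped for tau={c.tau}: incompatible grid")
            continue
        coverage[(c.tau, c.method)] = float(np.mean(sample.y <= fitted))
    for c in curves:
        meta = c.provenance.get("grid_meta") if c.provenance else None
        if meta and meta.get("widenings", 0) > 0:
            notes.append(f"tau={c.tau}: inversion grid widened "
                         f"{meta['widenings']} time(s)")
    return DiagnosticReport(crossings=tuple(crossings), coverage=coverage,
                            notes=tuple(notes))
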