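"""Linear and local-polynomial quantile-regression baselines.

Both estimators minimize the asymmetric check loss

    rho_tau(u) = u * (tau - 1{u < 0})

via its linear-programming form: split each residual into positive and
negative parts u_i, v_i >= 0 with X beta + u - v = y and minimize
tau * 1'u + (1 - tau) * 1'v.  The local-polynomial variant weights each
row's loss contribution by a Gaussian kernel centred at the evaluation
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .direct_qr import QuantileCurve, RegressionSample
from .errors import (
    DegenerateDesignError,
    InsufficientLocalDataError,
    InvalidInputError,
    SolverError,
)
from .kernels import KernelSpec, per_dimension_bandwidth

__all__ = [
    "LinearQRFit",
    "LPQRFit",
    "check_loss",
    "fit_linear_qr",
    "predict_linear_qr",
    "fit_lpqr",
    "lpqr_curve",
    "default_lpqr_bandwidth",
]

_WEIGHT_FLOOR = 1e-10  # relative kernel-weight cutoff for the local LP


def check_loss(u, tau: float):
    """Check (pinball) loss rho_tau(u); vectorized over u."""
    tau = float(tau)
    if not (0.0 < tau < 1.0):
        raise InvalidInputError("tau must lie in (0, 1)")
    u = np.asarray(u, dtype=float)
    out = np.where(u >= 0.0, u * tau, u * (tau - 1.0))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LinearQRFit:
    """Coefficients of a linear quantile-regression fit (intercept first)."""

    tau: float
    beta: np.ndarray
    objective: float
    n_interpolated: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float).ravel())


@dataclass(frozen=True)
class LPQRFit:
    """Local linear quantile fit at one evaluation point x0.

    a0 is the fitted conditional quantile at x0; a1 the local slope.
    """

    tau: float
    x0: float
    a0: float
    a1: float
    bandwidth: float
    kernel: KernelSpec = field(default=KernelSpec("gaussian", 1))


def _solve_check_loss_lp(Xp: np.ndarray, y: np.ndarray, tau: float,
                         weights: np.ndarray | None = None) -> np.ndarray:
    """Minimize sum_i w_i * rho_tau(y_i - Xp_i' beta) via the split-residual LP."""
    n, p = Xp.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    c = np.concatenate([np.zeros(p), tau * w, (1.0 - tau) * w])
    A_eq = np.hstack([Xp, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"LP solver failed: {res.status} {res.message}")
    return res.x[:p]


def fit_linear_qr(sample: RegressionSample, tau: float) -> LinearQRFit:
    """Linear quantile regression by check-loss minimization (LP form)."""
    tau = float(tau)
    if not (0.0 < tau < 1.0):
        raise InvalidInputError("tau must lie in (0, 1)")
    Xp = np.column_stack([np.ones(sample.n), sample.X])
    if np.linalg.matrix_rank(Xp) < Xp.shape[1]:
        raise DegenerateDesignError("design matrix [1 X] is rank deficient")
    beta = _solve_check_loss_lp(Xp, sample.y, tau)
    resid = sample.y - Xp @ beta
    objective = float(np.sum(check_loss(resid, tau)))
    scale = max(1.0, float(np.max(np.abs(sample.y))))
    n_interp = int(np.sum(np.abs(resid) <= 1e-9 * scale))
    return LinearQRFit(tau=tau, beta=beta, objective=objective,
                       n_interpolated=n_interp)


def predict_linear_qr(fit: LinearQRFit, x_eval) -> QuantileCurve:
    """Evaluate the fitted line/plane on a covariate grid."""
    x = np.asarray(x_eval, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != fit.beta.size - 1:
        raise InvalidInputError(
            f"grid dimension {x.shape[1]} does not match fit with "
            f"{fit.beta.size - 1} covariate(s)"
        )
    q = fit.beta[0] + x @ fit.beta[1:]
    return QuantileCurve(tau=fit.tau, x_eval=x, q_values=q, method="linear",
                         provenance={"beta": tuple(fit.beta),
                                     "objective": fit.objective})


def default_lpqr_bandwidth(x, scale: float = 4.0) -> float:
    """Default local-fit bandwidth: ``scale`` times the per-dimension plug-in.

    Local check-loss fits need wider windows than density estimates; the
    factor is configurable and recorded in provenance.
    """
    return scale * per_dimension_bandwidth(np.asarray(x, dtype=float).ravel())


def fit_lpqr(sample: RegressionSample, tau: float, x0: float,
             h: float) -> LPQRFit:
    """First-order local-polynomial quantile fit at x0 (d = 1 only).

    Minimizes sum_i rho_tau(y_i - a0 - a1 (x_i - x0)) K((x0 - x_i)/h).
    Rows whose kernel weight is below 1e-10 of the maximum are dropped from
    the LP; they cannot change the optimum at double precision.
    """
    tau = float(tau)
    if not (0.0 < tau < 1.0):
        raise InvalidInputError("tau must lie in (0, 1)")
    if sample.d != 1:
        raise InvalidInputError("local-polynomial fit is implemented for d=1 only")
    if not (np.isfinite(h) and h > 0):
        raise InvalidInputError("bandwidth must be positive and finite")
    x = sample.X[:, 0]
    logw = -0.5 * ((float(x0) - x) / float(h)) ** 2
    m = float(np.max(logw))
    if m < -690.0:
        raise InsufficientLocalDataError(
            f"no observations within kernel support of x0={x0}"
        )
    w = np.exp(logw - m)
    keep = w > _WEIGHT_FLOOR
    if int(np.sum(keep)) < 2:
        raise InsufficientLocalDataError(
            f"fewer than 2 observations carry weight at x0={x0}"
        )
    Xp = np.column_stack([np.ones(int(np.sum(keep))), x[keep] - float(x0)])
    coef = _solve_check_loss_lp(Xp, sample.y[keep], tau, weights=w[keep])
    return LPQRFit(tau=tau, x0=float(x0), a0=float(coef[0]), a1=float(coef[1]),
                   bandwidth=float(h))


def lpqr_curve(sample: RegressionSample, tau: float, x_eval,
               h: float | None = None,
               bandwidth_scale: float = 4.0) -> QuantileCurve:
    """Local-polynomial quantile curve on a grid.

    Evaluation points outside the observed covariate range are clamped to the
    nearest data boundary before fitting (constant extension beyond the data
    hull): a local line fitted from one-sided, distant observations is an
    extrapolation with unbounded variance, and high-quantile grids routinely
    extend past the largest covariate draw.  Points where even the clamped
    fit is infeasible reuse the nearest feasible fit's intercept.
    """
    if sample.d != 1:
        raise InvalidInputError("local-polynomial fit is implemented for d=1 only")
    if h is None:
        h = default_lpqr_bandwidth(sample.X[:, 0], scale=bandwidth_scale)
    grid = np.asarray(x_eval, dtype=float).ravel()
    x = sample.X[:, 0]
    lo, hi = float(x.min()), float(x.max())
    clamped = np.clip(grid, lo, hi)
    n_clamped = int(np.sum(clamped != grid))
    fits: dict[int, LPQRFit] = {}
    failed = []
    cache: dict[float, LPQRFit] = {}
    for i, x0 in enumerate(clamped):
        x0 = float(x0)
        try:
            if x0 not in cache:
                cache[x0] = fit_lpqr(sample, tau, x0, h)
            fits[i] = cache[x0]
        except InsufficientLocalDataError:
            failed.append(i)
    if not fits:
        raise InsufficientLocalDataError("local fit failed at every grid point")
    q = np.empty(grid.size)
    for i, f in fits.items():
        q[i] = f.a0
    if failed:
        ok_idx = np.array(sorted(fits))
        for i in failed:
            k = int(ok_idx[np.argmin(np.abs(clamped[ok_idx] - clamped[i]))])
            q[i] = fits[k].a0
    return QuantileCurve(tau=float(tau), x_eval=grid, q_values=q, method="lpqr",
                         provenance={"bandwidth": float(h),
                                     "n_fallback": len(failed),
                                     "n_clamped": n_clamped})
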