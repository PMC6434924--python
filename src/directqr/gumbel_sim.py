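"""Gumbel's second kind of bivariate exponential distribution.

Closed forms:

    F(x, y) = (1 - e^-x)(1 - e^-y)(1 + a * e^-(x+y))
    f(x, y) = e^-(x+y) * (1 + a (2e^-x - 1)(2e^-y - 1))
    F(y|x)  = e^-y * (a (2e^-x - 1)(1 - e^-y) - 1) + 1

Both marginals are unit exponential.  Writing c = 2e^-x - 1 and t = e^-y,
F(y|x) = tau is the quadratic a*c*t^2 - (a*c - 1)*t - (1 - tau) = 0 whose
relevant root, in a cancellation-free form valid for all a*c in [-1, 1]
(including the removable singularity at c = 0, i.e. x = ln 2), is

    t = 2 (1 - tau) / (sqrt((a*c + 1)^2 - 4*a*c*tau) + 1 - a*c),

giving the conditional quantile xi(tau|x) = -ln t.  Sampling uses x ~ Exp(1)
and inverse-transform of F(y|x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "GumbelParams",
    "joint_cdf",
    "joint_pdf",
    "conditional_pdf_y_given_x",
    "conditional_cdf_y_given_x",
    "true_conditional_quantile",
    "sample_pairs",
]


@dataclass(frozen=True)
class GumbelParams:
    """Dependence parameter and sampling seed.

    A valid (nonnegative) density requires |alpha| <= 1; values outside
    [-1, 1] are rejected at construction.
    """

    alpha: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        a = float(self.alpha)
        if not np.isfinite(a) or abs(a) > 1.0:
            raise InvalidInputError(
                f"alpha={self.alpha} outside [-1, 1]; density would go negative"
            )
        object.__setattr__(self, "alpha", a)


def _check_nonneg(*arrays) -> list:
    out = []
    for arr in arrays:
        a = np.asarray(arr, dtype=float)
        if not np.all(np.isfinite(a) | np.isposinf(a)):
            raise InvalidInputError("arguments must not be NaN or -inf")
        if np.any(a < 0.0):
            raise InvalidInputError("arguments must be nonnegative")
        out.append(a)
    return out


def _maybe_scalar(x):
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


def joint_cdf(x, y, params: GumbelParams):
    """F(x, y) = (1 - e^-x)(1 - e^-y)(1 + alpha e^-(x+y))."""
    x, y = _check_nonneg(x, y)
    ex, ey = np.exp(-x), np.exp(-y)
    return _maybe_scalar((1.0 - ex) * (1.0 - ey) * (1.0 + params.alpha * ex * ey))


def joint_pdf(x, y, params: GumbelParams):
    """f(x, y) = e^-(x+y) (1 + alpha (2e^-x - 1)(2e^-y - 1))."""
    x, y = _check_nonneg(x, y)
    ex, ey = np.exp(-x), np.exp(-y)
    return _maybe_scalar(
        ex * ey * (1.0 + params.alpha * (2.0 * ex - 1.0) * (2.0 * ey - 1.0)))


def conditional_pdf_y_given_x(y, x, params: GumbelParams):
    """f(y|x) = e^-y (1 + alpha (2e^-x - 1)(2e^-y - 1)); x-marginal is Exp(1)."""
    x, y = _check_nonneg(x, y)
    ex, ey = np.exp(-x), np.exp(-y)
    return _maybe_scalar(
        ey * (1.0 + params.alpha * (2.0 * ex - 1.0) * (2.0 * ey - 1.0)))


def conditional_cdf_y_given_x(y, x, params: GumbelParams):
    """F(y|x) = e^-y (alpha (2e^-x - 1)(1 - e^-y) - 1) + 1."""
    x, y = _check_nonneg(x, y)
    ex, ey = np.exp(-x), np.exp(-y)
    return _maybe_scalar(
        ey * (params.alpha * (2.0 * ex - 1.0) * (1.0 - ey) - 1.0) + 1.0)


def true_conditional_quantile(tau, x, params: GumbelParams):
    """xi(tau|x): exact inverse of F(.|x), stable for tau -> 1 and x near ln 2."""
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0.0) or np.any(tau_arr >= 1.0):
        raise InvalidInputError("tau must lie in (0, 1)")
    (x_arr,) = _check_nonneg(x)
    a = params.alpha * (2.0 * np.exp(-x_arr) - 1.0)
    # discriminant (a+1)^2 - 4*a*tau rewritten to avoid cancellation for a ~ 1
    disc = (a - 1.0) ** 2 + 4.0 * a * (1.0 - tau_arr)
    t = 2.0 * (1.0 - tau_arr) / (np.sqrt(disc) + 1.0 - a)
    return _maybe_scalar(-np.log(t))


def sample_pairs(n: int, params: GumbelParams,
                 rng: np.random.Generator | None = None) -> tuple:
    """Draw n pairs: x ~ Exp(1), then y by inverse-transform of F(.|x).

    Returns (x, y) arrays.  Reproducible from ``params.seed`` unless an
    explicit generator is supplied.
    """
    if int(n) < 1:
        raise InvalidInputError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x = rng.exponential(size=int(n))
    u = rng.uniform(size=int(n))
    y = true_conditional_quantile(u, x, params)
    return x, np.asarray(y, dtype=float)
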