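"""Relative goodness-of-fit index comparing two fitted quantile curves.

For a fitted conditional quantile q_i at each observation, the weighted
absolute loss is

    V(tau) = (1/n) * [ sum_{y_i >= q_i} tau * |y_i - q_i|
                       + sum_{y_i < q_i} (1 - tau) * |y_i - q_i| ],

which equals the mean check loss of the residuals.  The relative index of a
"direct" fit against a "reference" fit is R(tau) = 1 - V_D / V_R; positive
values mean the direct fit tracks the data more closely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .direct_qr import RegressionSample
from .errors import (
    InvalidInputError,
    PerfectReferenceError,
    RelativeROutOfRangeWarning,
)

__all__ = ["GOFReport", "weighted_loss", "relative_R"]


@dataclass(frozen=True)
class GOFReport:
    """V_D, V_R and the relative index for one tau."""

    tau: float
    V_D: float
    V_R: float
    relative_R: float
    in_stated_range: bool


def weighted_loss(y, q_at_x, tau: float) -> float:
    """Mean tau-weighted absolute deviation of y from fitted quantiles q."""
    tau = float(tau)
    if not (0.0 < tau < 1.0):
        raise InvalidInputError("tau must lie in (0, 1)")
    y = np.asarray(y, dtype=float).ravel()
    q = np.asarray(q_at_x, dtype=float).ravel()
    if y.size != q.size or y.size < 1:
        raise InvalidInputError("y and fitted values must have equal nonzero length")
    dev = np.abs(y - q)
    # ties y_i == q_i sit on the tau-weighted branch; they contribute 0 anyway
    w = np.where(y >= q, tau, 1.0 - tau)
    return float(np.mean(w * dev))


def relative_R(sample, curve_D, curve_R, tau: float) -> GOFReport:
    """Relative index R(tau) = 1 - V_D/V_R of a direct fit vs a reference fit.

    ``sample`` may be a :class:`RegressionSample` or a bare response vector;
    ``curve_D``/``curve_R`` are fitted values at the sample covariates.
    Values outside the nominal [-1, 1] range are reported raw with a warning
    rather than clipped.
    """
    y = sample.y if isinstance(sample, RegressionSample) else np.asarray(
        sample, dtype=float).ravel()
    V_D = weighted_loss(y, curve_D, tau)
    V_R = weighted_loss(y, curve_R, tau)
    if V_R == 0.0:
        raise PerfectReferenceError(
            "reference fit interpolates every observation; R(tau) undefined"
        )
    R = 1.0 - V_D / V_R
    in_range = -1.0 <= R <= 1.0
    if not in_range:
        warnings.warn(
            f"relative R(tau)={R:.4f} outside the nominal [-1, 1] range",
            RelativeROutOfRangeWarning, stacklevel=2)
    return GOFReport(tau=float(tau), V_D=V_D, V_R=V_R, relative_R=R,
                     in_stated_range=in_range)
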