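"""Gaussian kernels, plug-in bandwidth rules and kernel density estimators.

The kernel is the standard multivariate normal density

    K(u) = (2*pi)**(-d/2) * exp(-u'u / 2)

shared by the density stage (joint and marginal estimates) and the
Nadaraya-Watson smoothing stage.  Two plug-in bandwidth rules are provided:

``normal_reference_multivariate``
    The scalar rule h = {4/(d+2)}**(1/(d+4)) * n**(-1/(d+4)), exact for a
    normal reference density with unit variance; intended for use with the
    covariance-whitened estimator where the data scale is absorbed by S.

``normal_reference_per_dim``
    The per-dimension rule h_j = (4/3)**(1/5) * sigma_j * n**(-1/5), the
    d=1 normal-reference rule applied marginally with a robust scale
    estimate sigma_j = min(sample sd, IQR/1.349).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateCovarianceError,
    DegenerateScaleError,
    InvalidInputError,
)

__all__ = [
    "KernelSpec",
    "BandwidthSpec",
    "gaussian_kernel",
    "normal_reference_bandwidth",
    "robust_scale",
    "per_dimension_bandwidth",
    "kde_marginal",
    "kde_whitened",
]

BANDWIDTH_RULES = (
    "normal_reference_multivariate",
    "normal_reference_per_dim",
    "user_fixed",
)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and dimensionality. Only the Gaussian kernel is supported."""

    name: str = "gaussian"
    dimension: int = 1

    def __post_init__(self) -> None:
        if self.name != "gaussian":
            raise InvalidInputError(f"unsupported kernel {self.name!r}; only 'gaussian'")
        if int(self.dimension) < 1:
            raise InvalidInputError("kernel dimension must be >= 1")


@dataclass(frozen=True)
class BandwidthSpec:
    """Bandwidth values plus the rule that produced them.

    ``values`` has length 1 (a scalar bandwidth h) or length d (per-dimension
    bandwidths h_j).  ``sample_size`` records the n the rule was applied to.
    """

    values: tuple
    rule: str
    sample_size: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise InvalidInputError("bandwidth values must be a 1-d sequence")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0.0):
            raise InvalidInputError("bandwidths must be strictly positive and finite")
        if self.rule not in BANDWIDTH_RULES:
            raise InvalidInputError(f"unknown bandwidth rule {self.rule!r}")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    @classmethod
    def normal_reference(cls, n: int, d: int) -> "BandwidthSpec":
        """Scalar normal-reference bandwidth for d-dimensional whitened data."""
        return cls((normal_reference_bandwidth(n, d),), "normal_reference_multivariate", n)

    @classmethod
    def per_dimension(cls, X: np.ndarray) -> "BandwidthSpec":
        """Per-dimension plug-in bandwidths, one per column of X."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        hs = tuple(per_dimension_bandwidth(X[:, j], n) for j in range(X.shape[1]))
        return cls(hs, "normal_reference_per_dim", n)

    @classmethod
    def fixed(cls, values, sample_size: int = 0) -> "BandwidthSpec":
        values = np.atleast_1d(np.asarray(values, dtype=float))
        return cls(tuple(values), "user_fixed", sample_size)

    def per_dim(self, d: int) -> np.ndarray:
        """Bandwidth vector of length d (a scalar h is broadcast)."""
        vals = np.asarray(self.values, dtype=float)
        if vals.size == d:
            return vals
        if vals.size == 1:
            return np.full(d, vals[0])
        raise InvalidInputError(
            f"bandwidth of length {vals.size} incompatible with dimension {d}"
        )


def gaussian_kernel(u) -> np.ndarray | float:
    """Standard normal kernel K(u) = (2*pi)**(-d/2) exp(-u'u/2).

    ``u`` is a vector of length d, or an array whose last axis is the
    dimension (evaluated pointwise along leading axes).
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise InvalidInputError("kernel argument must be finite")
    if u.ndim == 0:
        u = u.reshape(1)
    d = u.shape[-1]
    q = np.sum(u * u, axis=-1)
    out = (2.0 * np.pi) ** (-d / 2.0) * np.exp(-0.5 * q)
    return float(out) if out.ndim == 0 else out


def normal_reference_bandwidth(n: int, d: int) -> float:
    """Scalar plug-in bandwidth {4/(d+2)}**(1/(d+4)) * n**(-1/(d+4))."""
    if int(n) < 2:
        raise InvalidInputError("need n >= 2 for a bandwidth rule")
    if int(d) < 1:
        raise InvalidInputError("dimension must be >= 1")
    n, d = int(n), int(d)
    return (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))


def robust_scale(column) -> float:
    """min(sample sd, IQR/1.349) — robust scale for the per-dimension rule."""
    col = np.asarray(column, dtype=float)
    if col.ndim != 1 or col.size < 2:
        raise InvalidInputError("column must be a 1-d array with >= 2 entries")
    if not np.all(np.isfinite(col)):
        raise InvalidInputError("column must be finite")
    sd = float(np.std(col, ddof=1))
    q75, q25 = np.percentile(col, [75.0, 25.0])
    iqr_scale = (q75 - q25) / 1.349
    candidates = [s for s in (sd, iqr_scale) if s > 0.0]
    if not candidates:
        raise DegenerateScaleError("column has no spread; cannot form a bandwidth")
    return min(candidates)


def per_dimension_bandwidth(column, n: int | None = None) -> float:
    """Per-dimension plug-in bandwidth h_j = (4/3)**(1/5) * sigma_j * n**(-1/5).

    The curvature functional in the optimal-bandwidth expression is replaced
    by its normal-reference value with a robust scale estimate (Silverman's
    rule of thumb), keeping the rule closed-form and deterministic.
    """
    col = np.asarray(column, dtype=float)
    if n is None:
        n = col.size
    if int(n) < 2:
        raise InvalidInputError("need n >= 2 for a bandwidth rule")
    scale = robust_scale(col)
    return (4.0 / 3.0) ** 0.2 * scale * int(n) ** (-0.2)


def _mixture_density(eval_pts: np.ndarray, scaled_data: np.ndarray,
                     transform: np.ndarray, log_det_transform: float,
                     chunk: int = 16384) -> np.ndarray:
    """Density of the equal-weight Gaussian mixture with whitening ``transform``.

    ``transform`` maps original coordinates to unit-kernel coordinates;
    scaled_data = data @ transform.T is precomputed by callers that reuse it.
    """
    n, p = scaled_data.shape
    scaled_eval = eval_pts @ transform.T
    log_norm = log_det_transform - (p / 2.0) * np.log(2.0 * np.pi) - np.log(n)
    out = np.empty(scaled_eval.shape[0])
    for start in range(0, scaled_eval.shape[0], chunk):
        block = scaled_eval[start:start + chunk]
        d2 = cdist(block, scaled_data, metric="sqeuclidean")
        out[start:start + chunk] = np.exp(log_norm) * np.sum(np.exp(-0.5 * d2), axis=1)
    return out


def kde_marginal(data, point, bw: BandwidthSpec) -> np.ndarray | float:
    """Product-kernel density estimate at ``point`` (a d-vector or (m, d) array).

    With a scalar bandwidth this is (1/(n h^d)) sum_i K((x - X_i)/h); with
    per-dimension bandwidths the kernel is the product of 1-d Gaussians.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.ndim != 2 or data.shape[0] < 1:
        raise InvalidInputError("data must be an (n, d) array")
    n, d = data.shape
    pts = np.asarray(point, dtype=float)
    scalar_out = pts.ndim <= 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != d:
        raise InvalidInputError(
            f"point dimension {pts.shape[1]} does not match data dimension {d}"
        )
    if not (np.all(np.isfinite(data)) and np.all(np.isfinite(pts))):
        raise InvalidInputError("data and point must be finite")
    h = bw.per_dim(d)
    transform = np.diag(1.0 / h)
    dens = _mixture_density(pts, data @ transform.T, transform,
                            float(-np.sum(np.log(h))))
    return float(dens[0]) if scalar_out and dens.size == 1 else dens


def kde_whitened(data, point, h: float) -> np.ndarray | float:
    """Covariance-whitened (Fukunaga) density estimate with scalar bandwidth h.

    (det S)**(-1/2) / (n h^d) * sum_i k((x - X_i)' S^{-1} (x - X_i) / h^2),
    where S is the sample covariance.  Invariant under joint affine changes
    of coordinates applied to data and point.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    if n <= d:
        raise DegenerateCovarianceError(
            "need n > d observations for a nonsingular covariance; "
            "fall back to the product kernel"
        )
    if not (np.isfinite(h) and h > 0):
        raise InvalidInputError("bandwidth must be positive and finite")
    pts = np.asarray(point, dtype=float)
    scalar_out = pts.ndim <= 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != d:
        raise InvalidInputError(
            f"point dimension {pts.shape[1]} does not match data dimension {d}"
        )
    S = np.atleast_2d(np.cov(data, rowvar=False, ddof=1))
    if not np.all(np.isfinite(S)) or np.linalg.cond(S) > 1e12:
        raise DegenerateCovarianceError(
            "near-singular sample covariance; fall back to the product kernel"
        )
    try:
        L = cholesky(S, lower=True)
    except Exception as exc:
        raise DegenerateCovarianceError(
            "singular sample covariance; fall back to the product kernel"
        ) from exc
    # transform = L^{-1} / h maps x to whitened unit-kernel coordinates
    Linv = solve_triangular(L, np.eye(d), lower=True)
    transform = Linv / h
    log_det = float(np.sum(np.log(np.diag(Linv)))) - d * np.log(h)
    dens = _mixture_density(pts, data @ transform.T, transform, log_det)
    return float(dens[0]) if scalar_out and dens.size == 1 else dens
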