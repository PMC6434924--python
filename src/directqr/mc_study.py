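"""Monte-Carlo efficiency study of the quantile-regression estimators.

For each of m replicates, n pairs are drawn from the bivariate exponential
simulator; each configured estimator is fitted at each tau and evaluated on
a quadrature grid over [0, N].  The simulation mean squared error is

    SMSE(Q) = (1/m) * sum_i integral_0^N (Q_i(tau|x) - xi(tau|x))^2 dx

and the efficiency of an estimator against the linear baseline is

    SEFF(Q) = SMSE(Q_linear) / SMSE(Q).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .baseline_qr import default_lpqr_bandwidth, fit_linear_qr, lpqr_curve, predict_linear_qr
from .direct_qr import QuantileCurve, RegressionSample, direct_quantile_curves
from .errors import DirectQRError, InvalidInputError, StudyAbortedError
from .gumbel_sim import GumbelParams, joint_cdf, sample_pairs, true_conditional_quantile

__all__ = [
    "StudyConfig",
    "SimulationReport",
    "smse_one_replicate",
    "run_study",
    "format_table1",
]

logger = logging.getLogger(__name__)

ESTIMATORS = ("linear", "lpqr", "direct")
_TABLE_LABELS = {"linear": "Q_R", "lpqr": "Q_LP", "direct": "Q_D"}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one Monte-Carlo study."""

    m: int = 100
    n: int = 100
    taus: tuple = (0.95, 0.96, 0.97, 0.98, 0.99)
    alpha: float = 1.0
    N: float = 6.0
    x_nodes: int = 121
    seed: int = 0
    estimators: tuple = ESTIMATORS
    lpqr_bandwidth_scale: float = 4.0
    max_failure_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 2:
            raise InvalidInputError("m and n must both be >= 2")
        taus = tuple(float(t) for t in self.taus)
        if not taus or any(not (0.0 < t < 1.0) for t in taus):
            raise InvalidInputError("tau values must lie in (0, 1)")
        object.__setattr__(self, "taus", taus)
        ests = tuple(self.estimators)
        unknown = set(ests) - set(ESTIMATORS)
        if unknown or not ests:
            raise InvalidInputError(f"unknown estimators {sorted(unknown)}")
        object.__setattr__(self, "estimators", ests)
        if joint_cdf(self.N, self.N, GumbelParams(self.alpha)) < 0.99:
            raise InvalidInputError(
                f"N={self.N} too small: joint CDF at (N, N) below 0.99"
            )

    @property
    def x_grid(self) -> np.ndarray:
        return np.linspace(0.0, float(self.N), int(self.x_nodes))

    @property
    def params(self) -> GumbelParams:
        return GumbelParams(alpha=self.alpha)


@dataclass(frozen=True)
class SimulationReport:
    """SMSE per (estimator, tau) and SEFF ratios against the linear baseline."""

    smse: dict
    seff: dict
    config: StudyConfig
    n_resampled: int = 0

    def to_dict(self) -> dict:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(self.config).items()}
        return {
            "config": cfg,
            "n_resampled": self.n_resampled,
            "smse": {est: {str(t): v for t, v in by_tau.items()}
                     for est, by_tau in self.smse.items()},
            "seff": {est: {str(t): v for t, v in by_tau.items()}
                     for est, by_tau in self.seff.items()},
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def smse_one_replicate(curve: QuantileCurve, tau: float, params: GumbelParams,
                       N: float) -> float:
    """Integrated squared error of one fitted curve against the true quantile."""
    x = curve.x_eval[:, 0]
    if curve.x_eval.shape[1] != 1:
        raise InvalidInputError("study curves must be one-dimensional in x")
    if x[0] > 1e-12 or x[-1] < N - 1e-12:
        raise InvalidInputError(f"curve grid must span [0, {N}]")
    truth = true_conditional_quantile(float(tau), x, params)
    return float(np.trapezoid((curve.q_values - truth) ** 2, x))


def _fit_replicate(x: np.ndarray, y: np.ndarray, config: StudyConfig) -> dict:
    """Fit every configured estimator at every tau; returns {(est, tau): curve}."""
    sample = RegressionSample(y=y, X=x[:, None])
    grid = config.x_grid
    curves = {}
    if "linear" in config.estimators:
        for tau in config.taus:
            fit = fit_linear_qr(sample, tau)
            curves[("linear", tau)] = predict_linear_qr(fit, grid)
    if "lpqr" in config.estimators:
        h = default_lpqr_bandwidth(x, scale=config.lpqr_bandwidth_scale)
        for tau in config.taus:
            curves[("lpqr", tau)] = lpqr_curve(sample, tau, grid, h=h)
    if "direct" in config.estimators:
        for c in direct_quantile_curves(sample, config.taus, grid):
            curves[("direct", c.tau)] = c
    return curves


def run_study(config: StudyConfig) -> SimulationReport:
    """Run the full replicate loop and aggregate SMSE/SEFF.

    Replicates whose estimation fails are resampled from a fresh random
    sub-stream (so averages stay over exactly m replicates); the study aborts
    if failures exceed ``max_failure_frac`` of m.
    """
    ss = np.random.SeedSequence(config.seed)
    children = list(ss.spawn(config.m))
    params = config.params
    ise = {(est, tau): [] for est in config.estimators for tau in config.taus}
    n_failures = 0
    max_failures = int(np.ceil(config.max_failure_frac * config.m))
    i = 0
    while i < config.m:
        child = children[i]
        rng = np.random.default_rng(child)
        x, y = sample_pairs(config.n, params, rng=rng)
        try:
            curves = _fit_replicate(x, y, config)
        except DirectQRError as exc:
            n_failures += 1
            logger.warning("replicate %d failed (%s); resampling", i, exc)
            if n_failures > max_failures:
                raise StudyAbortedError(
                    f"{n_failures} replicate failures exceed the "
                    f"{config.max_failure_frac:.0%} budget"
                ) from exc
            children[i] = ss.spawn(1)[0]
            continue
        for key, curve in curves.items():
            ise[key].append(smse_one_replicate(curve, key[1], params, config.N))
        logger.debug("replicate %d/%d done", i + 1, config.m)
        i += 1
    smse = {est: {tau: float(np.mean(ise[(est, tau)])) for tau in config.taus}
            for est in config.estimators}
    seff = {}
    if "linear" in config.estimators:
        for est in config.estimators:
            if est == "linear":
                continue
            seff[est] = {tau: smse["linear"][tau] / smse[est][tau]
                         for tau in config.taus}
    return SimulationReport(smse=smse, seff=seff, config=config,
                            n_resampled=n_failures)


def format_table1(report: SimulationReport) -> str:
    """Plain-text SMSE/SEFF table, tau values as columns."""
    taus = report.config.taus
    lines = []
    header = ["tau"] + [f"{t:g}" for t in taus]
    widths = [18] + [10] * len(taus)

    def row(cells):
        return "  ".join(str(c).rjust(w) for c, w in zip(cells, widths))

    lines.append(row(header))
    lines.append(row(["-" * 10] * (len(taus) + 1)))
    missing = [e for e in ESTIMATORS if e not in report.smse]
    for est in ESTIMATORS:
        if est in report.smse:
            label = f"SMSE({_TABLE_LABELS[est]})"
            lines.append(row([label] + [f"{report.smse[est][t]:.3f}" for t in taus]))
    for est in ("lpqr", "direct"):
        if est in report.seff:
            label = f"SEFF({_TABLE_LABELS[est]})"
            lines.append(row([label] + [f"{report.seff[est][t]:.4f}" for t in taus]))
    if missing:
        lines.append(f"(partial table: missing estimator(s) {', '.join(missing)})")
    return "\n".join(lines)
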