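"""Relative-risk summaries of a fitted temperature-lag model.

Converts the cross-basis coefficient block of a Poisson DLNM fit into
cumulative (summed over lags) relative-risk curves against a reference
temperature, defines Mild/Moderate/Severe heat-day bins from summer Tmax
percentiles, and computes the percent change of RR per 1 degC over a bin:

    percent change = (RR_n - RR_1) / (n - 1) * 100

with RR evaluated on a 1 degC grid from the bin's lower to upper threshold
(n = floor(span) + 1 points). Confidence intervals for that statistic are
Monte-Carlo over the asymptotic normal distribution of the coefficients,
because the statistic is a nonlinear functional of the fitted curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .glm import DLNMResults
from .splines import CrossBasisSpec, ns_basis

__all__ = [
    "HeatDayBins",
    "RRCurve",
    "PercentChange",
    "heat_day_bins",
    "bin_grid",
    "predict_rr",
    "percent_change",
    "percent_change_ci",
]

_Z95 = 1.959963984540054

BIN_LABELS = ("Mild", "Moderate", "Severe")


@dataclass(frozen=True)
class HeatDayBins:
    """Heat-day thresholds from summer (JJA) Tmax percentiles.

    Mild days have Tmax in the 60th-90th percentile range, Moderate in the
    90th-99th, Severe at or above the 99th.
    """

    p60: float
    p90: float
    p99: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.p60 < self.p90 < self.p99:
            raise ValueError(
                f"degenerate heat-day thresholds: p60={self.p60}, p90={self.p90}, p99={self.p99}"
            )

    def bin_range(self, label: str, tmax_upper: Optional[float] = None) -> tuple[float, float]:
        """(lower, upper) temperature span of a bin; the Severe bin's upper
        end is the supplied series maximum ``tmax_upper``."""
        if label == "Mild":
            return (self.p60, self.p90)
        if label == "Moderate":
            return (self.p90, self.p99)
        if label == "Severe":
            if tmax_upper is None:
                raise ValueError("Severe bin needs the series maximum as its upper end")
            return (self.p99, float(tmax_upper))
        raise ValueError(f"unknown bin label {label!r}")


def heat_day_bins(summer_tmax: Sequence[float], source: str = "") -> HeatDayBins:
    """Thresholds at the 60th/90th/99th percentiles of pooled summer Tmax
    (linear-interpolation percentile definition)."""
    x = np.asarray(summer_tmax, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("summer Tmax contains non-finite values")
    if x.size < 100:
        warnings.warn(
            f"only {x.size} summer days available for percentile thresholds", UserWarning, stacklevel=2
        )
    p60, p90, p99 = (float(v) for v in np.percentile(x, [60.0, 90.0, 99.0]))
    return HeatDayBins(p60, p90, p99, source)


@dataclass
class RRCurve:
    """Cumulative-over-lag relative risk vs a reference temperature with
    pointwise 95% (delta-method) intervals."""

    temp_grid: np.ndarray
    rr: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    reference_temp: float

    def at(self, temps: Sequence[float]) -> np.ndarray:
        """RR at the requested temperatures (grid lookup, linear
        interpolation between grid points)."""
        t = np.atleast_1d(np.asarray(temps, dtype=float))
        return np.interp(t, self.temp_grid, self.rr)


def _cumulative_contrast(
    cb_spec: CrossBasisSpec, temp_grid: np.ndarray, reference_temp: float
) -> np.ndarray:
    """Rows u(T) with logRR(T vs ref) = u(T) . beta_cb.

    u(T)[(i,j)] = (b_i(T) - b_i(ref)) * sum_l c_j(l), matching the
    cross-basis column order."""
    grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    var_b = ns_basis(np.append(grid, reference_temp), cb_spec.var_spec).values
    b_diff = var_b[:-1] - var_b[-1]  # (g, dv)
    lag_sum = cb_spec.lag_basis().sum(axis=0)  # (dl,)
    return (b_diff[:, :, None] * lag_sum[None, None, :]).reshape(grid.size, -1)


def predict_rr(
    fit: DLNMResults,
    cb_spec: Optional[CrossBasisSpec],
    temp_grid: Sequence[float],
    reference_temp: float,
) -> RRCurve:
    """Cumulative RR curve over ``temp_grid`` against ``reference_temp``.

    log RR(T) sums the fitted exposure-lag surface over lags 0..L; the 95%
    band is the delta method on the cross-basis coefficient block. The curve
    is exactly 1 at the reference by construction. Grid points beyond the
    temperature-basis boundary knots trigger an extrapolation warning (the
    curve continues linearly there, by the natural-spline property).
    """
    if cb_spec is None:
        cb_spec = fit.cb_spec
    if cb_spec is None:
        raise ValueError("no cross-basis specification available")
    if not fit.converged:
        raise ValueError("relative risks requested from an unconverged fit")
    lo, hi = cb_spec.var_spec.boundary_knots
    if not lo <= reference_temp <= hi:
        raise ValueError(f"reference temperature {reference_temp} outside boundary knots ({lo}, {hi})")
    grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    if grid.min() < lo or grid.max() > hi:
        warnings.warn(
            "temperature grid extends beyond the basis boundary knots; "
            "the curve is a linear extrapolation there",
            UserWarning,
            stacklevel=2,
        )
    beta, cov = fit.cb_block()
    U = _cumulative_contrast(cb_spec, grid, reference_temp)
    log_rr = U @ beta
    var = np.einsum("ij,jk,ik->i", U, cov, U)
    se = np.sqrt(np.clip(var, 0.0, None))
    return RRCurve(
        temp_grid=grid,
        rr=np.exp(log_rr),
        lower95=np.exp(log_rr - _Z95 * se),
        upper95=np.exp(log_rr + _Z95 * se),
        reference_temp=float(reference_temp),
    )


def bin_grid(lower: float, upper: float) -> np.ndarray:
    """1 degC evaluation grid for the percent-change formula: points
    lower, lower+1, ..., n = floor(upper-lower)+1 of them (so the last point
    is the largest whole-degree step not exceeding the upper threshold)."""
    span = float(upper) - float(lower)
    if span < 1.0:
        raise ValueError(f"temperature bin [{lower}, {upper}] is narrower than 1 degC")
    n = int(np.floor(span)) + 1
    return float(lower) + np.arange(n, dtype=float)


@dataclass
class PercentChange:
    """Percent change of RR per 1 degC over a heat-day bin."""

    label: str
    rr_first: float
    rr_last: float
    n_points: int
    value: float
    lower95: Optional[float] = None
    upper95: Optional[float] = None

    @property
    def significant(self) -> Optional[bool]:
        """True when the 95% interval excludes 0."""
        if self.lower95 is None or self.upper95 is None:
            return None
        return self.lower95 > 0.0 or self.upper95 < 0.0


def percent_change(curve: RRCurve, bin_range: tuple[float, float], label: str = "") -> PercentChange:
    """Apply ((RR_n - RR_1)/(n - 1)) x 100 over the bin's 1 degC grid.

    RR values are read off ``curve``; the curve must cover the bin."""
    lower, upper = bin_range
    grid = bin_grid(lower, upper)
    if grid[0] < curve.temp_grid.min() - 1e-9 or grid[-1] > curve.temp_grid.max() + 1e-9:
        raise ValueError("curve does not cover the requested bin")
    rr = curve.at(grid)
    n = grid.size
    value = (rr[-1] - rr[0]) / (n - 1) * 100.0
    return PercentChange(label, float(rr[0]), float(rr[-1]), int(n), float(value))


def percent_change_ci(
    fit: DLNMResults,
    cb_spec: Optional[CrossBasisSpec],
    bin_range: tuple[float, float],
    reference_temp: float,
    n_draws: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo 95% interval for the percent-change statistic.

    Coefficient vectors are drawn from the asymptotic multivariate normal
    (mean = estimates, covariance = fit covariance restricted to the
    cross-basis block); the statistic is recomputed per draw and the
    2.5/97.5 empirical percentiles returned. Reproducible under a fixed seed.
    """
    if not fit.converged:
        raise ValueError("confidence interval requested from an unconverged fit")
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000 for stable tail percentiles")
    if cb_spec is None:
        cb_spec = fit.cb_spec
    beta, cov = fit.cb_block()
    cov = 0.5 * (cov + cov.T)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-8 * max(1.0, abs(eig.max())):
        raise ValueError("coefficient covariance is not positive semi-definite")
    grid = bin_grid(*bin_range)
    U = _cumulative_contrast(cb_spec, grid, reference_temp)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(beta, cov, size=n_draws, method="eigh")  # (n_draws, p)
    rr = np.exp(draws @ U.T)  # (n_draws, n_grid)
    pc = (rr[:, -1] - rr[:, 0]) / (grid.size - 1) * 100.0
    lo, hi = np.percentile(pc, [2.5, 97.5])
    return float(lo), float(hi)
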