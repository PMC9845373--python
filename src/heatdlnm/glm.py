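"""Poisson log-linear DLNM: model object, IRLS fit, AIC lag selection.

The model for daily death counts y_t is

    ln E(y_t) = alpha + beta . CB(Tmax)_t + NS(rhavg_t) + NS(prcp_t)
                + NS(doy_t) + NS(sn_t) + gamma . weekday_t,
    y_t ~ Poisson,

where CB is the temperature x lag cross-basis, NS are natural cubic spline
bases, doy is the day of year, sn the sequential serial number of the date
(adjusting the long-term mortality trend) and weekday_t day-of-week dummies.
Fitting is by iteratively reweighted least squares (maximum likelihood).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .splines import CrossBasis, CrossBasisSpec, SplineSpec, crossbasis, ns_basis

logger = logging.getLogger(__name__)

__all__ = [
    "ConfounderConfig",
    "DesignFrame",
    "DLNMResults",
    "PoissonDLNM",
    "LagSelection",
    "build_confounders",
    "fit_poisson",
    "aic_of",
    "select_lag",
]


@dataclass(frozen=True)
class ConfounderConfig:
    """Degrees of freedom (basis columns, intercept excluded) for the
    confounder splines, and whether weekday dummies enter.

    ``sn_df_per_decade`` scales with the data span: 1 df per decade means the
    long-term trend is linear within a single decade of data.
    """

    rh_df: int = 3
    prcp_df: int = 3
    doy_df: int = 4
    sn_df_per_decade: int = 1
    weekday: bool = True


@dataclass
class DesignFrame:
    """Assembled per-day design: intercept, cross-basis block, confounders.

    ``cb_columns`` names the cross-basis block so the risk module can slice
    the coefficient vector and covariance; ``valid`` marks rows retained for
    fitting (lag-complete, inside the fitting window, no missing values).
    """

    frame: pd.DataFrame
    cb_columns: list[str]
    valid: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.loc[self.valid].to_numpy(dtype=float)


def _spline_block(x: np.ndarray, df: int, name: str, positive_knots: bool = False) -> pd.DataFrame:
    """NS block with ``df`` columns; knots from quantiles. Returns an empty
    frame when the covariate is degenerate (fewer than 3 distinct values)."""
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if np.unique(finite).size < 3:
        logger.warning("covariate %s is degenerate (<3 distinct values); omitted", name)
        return pd.DataFrame(index=range(x.size))
    knot_source = finite[finite > 0] if positive_knots else finite
    if knot_source.size < 3:
        knot_source = finite
    n_interior = df - 1
    probs = [100.0 * (i + 1) / (n_interior + 1) for i in range(n_interior)]
    spec = SplineSpec.from_quantiles(
        knot_source, probs, include_intercept=False, boundary=(float(finite.min()), float(finite.max()))
    )
    basis = ns_basis(x, spec)
    return pd.DataFrame(basis.values, columns=[f"{name}_{c}" for c in basis.column_labels])


def build_confounders(
    dates: pd.Series,
    rhavg: Optional[np.ndarray] = None,
    prcp: Optional[np.ndarray] = None,
    config: ConfounderConfig = ConfounderConfig(),
) -> pd.DataFrame:
    """Confounder columns for the model: humidity/precipitation/seasonality/
    trend splines and weekday dummies, indexed 0..n-1."""
    dates = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    blocks: list[pd.DataFrame] = []
    if rhavg is not None:
        blocks.append(_spline_block(np.asarray(rhavg, float), config.rh_df, "rh"))
    if prcp is not None:
        blocks.append(_spline_block(np.asarray(prcp, float), config.prcp_df, "prcp", positive_knots=True))
    doy = dates.dt.dayofyear.to_numpy(dtype=float)
    blocks.append(_spline_block(doy, config.doy_df, "doy"))
    sn = (dates - dates.iloc[0]).dt.days.to_numpy(dtype=float)
    span_decades = max(1, int(np.ceil((sn.max() + 1) / 3652.5)))
    blocks.append(_spline_block(sn, config.sn_df_per_decade * span_decades, "sn"))
    if config.weekday:
        dow = dates.dt.dayofweek
        wd = pd.get_dummies(dow).reindex(columns=range(7), fill_value=0).astype(float)
        wd = wd.iloc[:, :6]  # Sunday is the reference level
        wd.columns = [f"wd_{d}" for d in ["mon", "tue", "wed", "thu", "fri", "sat"]]
        blocks.append(wd.reset_index(drop=True))
    out = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=range(len(dates)))
    return out


def _collinear_columns(X: np.ndarray, labels: Sequence[str], tol: float = 1e-8) -> list[str]:
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    r = np.linalg.qr(X / scale, mode="r")
    diag = np.abs(np.diag(r))
    return [labels[j] for j in np.flatnonzero(diag < tol * max(1.0, diag.max()))]


@dataclass
class DLNMResults:
    """Fit output: coefficient vector, covariance (inverse observed
    information), log-likelihood, AIC, deviance and convergence status.

    When the model carried a cross-basis, ``cb_spec``/``cb_index`` locate the
    exposure block so relative-risk summaries can be derived; see the
    ``predict_rr``/``percent_change*`` methods.
    """

    params: np.ndarray
    cov: np.ndarray
    column_labels: list[str]
    loglik: float
    aic: float
    deviance: float
    n_obs: int
    converged: bool
    iterations: int
    cb_spec: Optional[CrossBasisSpec] = None
    cb_index: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self.cov = 0.5 * (self.cov + self.cov.T)

    @property
    def bse(self) -> np.ndarray:
        """Standard errors."""
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def n_params(self) -> int:
        return self.params.size

    def cb_block(self) -> tuple[np.ndarray, np.ndarray]:
        """(coefficients, covariance) restricted to the cross-basis columns."""
        if self.cb_index is None:
            raise ValueError("fit carries no cross-basis block")
        idx = self.cb_index
        return self.params[idx], self.cov[np.ix_(idx, idx)]

    def summary(self) -> pd.DataFrame:
        """Coefficient table with Wald standard errors and 95% intervals."""
        se = self.bse
        z = np.divide(self.params, se, out=np.zeros_like(self.params), where=se > 0)
        from scipy import stats

        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std_err": se,
                "z": z,
                "p_value": 2 * stats.norm.sf(np.abs(z)),
                "ci_low": self.params - 1.959963984540054 * se,
                "ci_high": self.params + 1.959963984540054 * se,
            },
            index=self.column_labels,
        )
        return tab

    # relative-risk summaries delegate to the risk module -----------------
    def predict_rr(self, temp_grid, reference_temp):
        from . import risk

        return risk.predict_rr(self, self.cb_spec, temp_grid, reference_temp)

    def percent_change(self, lower, upper, reference_temp, label=""):
        from . import risk

        grid = risk.bin_grid(lower, upper)
        curve = self.predict_rr(grid, reference_temp)
        return risk.percent_change(curve, (lower, upper), label)

    def percent_change_ci(self, lower, upper, reference_temp, n_draws=2000, seed=0):
        from . import risk

        return risk.percent_change_ci(
            self, self.cb_spec, (lower, upper), reference_temp, n_draws=n_draws, seed=seed
        )


def fit_poisson(
    design: "DesignFrame | pd.DataFrame | np.ndarray",
    deaths: Sequence[float],
    column_labels: Optional[Sequence[str]] = None,
    cb_spec: Optional[CrossBasisSpec] = None,
    cb_columns: Optional[Sequence[str]] = None,
    tol: float = 1e-9,
    maxiter: int = 100,
    quasi_poisson: bool = False,
) -> DLNMResults:
    """Maximum-likelihood Poisson fit of ``ln E(y) = X theta`` via IRLS.

    Convergence: relative change in deviance below ``tol`` (default 1e-9)
    within ``maxiter`` iterations; a fit that does not converge is returned
    with ``converged=False`` and a warning, never silently. A rank-deficient
    design raises, naming the collinear columns.

    ``quasi_poisson=True`` inflates the covariance by the Pearson chi-square
    dispersion estimate (point estimates unchanged); off by default.
    """
    if isinstance(design, DesignFrame):
        frame = design.frame.loc[design.valid]
        X = frame.to_numpy(dtype=float)
        labels = list(frame.columns)
        y = np.asarray(deaths, dtype=float)[design.valid]
        if cb_columns is None:
            cb_columns = design.cb_columns
    else:
        if isinstance(design, pd.DataFrame):
            X = design.to_numpy(dtype=float)
            labels = list(design.columns)
        else:
            X = np.asarray(design, dtype=float)
            labels = list(column_labels) if column_labels else [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(deaths, dtype=float)
    if column_labels is not None:
        labels = list(column_labels)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("death counts must be non-negative integers")
    if not np.all(np.isfinite(X)):
        raise ValueError("design contains non-finite values in retained rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, labels)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=tol, scale="X2" if quasi_poisson else 1.0)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn("Poisson IRLS did not converge", RuntimeWarning, stacklevel=2)
    k = X.shape[1]
    cb_index = None
    if cb_columns:
        cb_index = np.asarray([labels.index(c) for c in cb_columns], dtype=int)
    return DLNMResults(
        params=res.params,
        cov=np.asarray(res.cov_params()),
        column_labels=labels,
        loglik=float(res.llf),
        aic=float(-2.0 * res.llf + 2.0 * k),
        deviance=float(res.deviance),
        n_obs=int(y.size),
        converged=converged,
        iterations=int(getattr(res, "fit_history", {}).get("iteration", maxiter) or 0),
        cb_spec=cb_spec,
        cb_index=cb_index,
    )


def aic_of(fit: DLNMResults) -> float:
    """AIC = -2 loglik + 2 k. Rejects unconverged fits."""
    if not fit.converged:
        raise ValueError("AIC requested for an unconverged fit")
    return -2.0 * fit.loglik + 2.0 * fit.n_params


class PoissonDLNM:
    """Poisson time-series model with a temperature x lag cross-basis.

    Parameters
    ----------
    deaths : array of daily counts, aligned with the cross-basis rows.
    cb : CrossBasis for the exposure term.
    confounders : optional DataFrame of additional columns (one row per day).
    fit_mask : optional boolean array restricting the fitting window (e.g.
        summer days only); lag-incomplete rows are always excluded.
    """

    def __init__(
        self,
        deaths: Sequence[float],
        cb: CrossBasis,
        confounders: Optional[pd.DataFrame] = None,
        fit_mask: Optional[np.ndarray] = None,
        add_intercept: bool = True,
    ) -> None:
        n = cb.values.shape[0]
        deaths = np.asarray(deaths, dtype=float)
        if deaths.size != n:
            raise ValueError("deaths and cross-basis must cover the same days")
        valid = cb.complete.copy()
        if fit_mask is not None:
            fit_mask = np.asarray(fit_mask, dtype=bool)
            if fit_mask.size != n:
                raise ValueError("fit_mask length mismatch")
            valid &= fit_mask
        parts = []
        if add_intercept:
            parts.append(pd.DataFrame({"const": np.ones(n)}))
        cb_frame = pd.DataFrame(cb.values, columns=cb.column_labels)
        parts.append(cb_frame)
        if confounders is not None:
            conf = confounders.reset_index(drop=True)
            if len(conf) != n:
                raise ValueError("confounder frame length mismatch")
            valid &= ~conf.isna().any(axis=1).to_numpy()
            parts.append(conf)
        frame = pd.concat(parts, axis=1)
        self.design = DesignFrame(frame, list(cb.column_labels), valid)
        self.deaths = deaths
        self.cb = cb

    def fit(self, tol: float = 1e-9, maxiter: int = 100, quasi_poisson: bool = False) -> DLNMResults:
        return fit_poisson(
            self.design,
            self.deaths,
            cb_spec=self.cb.spec,
            tol=tol,
            maxiter=maxiter,
            quasi_poisson=quasi_poisson,
        )


@dataclass
class LagSelection:
    """Outcome of AIC-based lag-window selection."""

    chosen: int
    table: pd.DataFrame  # columns: max_lag, aic, converged
    fits: dict[int, DLNMResults]


def select_lag(
    candidates: Sequence[int],
    tmax: Sequence[float],
    deaths: Sequence[float],
    confounders: Optional[pd.DataFrame] = None,
    fit_mask: Optional[np.ndarray] = None,
    var_knot_percentiles: Sequence[float] = (10.0, 75.0, 90.0),
) -> LagSelection:
    """Fit one model per candidate maximum lag and pick the AIC minimiser.

    All candidates are fitted on a common row set — the rows lag-complete for
    the *largest* candidate — so their AICs are comparable. Ties break toward
    the smaller lag; candidates whose fit fails or does not converge are
    excluded with a warning; if all fail an error is raised.
    """
    cands = sorted(set(int(c) for c in candidates))
    if not cands:
        raise ValueError("need at least one candidate lag")
    tmax = np.asarray(tmax, dtype=float)
    n = tmax.size
    common = np.ones(n, dtype=bool)
    common[: max(cands)] = False
    if fit_mask is not None:
        common &= np.asarray(fit_mask, dtype=bool)
    rows = []
    fits: dict[int, DLNMResults] = {}
    for L in cands:
        try:
            spec = CrossBasisSpec.default(tmax[common], L, var_knot_percentiles)
            cb = crossbasis(tmax, spec)
            model = PoissonDLNM(deaths, cb, confounders=confounders, fit_mask=common)
            res = model.fit()
            if not res.converged:
                raise RuntimeError("fit did not converge")
            fits[L] = res
            rows.append({"max_lag": L, "aic": aic_of(res), "converged": True})
        except Exception as exc:  # noqa: BLE001 - candidate failures are data, not bugs
            warnings.warn(f"lag candidate {L} excluded: {exc}", RuntimeWarning, stacklevel=2)
            rows.append({"max_lag": L, "aic": np.nan, "converged": False})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["aic"])
    if ok.empty:
        raise RuntimeError("no lag candidate produced a converged fit")
    # idxmin on the ascending-sorted table breaks ties toward the smaller lag
    chosen = int(ok.loc[ok["aic"].idxmin(), "max_lag"])
    return LagSelection(chosen, table, fits)
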