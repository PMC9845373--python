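"""Natural cubic spline bases and the temperature x lag cross-basis.

The cross-basis is the design-matrix block of a distributed lag non-linear
model (DLNM): its columns are products of basis functions over the exposure
value (here daily maximum temperature) and basis functions over lag time,
so a single coefficient vector encodes a full exposure-lag response surface.

Natural cubic splines are used throughout: piecewise cubics with continuous
second derivatives at the interior knots and zero second derivative beyond
the boundary knots, so the fitted curve is linear in the tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SplineSpec",
    "BasisMatrix",
    "CrossBasisSpec",
    "CrossBasis",
    "ns_basis",
    "lag_stack",
    "crossbasis",
]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for a natural cubic spline basis.

    Parameters
    ----------
    interior_knots : tuple of float
        Strictly increasing knots, strictly inside the boundary knots.
    boundary_knots : (float, float)
        Beyond these the basis functions are linear.
    include_intercept : bool
        If True a constant column is prepended; the basis then has
        ``len(interior_knots) + 2`` columns, otherwise one fewer.
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    include_intercept: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "interior_knots", tuple(float(k) for k in self.interior_knots))
        object.__setattr__(self, "boundary_knots", tuple(float(k) for k in self.boundary_knots))
        lo, hi = self.boundary_knots
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("boundary knots must be finite")
        if not lo < hi:
            raise ValueError(f"boundary knots must be distinct and ordered, got ({lo}, {hi})")
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size and not np.all(np.isfinite(ik)):
            raise ValueError("interior knots must be finite")
        if ik.size and not np.all(np.diff(ik) > 0):
            raise ValueError(f"interior knots must be strictly increasing, got {self.interior_knots}")
        if ik.size and not (ik[0] > lo and ik[-1] < hi):
            raise ValueError(
                f"interior knots {self.interior_knots} must lie strictly inside "
                f"boundary knots ({lo}, {hi})"
            )

    @property
    def all_knots(self) -> np.ndarray:
        """All knots, boundary included, ascending."""
        return np.asarray(sorted((*self.interior_knots, *self.boundary_knots)), dtype=float)

    @property
    def ndim(self) -> int:
        """Number of basis columns."""
        return len(self.interior_knots) + 1 + int(self.include_intercept)

    @classmethod
    def from_quantiles(
        cls,
        x: Sequence[float],
        probs: Sequence[float],
        include_intercept: bool = False,
        boundary: Optional[tuple[float, float]] = None,
    ) -> "SplineSpec":
        """Place interior knots at the given quantiles of ``x`` (in percent),
        boundary knots at min/max of ``x`` unless given explicitly."""
        arr = np.asarray(x, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            raise ValueError("need at least two finite values to place knots")
        lo, hi = boundary if boundary is not None else (float(arr.min()), float(arr.max()))
        ik = [float(q) for q in np.percentile(arr, list(probs))] if len(list(probs)) else []
        # drop ties and knots on/outside the boundary
        keep: list[float] = []
        for k in ik:
            if lo < k < hi and (not keep or k > keep[-1]):
                keep.append(k)
        return cls(tuple(keep), (lo, hi), include_intercept)

    @classmethod
    def df(
        cls,
        x: Sequence[float],
        df: int,
        include_intercept: bool = False,
    ) -> "SplineSpec":
        """Spec with ``df`` basis columns (intercept excluded from the count):
        df-1 interior knots at equally spaced quantiles, boundary at min/max."""
        if df < 1:
            raise ValueError("df must be >= 1")
        n_interior = df - 1
        probs = [100.0 * (i + 1) / (n_interior + 1) for i in range(n_interior)]
        return cls.from_quantiles(x, probs, include_intercept)


@dataclass
class BasisMatrix:
    """Dense basis evaluation: rows are observations, columns basis functions."""

    values: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("basis values must be a 2-d array")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("label count does not match column count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def ns_basis(x: Sequence[float], spec: SplineSpec) -> BasisMatrix:
    """Evaluate the natural cubic spline basis of ``spec`` at ``x``.

    The basis is the classical reduced truncated-power form: with knots
    xi_1 < ... < xi_m (boundary knots included), columns are

        [1,]  x,  N_k(x) = d_k(x) - d_{m-1}(x)   for k = 1..m-2,

    where d_k(x) = [(x - xi_k)_+^3 - (x - xi_m)_+^3] / (xi_m - xi_k).
    Each N_k has zero second and third derivative outside the boundary
    knots, so the span is exactly the natural cubic splines on these knots.
    """
    xv = np.asarray(x, dtype=float)
    if xv.ndim != 1:
        raise ValueError("x must be one-dimensional")
    bad = np.flatnonzero(~np.isfinite(xv))
    if bad.size:
        raise ValueError(f"non-finite covariate value at index {bad[0]}")
    knots = spec.all_knots
    m = knots.size
    cols: list[np.ndarray] = []
    labels: list[str] = []
    if spec.include_intercept:
        cols.append(np.ones_like(xv))
        labels.append("const")
    cols.append(xv)
    labels.append("lin")

    def d(k: int) -> np.ndarray:
        return (
            np.clip(xv - knots[k], 0.0, None) ** 3 - np.clip(xv - knots[m - 1], 0.0, None) ** 3
        ) / (knots[m - 1] - knots[k])

    d_last = d(m - 2)
    for k in range(m - 2):
        cols.append(d(k) - d_last)
        labels.append(f"ns{k + 1}")
    return BasisMatrix(np.column_stack(cols), labels)


def lag_stack(x: Sequence[float], max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Table of lagged values: entry (t, l) is ``x[t - l]``.

    Returns ``(matrix, complete)`` where ``complete[t]`` is False for the
    first ``max_lag`` rows, whose lagged values would precede the series;
    those entries are NaN.
    """
    xv = np.asarray(x, dtype=float)
    if xv.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    n = xv.size
    if max_lag >= n:
        raise ValueError(f"max_lag={max_lag} must be smaller than the series length {n}")
    out = np.full((n, max_lag + 1), np.nan)
    for l in range(max_lag + 1):
        out[l:, l] = xv[: n - l]
    complete = np.ones(n, dtype=bool)
    complete[:max_lag] = False
    return out, complete


@dataclass(frozen=True)
class CrossBasisSpec:
    """Specification of the temperature x lag cross-basis.

    ``lag_spec=None`` means an intercept-only lag basis (a single constant
    lag weight), which is the only valid choice when ``max_lag == 0``.
    """

    max_lag: int
    var_spec: SplineSpec
    lag_spec: Optional[SplineSpec] = None

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.lag_spec is not None:
            lo, hi = self.lag_spec.boundary_knots
            if (lo, hi) != (0.0, float(self.max_lag)):
                raise ValueError(
                    f"lag basis boundary knots must be (0, {self.max_lag}), got ({lo}, {hi})"
                )
        elif self.max_lag > 0:
            # intercept-only lag basis is allowed for any L but is the only
            # option at L=0; nothing to validate here.
            pass

    @property
    def var_dim(self) -> int:
        return self.var_spec.ndim

    @property
    def lag_dim(self) -> int:
        return 1 if self.lag_spec is None else self.lag_spec.ndim

    @property
    def ndim(self) -> int:
        return self.var_dim * self.lag_dim

    def lag_basis(self) -> np.ndarray:
        """Lag basis evaluated at the integer lags 0..max_lag, shape (L+1, lag_dim)."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        if self.lag_spec is None:
            return np.ones((self.max_lag + 1, 1))
        return ns_basis(lags, self.lag_spec).values

    @classmethod
    def default(
        cls,
        tmax: Sequence[float],
        max_lag: int,
        var_knot_percentiles: Sequence[float] = (10.0, 75.0, 90.0),
        n_lag_knots: Optional[int] = None,
    ) -> "CrossBasisSpec":
        """Conventional DLNM layout: temperature basis with interior knots at
        the 10th/75th/90th percentiles of the fitted series and boundary
        knots at its min/max (the layout customary for temperature
        exposure-response surfaces); lag basis a natural spline over 0..L
        with intercept and
        interior knots equally spaced on the log(lag+1) scale (2 knots for
        L >= 7, 1 for 3 <= L < 7, none below)."""
        var_spec = SplineSpec.from_quantiles(tmax, var_knot_percentiles, include_intercept=False)
        if max_lag == 0:
            return cls(0, var_spec, None)
        if n_lag_knots is None:
            n_lag_knots = 2 if max_lag >= 7 else (1 if max_lag >= 3 else 0)
        interior = tuple(
            float(k)
            for k in np.exp(np.linspace(0.0, np.log(max_lag + 1.0), n_lag_knots + 2))[1:-1] - 1.0
        )
        lag_spec = SplineSpec(interior, (0.0, float(max_lag)), include_intercept=True)
        return cls(max_lag, var_spec, lag_spec)


@dataclass
class CrossBasis:
    """Evaluated cross-basis: rows are days, columns the d_var x d_lag
    tensor-product terms; the first ``max_lag`` rows are lag-incomplete
    (NaN, flagged in ``complete``) and are dropped from model fits."""

    values: np.ndarray
    spec: CrossBasisSpec
    complete: np.ndarray = field(repr=False)
    source_series_id: str = ""
    column_labels: list[str] = field(default_factory=list)


def crossbasis(tmax: Sequence[float], spec: CrossBasisSpec, source_series_id: str = "") -> CrossBasis:
    """Build the cross-basis of a daily Tmax series.

    Column (i, j) at day t holds sum over lags l of
    ``b_i(tmax[t-l]) * c_j(l)`` where ``b`` are the temperature basis
    functions and ``c`` the lag basis functions evaluated at integer lags.
    """
    xv = np.asarray(tmax, dtype=float)
    var_b = ns_basis(xv, spec.var_spec).values  # (n, dv)
    lag_b = spec.lag_basis()  # (L+1, dl)
    n = xv.size
    L = spec.max_lag
    if L >= n:
        raise ValueError(f"max_lag={L} must be smaller than the series length {n}")
    dv, dl = var_b.shape[1], lag_b.shape[1]
    vals = np.zeros((n, dv * dl))
    for l in range(L + 1):
        shifted = np.empty_like(var_b)
        shifted[l:] = var_b[: n - l]
        shifted[:l] = 0.0
        # outer product over basis dimensions, accumulated over lags
        vals += (shifted[:, :, None] * lag_b[l][None, None, :]).reshape(n, dv * dl)
    complete = np.ones(n, dtype=bool)
    complete[:L] = False
    vals[~complete] = np.nan
    labels = [f"cb_v{i + 1}l{j + 1}" for i in range(dv) for j in range(dl)]
    return CrossBasis(vals, spec, complete, source_series_id, labels)
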