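"""Synthetic weather and mortality with known ground truth.

Emulates the data layout of a two-decade, multi-city summer heat-mortality
study: daily weather series (seasonal Tmax with a configurable
between-decade warming shift, correlated Tmin/humidity/precipitation) and
record-level deaths whose Poisson log-rate contains a known temperature-lag
exposure surface, a seasonal cycle, a long-term trend, a weekday effect and
stratum-specific vulnerability. Every stochastic element is driven by an
explicit seed, and the exposure effect has a closed-form percent-change
oracle, so the full analysis pipeline can be validated without any
restricted data.

The exposure is a hockey stick on the log scale: zero below a percentile
threshold of summer Tmax, linear with slope ``s`` (log-RR per degC) above
it, distributed over lags 0..L with non-negative weights summing to one.
The cumulative log-RR at temperature T against a reference at the threshold
is then exactly ``s * max(0, T - threshold)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .risk import HeatDayBins, bin_grid

__all__ = [
    "CityParams",
    "CITY_DEFAULTS",
    "StratumSpec",
    "GeneratorTruth",
    "default_truth",
    "simulate_weather",
    "simulate_death_counts",
    "simulate_deaths",
    "resolve_threshold",
    "true_percent_change",
]

JJA_MONTHS = (6, 7, 8)

# ICD-10 chapter letters used when expanding counts to records. Internal
# (non-external) chapters A-R with plausible cause-of-death shares; external
# chapters drawn uniformly.
_INTERNAL_CHAPTERS = ("C", "I", "J", "E", "G", "K", "N", "A", "F", "D", "R")
_INTERNAL_PROBS = (0.28, 0.25, 0.12, 0.06, 0.05, 0.05, 0.04, 0.03, 0.04, 0.03, 0.05)
_EXTERNAL_CHAPTERS = ("S", "T", "V", "W", "X", "Y")


@dataclass(frozen=True)
class CityParams:
    """Weather-generator parameters for one city.

    ``summer_tmax_mean`` is the target JJA mean Tmax (degC) in the first
    period; ``warming_shift`` is added to Tmax in shift years (the second
    decade), emulating the observed between-decade warming.
    """

    name: str
    summer_tmax_mean: float = 28.5
    warming_shift: float = 1.0
    rh_mean: float = 72.0
    seasonal_amplitude: float = 12.5
    noise_sd: float = 2.5
    noise_ar: float = 0.55
    diurnal_range: float = 8.0
    rain_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd <= 0 or not (0 <= self.noise_ar < 1):
            raise ValueError("noise_sd must be > 0 and 0 <= noise_ar < 1")
        if not (0 <= self.rh_mean <= 100) or not (0 <= self.rain_prob <= 1):
            raise ValueError("rh_mean must be in [0,100] and rain_prob in [0,1]")
        if self.seasonal_amplitude < 0 or self.diurnal_range < 0:
            raise ValueError("seasonal_amplitude and diurnal_range must be non-negative")


# JJA mean Tmax and Rh sized after large Korean metropolitan cities; the
# warming shift is the between-decade JJA mean difference being emulated.
CITY_DEFAULTS: dict[str, CityParams] = {
    "Seoul": CityParams("Seoul", 28.5, 1.0, 72.1),
    "Incheon": CityParams("Incheon", 27.8, -0.2, 77.9),
    "Gwangju": CityParams("Gwangju", 29.2, 1.2, 74.8),
    "Daegu": CityParams("Daegu", 29.7, 1.2, 69.7),
}


def simulate_weather(
    city: "CityParams | str",
    start_year: int = 1999,
    end_year: int = 2018,
    seed: int = 0,
    shift_start_year: int = 2009,
) -> pd.DataFrame:
    """Daily weather for ``city`` over whole calendar years.

    Tmax is a seasonal sinusoid (peak late July) plus a mean shift of
    ``warming_shift`` degC in years >= ``shift_start_year`` plus AR(1) daily
    noise with the stated marginal standard deviation. Tmin tracks Tmax
    minus the diurnal range with its own noise (never exceeding Tmax);
    relative humidity is anticorrelated with the Tmax anomaly and raised on
    wet days; precipitation is a Bernoulli-Gamma mixture. Deterministic
    under a fixed seed.
    """
    if isinstance(city, str):
        city = CITY_DEFAULTS[city]
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seas = np.cos(2.0 * np.pi * (doy - 210.0) / 365.25)
    jja = np.asarray(dates.month.isin(JJA_MONTHS))
    # anchor the *first-period* JJA mean at summer_tmax_mean
    base = city.summer_tmax_mean - city.seasonal_amplitude * seas[jja].mean()
    n = dates.size
    z = rng.standard_normal(n)
    eps = np.empty(n)
    innov_sd = city.noise_sd * np.sqrt(1.0 - city.noise_ar**2)
    eps[0] = city.noise_sd * z[0]
    for t in range(1, n):
        eps[t] = city.noise_ar * eps[t - 1] + innov_sd * z[t]
    shift = np.where(dates.year.to_numpy() >= shift_start_year, city.warming_shift, 0.0)
    tmax = base + city.seasonal_amplitude * seas + shift + eps
    tmin = tmax - city.diurnal_range + rng.normal(0.0, 1.0, n)
    tmin = np.minimum(tmin, tmax)
    wet = rng.random(n) < city.rain_prob
    prcp = np.where(wet, rng.gamma(0.7, 12.0, n), 0.0)
    rh = city.rh_mean - 0.8 * eps + 6.0 * wet + rng.normal(0.0, 5.0, n)
    rh = np.clip(rh, 5.0, 100.0)
    return pd.DataFrame(
        {
            "date": dates,
            "city": city.name,
            "tmax": tmax,
            "tmin": tmin,
            "rhavg": rh,
            "prcp": prcp,
        }
    )


@dataclass(frozen=True)
class StratumSpec:
    """One generating stratum (an exclusive demographic cell).

    ``baseline_log_rate`` is the log expected daily deaths with all other
    terms at zero; ``slope``/``slope_recent`` are the log-RR per degC of
    Tmax above the exposure threshold in the past and recent periods.
    Demographics are sampled per record, so a cell's decedents may fall into
    several analysis groups at once (groups are overlapping filters)."""

    name: str
    baseline_log_rate: float
    slope: float
    slope_recent: Optional[float] = None
    age_range: tuple[int, int] = (20, 64)
    marital_probs: tuple[tuple[str, float], ...] = (("married", 1.0),)
    education_probs: tuple[tuple[str, float], ...] = (("high", 1.0),)

    def slope_for(self, recent: bool) -> float:
        if recent and self.slope_recent is not None:
            return self.slope_recent
        return self.slope


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground truth of the mortality generator.

    Lag weights are geometric, ``decay**l`` over lags 0..max_lag, normalised
    to sum to one (or an explicit non-negative profile). The seasonal cycle
    peaks in mid-January (winter excess mortality); the trend is log-linear
    per year; weekday multipliers are on the log scale, Monday first.
    """

    strata: tuple[StratumSpec, ...]
    threshold_percentile: float = 60.0
    max_lag: int = 3
    lag_decay: float = 0.4
    lag_weights: Optional[tuple[float, ...]] = None
    seasonal_amplitude: float = 0.15
    seasonal_peak_doy: float = 15.0
    trend_per_year: float = -0.005
    weekday_log_effects: tuple[float, ...] = (0.01, 0.0, 0.0, 0.0, 0.01, -0.01, -0.01)
    external_cause_fraction: float = 0.08
    recent_start: str = "2009-01-01"

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if len(self.weekday_log_effects) != 7:
            raise ValueError("weekday_log_effects must have 7 entries (Monday first)")
        if not 0 <= self.external_cause_fraction < 1:
            raise ValueError("external_cause_fraction must be in [0, 1)")
        w = self.weights()
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("lag weights must be non-negative and finite")

    def weights(self) -> np.ndarray:
        """Normalised lag-weight profile over lags 0..max_lag."""
        if self.lag_weights is not None:
            w = np.asarray(self.lag_weights, dtype=float)
            if w.size != self.max_lag + 1:
                raise ValueError("lag_weights length must be max_lag + 1")
        else:
            w = self.lag_decay ** np.arange(self.max_lag + 1, dtype=float)
        return w / w.sum()


def default_truth() -> GeneratorTruth:
    """Default strata sized so group shares of summer mortality resemble a
    large ageing city: elderly dominate, with substantial overlap between
    the single-person and less-educated filters."""
    return GeneratorTruth(
        strata=(
            StratumSpec(
                "core_adult",
                baseline_log_rate=np.log(8.0),
                slope=0.02,
                age_range=(20, 64),
                marital_probs=(("married", 0.9), ("unmarried", 0.1)),
                education_probs=(("high", 0.6), ("tertiary", 0.4)),
            ),
            StratumSpec(
                "elderly",
                baseline_log_rate=np.log(25.0),
                slope=0.03,
                age_range=(65, 95),
                marital_probs=(("married", 0.5), ("bereaved", 0.45), ("divorced", 0.05)),
                education_probs=(("none", 0.3), ("elementary", 0.35), ("middle", 0.15), ("high", 0.2)),
            ),
            StratumSpec(
                "single_adult",
                baseline_log_rate=np.log(5.0),
                slope=0.035,
                age_range=(20, 64),
                marital_probs=(("unmarried", 0.5), ("divorced", 0.3), ("bereaved", 0.1), ("unknown", 0.1)),
                education_probs=(("middle", 0.3), ("high", 0.5), ("tertiary", 0.2)),
            ),
            StratumSpec(
                "low_edu_adult",
                baseline_log_rate=np.log(4.0),
                slope=0.03,
                age_range=(40, 64),
                marital_probs=(("married", 1.0),),
                education_probs=(("none", 0.2), ("elementary", 0.5), ("middle", 0.3)),
            ),
        )
    )


def resolve_threshold(truth: GeneratorTruth, weather: pd.DataFrame) -> float:
    """Exposure threshold in degC: the truth's percentile of pooled JJA Tmax."""
    jja = weather.loc[weather["date"].dt.month.isin(JJA_MONTHS), "tmax"]
    return float(np.percentile(jja.to_numpy(dtype=float), truth.threshold_percentile))


def _log_rate(
    weather: pd.DataFrame, truth: GeneratorTruth, stratum: StratumSpec, threshold_c: float
) -> np.ndarray:
    dates = pd.to_datetime(weather["date"]).reset_index(drop=True)
    tmax = weather["tmax"].to_numpy(dtype=float)
    n = tmax.size
    excess = np.clip(tmax - threshold_c, 0.0, None)
    w = truth.weights()
    lagged = np.zeros(n)
    for l, wl in enumerate(w):
        shifted = np.zeros(n)
        shifted[l:] = excess[: n - l]
        lagged += wl * shifted
    recent = (dates >= pd.Timestamp(truth.recent_start)).to_numpy()
    slope = np.where(recent, stratum.slope_for(True), stratum.slope_for(False))
    doy = dates.dt.dayofyear.to_numpy(dtype=float)
    seasonal = truth.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - truth.seasonal_peak_doy) / 365.25
    )
    years = (dates - dates.iloc[0]).dt.days.to_numpy(dtype=float) / 365.25
    weekday = np.asarray(truth.weekday_log_effects)[dates.dt.dayofweek.to_numpy()]
    log_rate = stratum.baseline_log_rate + slope * lagged + seasonal + truth.trend_per_year * years + weekday
    if np.any(log_rate > 20.0):
        raise ValueError("log death rate exceeds 20; generator misconfigured")
    return log_rate


def simulate_death_counts(
    weather: pd.DataFrame,
    truth: GeneratorTruth,
    stratum: StratumSpec,
    seed: int = 0,
    threshold_c: Optional[float] = None,
) -> np.ndarray:
    """Daily Poisson death counts for one stratum, aligned with ``weather``."""
    if threshold_c is None:
        threshold_c = resolve_threshold(truth, weather)
    rng = np.random.default_rng(seed)
    return rng.poisson(np.exp(_log_rate(weather, truth, stratum, threshold_c)))


def _sample_categorical(rng, table: tuple[tuple[str, float], ...], size: int) -> np.ndarray:
    labels = [t[0] for t in table]
    probs = np.asarray([t[1] for t in table], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=size, p=probs)


def simulate_deaths(
    weather: pd.DataFrame, truth: GeneratorTruth, seed: int = 0
) -> pd.DataFrame:
    """Record-level deaths for all strata of ``truth`` over ``weather``.

    Daily stratum counts are Poisson draws from the generator's log-rate,
    expanded to one record per death with demographics sampled per stratum.
    A further temperature-independent stream of external-cause records
    (ICD-10 chapters S/T/V/W/X/Y, ``external_cause_fraction`` of the total
    in expectation) is injected to exercise the cause-of-death filter.
    Byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    threshold_c = resolve_threshold(truth, weather)
    dates = pd.to_datetime(weather["date"]).reset_index(drop=True)
    city = str(weather["city"].iloc[0]) if "city" in weather else ""
    frames: list[pd.DataFrame] = []
    total_internal_rate = 0.0
    for stratum in truth.strata:
        rate = np.exp(_log_rate(weather, truth, stratum, threshold_c))
        total_internal_rate += float(rate.mean())
        counts = rng.poisson(rate)
        m = int(counts.sum())
        if m == 0:
            continue
        rec_dates = np.repeat(dates.to_numpy(), counts)
        lo, hi = stratum.age_range
        frames.append(
            pd.DataFrame(
                {
                    "date": rec_dates,
                    "city": city,
                    "age": rng.integers(lo, hi + 1, size=m),
                    "marital_status": _sample_categorical(rng, stratum.marital_probs, m),
                    "education": _sample_categorical(rng, stratum.education_probs, m),
                    "icd10": rng.choice(_INTERNAL_CHAPTERS, size=m, p=_INTERNAL_PROBS),
                    "stratum": stratum.name,
                }
            )
        )
    f = truth.external_cause_fraction
    if f > 0:
        ext_rate = total_internal_rate * f / (1.0 - f)
        counts = rng.poisson(ext_rate, size=dates.size)
        m = int(counts.sum())
        if m > 0:
            frames.append(
                pd.DataFrame(
                    {
                        "date": np.repeat(dates.to_numpy(), counts),
                        "city": city,
                        "age": rng.integers(20, 90, size=m),
                        "marital_status": rng.choice(
                            ["married", "unmarried", "divorced"], size=m, p=[0.6, 0.3, 0.1]
                        ),
                        "education": rng.choice(["elementary", "high", "tertiary"], size=m),
                        "icd10": rng.choice(_EXTERNAL_CHAPTERS, size=m),
                        "stratum": "external",
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["date", "city", "age", "marital_status", "education", "icd10", "stratum"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["date", "stratum"], kind="stable").reset_index(drop=True)


def true_percent_change(
    truth: GeneratorTruth,
    bins: HeatDayBins,
    reference_temp: float,
    tmax_upper: float,
    threshold_c: float,
    stratum: Optional[StratumSpec] = None,
    recent: bool = False,
) -> dict[str, float]:
    """Closed-form percent change per 1 degC implied by the generator.

    The generator's cumulative log-RR at T vs the reference is
    ``s * [(T - thr)_+ - (ref - thr)_+]``; the statistic is evaluated with
    the same 1 degC grid rule as the risk module, per heat-day bin."""
    if stratum is None:
        stratum = truth.strata[0]
    s = stratum.slope_for(recent)

    def rr(t: np.ndarray) -> np.ndarray:
        base = np.clip(np.asarray(t, float) - threshold_c, 0.0, None)
        ref = max(0.0, reference_temp - threshold_c)
        return np.exp(s * (base - ref))

    out: dict[str, float] = {}
    for label in ("Mild", "Moderate", "Severe"):
        lower, upper = bins.bin_range(label, tmax_upper)
        if upper - lower < 1.0:
            # mirrors the analysis-side NA discipline for degenerate bins
            out[label] = float("nan")
            continue
        grid = bin_grid(lower, upper)
        vals = rr(grid)
        out[label] = float((vals[-1] - vals[0]) / (grid.size - 1) * 100.0)
    return out
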