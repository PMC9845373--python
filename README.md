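# heatdlnm

Distributed-lag non-linear Poisson modelling of heat-day mortality, with a
synthetic study generator.

## The problem

Epidemiologists comparing the health impact of hot days across decades or
population groups fit Poisson time-series regressions of daily death counts
on daily maximum temperature, letting the effect act non-linearly in
temperature and be distributed over several days of lag. This package
implements that analysis end to end for a two-period, multi-city summer
study design — including the vulnerable-group stratification (elderly,
single-person households, less-educated) used in heatwave-adaptation
research — together with a synthetic-data generator with known ground
truth, so the whole pipeline can be exercised and validated without access
to restricted national mortality microdata.

## The model

Daily deaths $y_t$ in one city × group × period stratum follow

$$\ln E(y_t) = \alpha + \beta\,\mathrm{CB}(T^{max})_{t,\ell}
  + NS(rh_t) + NS(prcp_t) + NS(doy_t) + NS(sn_t) + \gamma\,weekday_t,
  \qquad y_t \sim \mathrm{Poisson},$$

where $\mathrm{CB}$ is the cross-basis of a distributed lag non-linear
model (DLNM): a tensor product of a natural cubic spline over temperature
and a natural cubic spline over lag $\ell = 0..L$. $NS(\cdot)$ are natural
spline confounder terms for mean relative humidity, precipitation, day of
year (within-season cycle) and the sequential serial number of the date
(long-term trend); $weekday_t$ are day-of-week dummies. The maximum lag
$L$ is chosen by AIC over a candidate set; fitting is maximum likelihood by
IRLS.

From a fitted model the package derives the cumulative (summed over lags)
relative risk $RR(T)$ against a reference temperature (default: the 60th
percentile of pooled summer Tmax, where heat effects start to appear), and
summarises each heat-day bin — Mild (60th–90th percentile of summer Tmax),
Moderate (90th–99th), Severe (≥ 99th) — by the percent change of RR per
1 °C:

$$\text{percent change} = \frac{RR_n - RR_1}{n-1}\times 100,$$

with $RR_1, RR_n$ the first and last values on the bin's 1 °C grid.
Confidence intervals are Monte-Carlo over the asymptotic distribution of
the cross-basis coefficients.

## Worked example

Fit one simulated decade (Seoul-like weather, elderly stratum with a known
exposure slope of 0.03 log-RR per °C above the summer 60th percentile):

```python
import numpy as np
import heatdlnm as h
from heatdlnm.glm import build_confounders
from heatdlnm.splines import CrossBasisSpec, crossbasis

truth = h.default_truth()
weather = h.simulate_weather("Seoul", 1999, 2008, seed=42)
stratum = truth.strata[1]                      # the elderly cell
counts = h.simulate_death_counts(weather, truth, stratum, seed=43)

jja = np.asarray(weather["date"].dt.month.isin((6, 7, 8)))
summer_tmax = weather["tmax"].to_numpy()[jja]
bins = h.heat_day_bins(summer_tmax)
print(f"thresholds: p60={bins.p60:.1f}  p90={bins.p90:.1f}  p99={bins.p99:.1f} degC")

conf = build_confounders(weather["date"], weather["rhavg"].to_numpy(),
                         weather["prcp"].to_numpy())
cb = crossbasis(weather["tmax"].to_numpy(),
                CrossBasisSpec.default(summer_tmax, max_lag=3))
result = h.PoissonDLNM(counts, cb, confounders=conf, fit_mask=jja).fit()
print(f"converged={result.converged}  n={result.n_obs}  AIC={result.aic:.1f}")

ref = bins.p60
for label in ("Mild", "Moderate", "Severe"):
    lo, hi = bins.bin_range(label, summer_tmax.max())
    pc = result.percent_change(lo, hi, ref, label)
    ci = result.percent_change_ci(lo, hi, ref, n_draws=2000, seed=7)
    print(f"{label:<9} {pc.value:5.2f} %/degC  (95% CI {ci[0]:.2f} ~ {ci[1]:.2f})")
```

Output:

```
thresholds: p60=29.4  p90=32.2  p99=34.7 degC
converged=True  n=920  AIC=5513.1
Mild       3.34 %/degC  (95% CI 0.68 ~ 6.01)
Moderate   2.87 %/degC  (95% CI -2.04 ~ 8.11)
Severe     0.53 %/degC  (95% CI -9.71 ~ 15.70)
```

The generator's closed-form truth for this stratum is 3.09 / 3.36 / 3.63
%/°C in the three bins; single-decade estimates scatter around it (the
Severe bin rests on the ~9 hottest days of each summer, hence the wide
interval), and the replication studies below show the estimator is
well-calibrated on average.

`result.summary()` returns the full coefficient table;
`result.predict_rr(grid, ref)` the RR curve with pointwise bands.

## Command line

```sh
heatdlnm simulate --config config.yml --out data/ --seed 1
heatdlnm fit --weather data/weather.csv --deaths data/deaths.csv \
             --config config.yml --out out/
heatdlnm compare --out out/         # period-comparison pivot table
heatdlnm describe --weather data/weather.csv --config config.yml
```

`fit` writes a comparison table (one row per city × group × period × bin),
per-stratum RR-curve CSVs, the AIC table, and a JSON run manifest; bins
with no days in a period are reported NA with a reason code. `describe`
tabulates p90days / p99days / tropical nights (Tmin ≥ 25 °C) per period.

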