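import logging

import numpy as np
import pandas as pd
import pytest

import heatdlnm as h

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def decade_weather() -> pd.DataFrame:
    """One decade of daily Seoul-like weather (1999-2008), fixed seed."""
    return h.simulate_weather("Seoul", 1999, 2008, seed=101)


@pytest.fixture(scope="session")
def jja_mask(decade_weather) -> np.ndarray:
    return np.asarray(decade_weather["date"].dt.month.isin((6, 7, 8)))


@pytest.fixture(scope="session")
def truth() -> h.GeneratorTruth:
    return h.default_truth()


@pytest.fixture(scope="session")
def fitted_stratum(decade_weather, jja_mask, truth):
    """A converged fit of the elderly stratum on the decade, with the
    derived bins/reference — shared by risk and acceptance tests."""
    from heatdlnm.glm import build_confounders
    from heatdlnm.splines import CrossBasisSpec, crossbasis

    w = decade_weather
    thr = h.resolve_threshold(truth, w)
    stratum = truth.strata[1]
    counts = h.simulate_death_counts(w, truth, stratum, seed=202, threshold_c=thr)
    tj = w["tmax"].to_numpy()[jja_mask]
    bins = h.heat_day_bins(tj)
    conf = build_confounders(w["date"], w["rhavg"].to_numpy(), w["prcp"].to_numpy())
    spec = CrossBasisSpec.default(tj, truth.max_lag)
    cb = crossbasis(w["tmax"].to_numpy(), spec)
    res = h.PoissonDLNM(counts, cb, confounders=conf, fit_mask=jja_mask).fit()
    assert res.converged
    return {
        "result": res,
        "bins": bins,
        "reference": bins.p60,
        "tmax_upper": float(tj.max()),
        "threshold": thr,
        "stratum": stratum,
        "counts": counts,
    }


@pytest.fixture()
def small_records() -> pd.DataFrame:
    """Small hand-checkable record table spanning two days and two cities."""
    return pd.DataFrame(
        {
            "date": pd.to_datetime(
                ["2000-07-01", "2000-07-01", "2000-07-01", "2000-07-02", "2000-07-02"]
            ),
            "city": ["A", "A", "B", "A", "B"],
            "age": [70, 30, 85, 19, 50],
            "marital_status": ["bereaved", "divorced", "married", "unmarried", "married"],
            "education": ["elementary", "high", "none", "high", "middle"],
            "icd10": ["I21", "C34", "J18", "I50", "E11"],
        }
    )
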