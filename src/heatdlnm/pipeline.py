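"""Study orchestration: validate inputs, classify and aggregate deaths,
fit one Poisson DLNM per city x group x period, and tabulate per-bin
percent changes of relative risk with confidence intervals.

Vulnerable groups are overlapping filters over record-level deaths, not a
partition: "All" is every retained (non-external-cause) record, elderly is
age >= 65, single-person household is age >= 20 with marital status
unmarried/unknown/divorced/bereaved, less-educated is education at or below
middle school. External causes of death (ICD-10 chapters outside A-R) are
excluded before any aggregation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glm import ConfounderConfig, DLNMResults, LagSelection, build_confounders, select_lag
from .risk import BIN_LABELS, HeatDayBins, bin_grid, heat_day_bins, percent_change, percent_change_ci
from .splines import crossbasis
from .synthetic import JJA_MONTHS

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "classify_record",
    "classify_records",
    "filter_causes",
    "FilterReport",
    "aggregate_daily",
    "count_threshold_days",
    "run_study",
    "write_outputs",
    "read_weather_csv",
    "read_deaths_csv",
]

GROUPS = ("All", "elderly", "single_person", "less_educated")

_MARITAL_VALUES = {"married", "unmarried", "unknown", "divorced", "bereaved"}
_EDUCATION_VALUES = {"none", "elementary", "middle", "high", "tertiary"}
_SINGLE_MARITAL = {"unmarried", "unknown", "divorced", "bereaved"}
_LOW_EDUCATION = {"none", "elementary", "middle"}


@dataclass
class StudyConfig:
    """Everything needed to reproduce a run; loadable from YAML.

    Periods are two non-overlapping (start, end) date spans, by default the
    decades 1999-2008 and 2009-2018. All spline/lag/reference defaults are
    overridable here.
    """

    cities: tuple[str, ...] = ("Seoul", "Incheon", "Gwangju", "Daegu")
    periods: tuple[tuple[str, str], ...] = (
        ("1999-01-01", "2008-12-31"),
        ("2009-01-01", "2018-12-31"),
    )
    period_labels: tuple[str, ...] = ("past", "recent")
    groups: tuple[str, ...] = GROUPS
    candidate_lags: tuple[int, ...] = (0, 3, 7, 14, 21)
    var_knot_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0)
    rh_df: int = 3
    prcp_df: int = 3
    doy_df: int = 4
    sn_df_per_decade: int = 1
    weekday: bool = True
    jja_only: bool = True
    pooled_bins: bool = True
    reference: "str | float" = "p60"
    n_draws: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.periods) != len(self.period_labels):
            raise ValueError("periods and period_labels must have equal length")
        spans = [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.periods]
        for a, b in spans:
            if a > b:
                raise ValueError("period start after end")
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("periods must be non-overlapping and ordered")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")

    @property
    def confounders(self) -> ConfounderConfig:
        return ConfounderConfig(
            self.rh_df, self.prcp_df, self.doy_df, self.sn_df_per_decade, self.weekday
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cities"] = list(self.cities)
        d["periods"] = [list(p) for p in self.periods]
        d["period_labels"] = list(self.period_labels)
        d["groups"] = list(self.groups)
        d["candidate_lags"] = list(self.candidate_lags)
        d["var_knot_percentiles"] = list(self.var_knot_percentiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("cities", "period_labels", "groups", "candidate_lags", "var_knot_percentiles"):
            if key in d:
                d[key] = tuple(d[key])
        if "periods" in d:
            d["periods"] = tuple(tuple(p) for p in d["periods"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: "str | Path") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# record-level operations


def classify_record(rec) -> set[str]:
    """Group labels of one death record (mapping or namedtuple-like with
    ``age``, ``marital_status``, ``education``). Groups overlap; every
    record (already cause-filtered) is in "All"."""
    get = rec.get if hasattr(rec, "get") else lambda k: getattr(rec, k)
    age = get("age")
    marital = get("marital_status")
    education = get("education")
    if marital not in _MARITAL_VALUES:
        raise ValueError(f"unknown marital_status value: {marital!r}")
    if education not in _EDUCATION_VALUES:
        raise ValueError(f"unknown education value: {education!r}")
    if age < 0:
        raise ValueError(f"negative age: {age}")
    labels = {"All"}
    if age >= 65:
        labels.add("elderly")
    if age >= 20 and marital in _SINGLE_MARITAL:
        labels.add("single_person")
    if education in _LOW_EDUCATION:
        labels.add("less_educated")
    return labels


def classify_records(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification: one boolean column per group."""
    bad = set(records["marital_status"].unique()) - _MARITAL_VALUES
    if bad:
        raise ValueError(f"unknown marital_status value: {sorted(bad)[0]!r}")
    bad = set(records["education"].unique()) - _EDUCATION_VALUES
    if bad:
        raise ValueError(f"unknown education value: {sorted(bad)[0]!r}")
    age = records["age"].to_numpy()
    out = pd.DataFrame(index=records.index)
    out["All"] = True
    out["elderly"] = age >= 65
    out["single_person"] = (age >= 20) & records["marital_status"].isin(_SINGLE_MARITAL).to_numpy()
    out["less_educated"] = records["education"].isin(_LOW_EDUCATION).to_numpy()
    return out


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_external: int
    n_quarantined: int
    quarantined: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def filter_causes(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Keep deaths whose ICD-10 chapter letter is A-R; drop external causes
    (S onwards). Malformed codes are quarantined with a report, never
    silently dropped. The chapter is the first letter of the ``icd10``
    column (full codes accepted)."""
    codes = records["icd10"].astype(str).str.strip().str.upper()
    first = codes.str[:1]
    wellformed = first.str.match(r"[A-Z]") & (codes.str.len() > 0)
    chapter_ok = first.between("A", "R")
    kept = records.loc[wellformed & chapter_ok].copy()
    external = int((wellformed & ~chapter_ok).sum())
    quarantined = records.loc[~wellformed].copy()
    report = FilterReport(len(records), len(kept), external, len(quarantined), quarantined)
    logger.info(
        "cause filter: %d records in, %d kept, %d external excluded, %d quarantined",
        report.n_input,
        report.n_kept,
        report.n_external,
        report.n_quarantined,
    )
    return kept, report


def aggregate_daily(
    records: pd.DataFrame,
    groups: Sequence[str],
    span: tuple[str, str],
    cities: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Daily death counts per date x city x group, zero-filled over the full
    span. Groups are overlapping: a record increments every group it
    belongs to. Records dated outside the span are excluded with a warning
    count in the log."""
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    recs = records.copy()
    recs["date"] = pd.to_datetime(recs["date"])
    inside = recs["date"].between(start, end)
    if (~inside).any():
        logger.warning("%d records outside the study span excluded", int((~inside).sum()))
    recs = recs.loc[inside]
    if cities is None:
        cities = sorted(recs["city"].unique())
    membership = classify_records(recs)
    all_dates = pd.date_range(start, end, freq="D")
    pieces = []
    for group in groups:
        sub = recs.loc[membership[group].to_numpy()]
        counts = sub.groupby(["city", "date"]).size()
        for city in cities:
            if len(counts) and city in counts.index.get_level_values(0):
                series = counts.xs(city)
            else:
                series = pd.Series(dtype=float)
            filled = series.reindex(all_dates, fill_value=0).astype(int)
            pieces.append(
                pd.DataFrame(
                    {"date": all_dates, "city": city, "group": group, "deaths": filled.to_numpy()}
                )
            )
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# descriptives


def count_threshold_days(
    weather: pd.DataFrame,
    thresholds: dict[str, HeatDayBins],
    periods: Sequence[tuple[str, str]],
    period_labels: Sequence[str] = ("past", "recent"),
) -> pd.DataFrame:
    """Summer day counts above pooled thresholds, per city and period.

    p90days / p99days count JJA days with Tmax above the pooled 90th / 99th
    percentile; tmin25days counts JJA days whose Tmin never falls below
    25 degC (tropical nights). The percent change column compares the last
    period against the first, undefined (NaN) when the first is zero."""
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    w = w.loc[w["date"].dt.month.isin(JJA_MONTHS)]
    rows = []
    for city, bins in thresholds.items():
        cw = w.loc[w["city"] == city]
        per_period: dict[str, dict[str, int]] = {}
        for (start, end), label in zip(periods, period_labels):
            sub = cw.loc[cw["date"].between(pd.Timestamp(start), pd.Timestamp(end))]
            if sub.empty:
                raise ValueError(f"no weather for city {city} in period {label}")
            per_period[label] = {
                "p90days": int((sub["tmax"] > bins.p90).sum()),
                "p99days": int((sub["tmax"] > bins.p99).sum()),
                "tmin25days": int((sub["tmin"] >= 25.0).sum()),
            }
        first, last = period_labels[0], period_labels[-1]
        for metric in ("p90days", "p99days", "tmin25days"):
            past_v = per_period[first][metric]
            recent_v = per_period[last][metric]
            pct = (recent_v - past_v) / past_v * 100.0 if past_v > 0 else np.nan
            row = {"city": city, "metric": metric, "pct_change": pct}
            for label in period_labels:
                row[label] = per_period[label][metric]
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the study driver


@dataclass
class StudyResult:
    comparison: pd.DataFrame
    rr_curves: dict[tuple[str, str, str], pd.DataFrame]
    aic_tables: pd.DataFrame
    bins: dict[str, HeatDayBins]
    fits: dict[tuple[str, str, str], DLNMResults]
    filter_report: Optional[FilterReport]
    failures: list[dict]
    manifest: dict


def _stratum_seed(base_seed: int, *parts: str) -> int:
    tag = zlib.crc32("|".join(parts).encode())
    return int((base_seed * 1_000_003 + tag) % (2**31 - 1))


def _bin_day_count(tmax: np.ndarray, bins: HeatDayBins, label: str) -> int:
    if label == "Mild":
        return int(((tmax >= bins.p60) & (tmax < bins.p90)).sum())
    if label == "Moderate":
        return int(((tmax >= bins.p90) & (tmax < bins.p99)).sum())
    return int((tmax >= bins.p99).sum())


def run_study(
    config: StudyConfig,
    weather: pd.DataFrame,
    death_records: Optional[pd.DataFrame] = None,
    mortality: Optional[pd.DataFrame] = None,
) -> StudyResult:
    """Run the full comparison study.

    Either record-level ``death_records`` (filtered, classified and
    aggregated here) or a pre-aggregated ``mortality`` series
    (date/city/group/deaths) must be supplied. For every city x group x
    period: build the cross-basis on the period's weather, select the lag
    window by AIC, fit the Poisson DLNM on summer days, derive the
    cumulative RR curve against the reference temperature, and compute the
    per-bin percent change of RR per 1 degC with Monte-Carlo intervals.
    Bins with no days in a period are reported NA with a reason code.
    Stratum failures are recorded and the run continues.
    """
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    for col in ("city", "tmax", "rhavg", "prcp"):
        if col not in weather.columns:
            raise ValueError(f"weather input missing required column {col!r}")
    span = (config.periods[0][0], config.periods[-1][1])
    filter_report = None
    if mortality is None:
        if death_records is None:
            raise ValueError("need death_records or mortality")
        kept, filter_report = filter_causes(death_records)
        mortality = aggregate_daily(kept, config.groups, span, config.cities)
    mortality = mortality.copy()
    mortality["date"] = pd.to_datetime(mortality["date"])

    bins_by_city: dict[str, HeatDayBins] = {}
    ref_by_city: dict[str, float] = {}
    max_by_city: dict[str, float] = {}
    full_start, full_end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    for city in config.cities:
        cw = weather.loc[(weather["city"] == city) & weather["date"].between(full_start, full_end)]
        if cw.empty:
            raise ValueError(f"no weather rows for city {city!r}")
        jja = cw.loc[cw["date"].dt.month.isin(JJA_MONTHS), "tmax"].to_numpy(dtype=float)
        bins_by_city[city] = heat_day_bins(jja, source=f"{city} pooled {span[0]}..{span[1]}")
        max_by_city[city] = float(jja.max())
        ref_by_city[city] = (
            bins_by_city[city].p60 if config.reference == "p60" else float(config.reference)
        )

    comparison_rows: list[dict] = []
    aic_rows: list[pd.DataFrame] = []
    rr_curves: dict[tuple[str, str, str], pd.DataFrame] = {}
    fits: dict[tuple[str, str, str], DLNMResults] = {}
    failures: list[dict] = []

    for city in config.cities:
        bins = bins_by_city[city]
        ref = ref_by_city[city]
        pooled_max = max_by_city[city]
        for (start, end), plabel in zip(config.periods, config.period_labels):
            p_start, p_end = pd.Timestamp(start), pd.Timestamp(end)
            cw = (
                weather.loc[(weather["city"] == city) & weather["date"].between(p_start, p_end)]
                .sort_values("date")
                .reset_index(drop=True)
            )
            jja_mask = cw["date"].dt.month.isin(JJA_MONTHS).to_numpy()
            fit_mask = jja_mask if config.jja_only else np.ones(len(cw), dtype=bool)
            confounders = build_confounders(
                cw["date"], cw["rhavg"].to_numpy(), cw["prcp"].to_numpy(), config.confounders
            )
            period_jja_tmax = cw.loc[jja_mask, "tmax"].to_numpy(dtype=float)
            for group in config.groups:
                key = (city, group, plabel)
                logger.info("fitting %s / %s / %s", city, group, plabel)
                try:
                    dm = mortality.loc[
                        (mortality["city"] == city) & (mortality["group"] == group)
                    ].set_index("date")["deaths"]
                    deaths = dm.reindex(cw["date"], fill_value=0).to_numpy(dtype=float)
                    sel = select_lag(
                        config.candidate_lags,
                        cw["tmax"].to_numpy(dtype=float),
                        deaths,
                        confounders=confounders,
                        fit_mask=fit_mask,
                        var_knot_percentiles=config.var_knot_percentiles,
                    )
                    res = sel.fits[sel.chosen]
                    fits[key] = res
                    tab = sel.table.copy()
                    tab.insert(0, "period", plabel)
                    tab.insert(0, "group", group)
                    tab.insert(0, "city", city)
                    tab["chosen"] = tab["max_lag"] == sel.chosen
                    aic_rows.append(tab)
                    grid_lo = min(ref - 5.0, float(period_jja_tmax.min()))
                    grid = np.round(np.arange(grid_lo, pooled_max + 0.25, 0.25), 6)
                    curve = res.predict_rr(grid, ref)
                    rr_curves[key] = pd.DataFrame(
                        {
                            "temp": curve.temp_grid,
                            "rr": curve.rr,
                            "lower95": curve.lower95,
                            "upper95": curve.upper95,
                        }
                    )
                    for label in BIN_LABELS:
                        lower, upper = bins.bin_range(label, pooled_max)
                        n_days = _bin_day_count(period_jja_tmax, bins, label)
                        row = {
                            "city": city,
                            "group": group,
                            "period": plabel,
                            "bin": label,
                            "n_days": n_days,
                            "max_lag": sel.chosen,
                            "pct_change": np.nan,
                            "lower95": np.nan,
                            "upper95": np.nan,
                            "n_points": 0,
                            "significant": False,
                            "reason": "",
                        }
                        if n_days == 0:
                            row["reason"] = "no_days_in_period"
                        elif upper - lower < 1.0:
                            row["reason"] = "bin_narrower_than_1c"
                        else:
                            pc = percent_change(
                                res.predict_rr(bin_grid(lower, upper), ref), (lower, upper), label
                            )
                            lo95, hi95 = percent_change_ci(
                                res,
                                res.cb_spec,
                                (lower, upper),
                                ref,
                                n_draws=config.n_draws,
                                seed=_stratum_seed(config.seed, city, group, plabel, label),
                            )
                            row.update(
                                pct_change=pc.value,
                                lower95=lo95,
                                upper95=hi95,
                                n_points=pc.n_points,
                                significant=bool(lo95 > 0 or hi95 < 0),
                            )
                        comparison_rows.append(row)
                except Exception as exc:  # noqa: BLE001 - stratum failures must not kill the run
                    logger.exception("stratum %s failed", key)
                    failures.append({"city": city, "group": group, "period": plabel, "error": str(exc)})

    comparison = pd.DataFrame(comparison_rows)
    aic_tables = pd.concat(aic_rows, ignore_index=True) if aic_rows else pd.DataFrame()
    manifest = {
        "package": "heatdlnm",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_weather_rows": int(len(weather)),
        "n_strata_fitted": len(fits),
        "n_failures": len(failures),
        "bins": {
            c: {"p60": b.p60, "p90": b.p90, "p99": b.p99} for c, b in bins_by_city.items()
        },
        "reference_temp": ref_by_city,
    }
    if filter_report is not None:
        manifest["cause_filter"] = {
            "n_input": filter_report.n_input,
            "n_kept": filter_report.n_kept,
            "n_external": filter_report.n_external,
            "n_quarantined": filter_report.n_quarantined,
        }
    return StudyResult(
        comparison, rr_curves, aic_tables, bins_by_city, fits, filter_report, failures, manifest
    )


# ---------------------------------------------------------------------------
# I/O


def read_weather_csv(path: "str | Path") -> pd.DataFrame:
    """Weather CSV: date (ISO-8601), city, tmax, tmin, rhavg, prcp."""
    df = pd.read_csv(path)
    missing = {"date", "city", "tmax", "tmin", "rhavg", "prcp"} - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_deaths_csv(path: "str | Path") -> pd.DataFrame:
    """Record-level deaths CSV: date, city, age, marital_status, education,
    icd10 (chapter letter or full code; first letter used)."""
    df = pd.read_csv(path)
    missing = {"date", "city", "age", "marital_status", "education", "icd10"} - set(df.columns)
    if missing:
        raise ValueError(f"deaths CSV missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_outputs(result: StudyResult, outdir: "str | Path") -> None:
    """Write comparison table, per-stratum RR curves, AIC table and a JSON
    run manifest (config hash, seeds, versions) into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.comparison.to_csv(out / "comparison.csv", index=False)
    result.aic_tables.to_csv(out / "aic.csv", index=False)
    for (city, group, period), curve in result.rr_curves.items():
        curve.to_csv(out / f"rr_curve_{city}_{group}_{period}.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
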