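"""Cumulative passage curves, the Annual Anomaly (AA), percentile dates and trends.

The Annual Anomaly is a single per-season timing statistic: the signed area,
in days, between a season's cumulative passage curve and a multi-year
baseline curve,

    AA_y = sum_d [ Cbar(d) - C_y(d) ],

so a season whose passage runs ahead of the baseline (curve above it) gets a
negative AA — earlier than average — and a late season a positive AA. An
exact k-day shift of the whole passage (mass staying inside the window)
yields AA = +/- k.

Curves are length-agnostic so toy windows can be used in tests; the
station analysis always uses the fixed 45-day spring window.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .catch_records import CatchArchive, SpringSeries
from .errors import AnalysisError

#: year number convention: the first study year (1982) is year 1
YEAR_ORIGIN = 1981


@dataclasses.dataclass
class CumulativeCurve:
    """Nondecreasing daily cumulative fractions (0..1) of a season's passage."""

    label: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise AnalysisError("curve must be a nonempty 1-D fraction array")
        if np.any(np.diff(f) < -1e-12):
            raise AnalysisError(f"curve {self.label!r} not nondecreasing")
        self.fractions = f

    def __len__(self) -> int:
        return self.fractions.size


@dataclasses.dataclass
class PercentileDates:
    """First-crossing dates of the 10/50/90% passage levels for one season."""

    label: str
    d10: int
    d50: int
    d90: int

    @property
    def duration(self) -> int:
        return self.d90 - self.d10


@dataclasses.dataclass
class TrendFit:
    """OLS of an annual response on year number (1982 = year 1)."""

    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    r_squared: float
    n: int
    stderr: float

    def predict(self, year: int) -> float:
        return self.intercept + self.slope * (year - YEAR_ORIGIN)

    def total_change(self, span_years: int = 36) -> float:
        """Change over the whole study period, slope x span."""
        return self.slope * span_years


@dataclasses.dataclass
class AnomalySeries:
    """Per-year AA values in days; trend-imputed gap years flagged separately."""

    values: dict[int, float]
    imputed_years: set[int] = dataclasses.field(default_factory=set)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values).sort_index()


def cumulative_curve(series: SpringSeries | np.ndarray, label: str | None = None) -> CumulativeCurve:
    """Cumulative daily fraction curve of one season's counts."""
    if isinstance(series, SpringSeries):
        counts = series.counts
        label = label or str(series.year)
        if series.missing_days:
            raise AnalysisError(
                f"year {series.year} still has missing days; impute first"
            )
    else:
        counts = np.asarray(series, dtype=float)
        label = label or "curve"
    total = counts.sum()
    if total <= 0:
        raise AnalysisError(f"curve {label!r}: season total is zero")
    return CumulativeCurve(label, np.cumsum(counts) / total)


def baseline_curve(archive: CatchArchive, method: str = "pooled") -> CumulativeCurve:
    """Multi-year baseline passage curve.

    ``pooled`` (default): cumulative fractions of the across-years sum of
    daily counts. ``mean_of_curves``: per-day arithmetic mean of the annual
    fraction curves (this variant makes the included years' AA values sum to
    zero exactly).
    """
    if len(archive.series) < 2:
        raise AnalysisError("baseline requires at least 2 included years")
    if method == "pooled":
        summed = np.sum([s.counts for s in archive.series.values()], axis=0)
        return CumulativeCurve("baseline:pooled", np.cumsum(summed) / summed.sum())
    if method == "mean_of_curves":
        curves = [cumulative_curve(s).fractions for s in archive.series.values()]
        return CumulativeCurve("baseline:mean_of_curves", np.mean(curves, axis=0))
    raise AnalysisError(f"unknown baseline method {method!r}")


def annual_anomaly(curve: CumulativeCurve, baseline: CumulativeCurve) -> float:
    """Annual Anomaly in days: sum over days of (baseline - year) fractions."""
    if len(curve) != len(baseline):
        raise AnalysisError(
            f"window mismatch: {len(curve)} vs {len(baseline)} days"
        )
    return float(np.sum(baseline.fractions - curve.fractions))


def percentile_dates(
    curve: CumulativeCurve, levels: tuple[float, float, float] = (0.10, 0.50, 0.90)
) -> PercentileDates:
    """First ordinal day whose cumulative fraction reaches each level."""
    f = curve.fractions
    days = []
    for p in levels:
        idx = int(np.searchsorted(f, p - 1e-12, side="left"))
        if idx >= f.size:  # total < 1 cannot happen for a valid season curve
            idx = f.size - 1
        days.append(idx + 1)
    return PercentileDates(curve.label, *days)


def trend_regression(values: Mapping[int, float]) -> TrendFit:
    """Least-squares linear trend of an annual response against year number.

    Years need not be consecutive: excluded seasons are simply absent.
    """
    years = np.array(sorted(values), dtype=float)
    if years.size < 3:
        raise AnalysisError("trend regression needs at least 3 years")
    if np.ptp(years) == 0:
        raise AnalysisError("trend regression needs distinct years")
    y = np.array([values[int(t)] for t in years])
    x = years - YEAR_ORIGIN
    if np.ptp(y) == 0:  # constant response: flat trend by convention
        return TrendFit(slope=0.0, intercept=float(y[0]), t_statistic=0.0,
                        p_value=1.0, r_squared=0.0, n=int(years.size), stderr=0.0)
    res = stats.linregress(x, y)
    if res.stderr == 0:
        t_stat, p = np.inf, 0.0
        if res.slope == 0:  # constant response: slope 0, R^2 0 by convention
            t_stat, p = 0.0, 1.0
    else:
        t_stat = res.slope / res.stderr
        p = res.pvalue
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        t_statistic=float(t_stat),
        p_value=float(p),
        r_squared=float(res.rvalue**2),
        n=int(years.size),
        stderr=float(res.stderr),
    )


def anomaly_series(archive: CatchArchive, method: str = "pooled") -> AnomalySeries:
    """AA for every included year against the archive's baseline."""
    base = baseline_curve(archive, method)
    vals = {
        y: annual_anomaly(cumulative_curve(s), base)
        for y, s in sorted(archive.series.items())
    }
    return AnomalySeries(vals)


def impute_missing_anomalies(
    series: AnomalySeries, all_years: Iterable[int]
) -> AnomalySeries:
    """Fill gap years with trend-predicted AA values.

    The filled values exist only so the autocorrelation screen can run on a
    gapless series; they are flagged and must never enter the climate
    regression.
    """
    missing = sorted(set(all_years) - set(series.values))
    if not missing:
        return series
    fit = trend_regression(series.values)
    vals = dict(series.values)
    for y in missing:
        vals[y] = fit.predict(y)
    return AnomalySeries(vals, imputed_years=set(series.imputed_years) | set(missing))


def season_table(archive: CatchArchive, method: str = "pooled") -> pd.DataFrame:
    """Per-year summary: total, AA, percentile dates and duration."""
    base = baseline_curve(archive, method)
    rows = []
    for y, s in sorted(archive.series.items()):
        c = cumulative_curve(s)
        p = percentile_dates(c)
        rows.append(
            dict(year=y, total=s.total, aa=annual_anomaly(c, base),
                 d10=p.d10, d50=p.d50, d90=p.d90, duration=p.duration)
        )
    return pd.DataFrame(rows)


def trend_table(seasons: pd.DataFrame, span_years: int = 36) -> pd.DataFrame:
    """Linear trends of AA, the percentile dates and the duration vs year."""
    rows = []
    for metric in ("aa", "d10", "d50", "d90", "duration"):
        fit = trend_regression(dict(zip(seasons["year"], seasons[metric])))
        rows.append(
            dict(metric=metric, slope=fit.slope, t=fit.t_statistic,
                 p=fit.p_value, r_squared=fit.r_squared, n=fit.n,
                 total_change=fit.total_change(span_years))
        )
    return pd.DataFrame(rows)
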