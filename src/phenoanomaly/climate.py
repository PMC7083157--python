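"""Climate-index parsing, seasonal-window averaging and screening diagnostics.

Covariates are monthly large-scale indices (NAOI, SCAND, SAH, IOD, SOI)
averaged over biologically meaningful windows relative to a focal spring:

* ``Apr-May`` — the focal spring itself (same calendar year);
* ``Nov-Mar`` — the preceding winter (Nov, Dec of the previous year; Jan,
  Feb, Mar of the focal year);
* ``Aug-Oct`` — the previous autumn migration (all previous year);
* ``Jun-Jul`` — the previous breeding season (all previous year);

plus the local Apr–May mean of daily station temperatures. Each windowed
series is screened for serial autocorrelation with a Ljung-Box portmanteau
test before entering the regression.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ClimateDataError, AnalysisError

DEFAULT_SENTINELS = (-99.9, -999.0, -999.9, -9999.0)


@dataclasses.dataclass
class MonthlyIndexSeries:
    """A named monthly climate-index series keyed by (year, month)."""

    name: str
    values: dict[tuple[int, int], float]
    source: str = ""

    def get(self, year: int, month: int) -> float:
        try:
            return self.values[(year, month)]
        except KeyError:
            raise ClimateDataError(
                f"{self.name}: no value for year {year} month {month}"
            ) from None


@dataclasses.dataclass(frozen=True)
class SeasonalWindow:
    """An ordered month window with per-month calendar-year offsets.

    ``months`` pairs each month number with an offset of 0 (same calendar
    year as the focal spring) or -1 (preceding calendar year).
    """

    name: str
    months: tuple[tuple[int, int], ...]

    def mapped_months(self, focal_year: int) -> list[tuple[int, int]]:
        return [(focal_year + off, m) for m, off in self.months]


WINDOWS: dict[str, SeasonalWindow] = {
    "Apr-May": SeasonalWindow("Apr-May", ((4, 0), (5, 0))),
    "Nov-Mar": SeasonalWindow(
        "Nov-Mar", ((11, -1), (12, -1), (1, 0), (2, 0), (3, 0))
    ),
    "Aug-Oct": SeasonalWindow("Aug-Oct", ((8, -1), (9, -1), (10, -1))),
    "Jun-Jul": SeasonalWindow("Jun-Jul", ((6, -1), (7, -1))),
}

#: Table of the 13 windowed climate covariates: column name -> (index, window).
COVARIATE_PLAN: tuple[tuple[str, str, str], ...] = (
    ("NAOI Apr-May", "NAOI", "Apr-May"),
    ("SCAND Apr-May", "SCAND", "Apr-May"),
    ("NAOI Nov-Mar", "NAOI", "Nov-Mar"),
    ("SAH Nov-Mar", "SAH", "Nov-Mar"),
    ("IOD Nov-Mar", "IOD", "Nov-Mar"),
    ("SOI Nov-Mar", "SOI", "Nov-Mar"),
    ("NAOI Aug-Oct", "NAOI", "Aug-Oct"),
    ("SAH Aug-Oct", "SAH", "Aug-Oct"),
    ("IOD Aug-Oct", "IOD", "Aug-Oct"),
    ("SOI Aug-Oct", "SOI", "Aug-Oct"),
    ("NAOI Jun-Jul", "NAOI", "Jun-Jul"),
    ("SCAND Jun-Jul", "SCAND", "Jun-Jul"),
)

TEMPERATURE_COLUMN = "LEB T Apr-May"
YEAR_COLUMN = "Year"

#: Column order of the full 14-variable covariate table.
COVARIATE_COLUMNS: tuple[str, ...] = (
    (YEAR_COLUMN, TEMPERATURE_COLUMN)
    + tuple(c for c, _, _ in COVARIATE_PLAN[:2])
    + tuple(c for c, _, _ in COVARIATE_PLAN[2:])
)


@dataclasses.dataclass
class LjungBoxResult:
    """Portmanteau Q statistic with its chi-square p-value."""

    chi_square: float
    p_value: float
    max_lag: int


def read_noaa_monthly(
    source,
    name: str,
    sentinels: Sequence[float] = DEFAULT_SENTINELS,
) -> MonthlyIndexSeries:
    """Parse a NOAA CPC-style monthly table (year + 12 columns, or long form).

    Sentinel-coded cells (e.g. -99.9) become missing. Ragged rows,
    non-numeric cells and duplicate year rows are hard errors.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        label = "<stream>"
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
        label = str(source)

    rows = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.replace(",", " ").split()
        if rows and len(tokens) != len(rows[0][1]):
            raise ClimateDataError(
                f"{label}:{lineno}: ragged row ({len(tokens)} fields, "
                f"expected {len(rows[0][1])})"
            )
        try:
            values = [float(t) for t in tokens]
        except ValueError:
            # a header line is tolerated only before any data
            if not rows:
                continue
            raise ClimateDataError(f"{label}:{lineno}: non-numeric cell") from None
        rows.append((lineno, values))

    if not rows:
        raise ClimateDataError(f"{label}: no data rows")
    width = len(rows[0][1])
    if width not in (13, 3):
        raise ClimateDataError(
            f"{label}: expected 13 columns (year + 12 months) or 3 "
            f"(year, month, value), got {width}"
        )

    sent = set(float(s) for s in sentinels)
    values: dict[tuple[int, int], float] = {}
    if width == 13:
        seen_years = set()
        for lineno, vals in rows:
            year = int(vals[0])
            if year in seen_years:
                raise ClimateDataError(f"{label}:{lineno}: duplicate year {year}")
            seen_years.add(year)
            for month, v in enumerate(vals[1:], start=1):
                if v not in sent:
                    values[(year, month)] = v
    else:
        for lineno, vals in rows:
            year, month, v = int(vals[0]), int(vals[1]), vals[2]
            if not 1 <= month <= 12:
                raise ClimateDataError(f"{label}:{lineno}: month {month} out of range")
            if (year, month) in values:
                raise ClimateDataError(
                    f"{label}:{lineno}: duplicate entry for {year}-{month:02d}"
                )
            if v not in sent:
                values[(year, month)] = v
    return MonthlyIndexSeries(name, values, source=label)


def read_ecad_daily_temperature(source) -> pd.Series:
    """Parse an ECA&D station file into a daily °C series.

    The file carries SOUID/DATE/TG/Q_TG columns with TG in 0.1 °C; rows
    whose quality flag marks the value suspect/missing (Q_TG = 9) are
    dropped.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        first = line.split(",")[0].strip().upper()
        if first in ("SOUID", "STAID"):
            header_idx = i
            break
    if header_idx is None:
        raise ClimateDataError("no SOUID/DATE/TG/Q_TG header found")
    df = pd.read_csv(io.StringIO("\n".join(lines[header_idx:])), skipinitialspace=True)
    df.columns = [c.strip().upper() for c in df.columns]
    for col in ("DATE", "TG", "Q_TG"):
        if col not in df.columns:
            raise ClimateDataError(f"missing column {col} in station file")
    dates = pd.to_datetime(df["DATE"].astype(str), format="%Y%m%d", errors="coerce")
    if dates.isna().any():
        bad = df["DATE"][dates.isna()].iloc[0]
        raise ClimateDataError(f"malformed DATE value {bad!r}")
    keep = df["Q_TG"].astype(int) != 9
    series = pd.Series(
        df["TG"].astype(float).to_numpy() / 10.0, index=dates, name="TG"
    )[keep.to_numpy()]
    return series


def seasonal_average(series, window: SeasonalWindow, focal_year: int) -> float:
    """Mean of a monthly index over a seasonal window mapped to a focal spring.

    For a daily temperature series (pandas Series indexed by date) the
    window must be ``Apr-May``: the mean is over all non-missing April–May
    days of the focal year.
    """
    if isinstance(series, MonthlyIndexSeries):
        vals = [series.get(y, m) for y, m in window.mapped_months(focal_year)]
        return float(np.mean(vals))
    if isinstance(series, pd.Series):
        if window.name != "Apr-May":
            raise ClimateDataError(
                f"daily temperature only supports the Apr-May window, "
                f"not {window.name!r}"
            )
        sel = series[
            (series.index.year == focal_year)
            & series.index.month.isin([4, 5])
        ]
        if sel.empty:
            raise ClimateDataError(
                f"temperature: no Apr-May days for year {focal_year}"
            )
        return float(sel.mean())
    raise TypeError(f"unsupported series type {type(series)!r}")


def build_covariate_table(
    indices: Mapping[str, MonthlyIndexSeries],
    temperature: pd.Series,
    years: Sequence[int],
    year_origin: int = 1981,
) -> pd.DataFrame:
    """Assemble the 14-column covariate table (year number + 13 windowed series)."""
    rows = {}
    for year in years:
        row = {YEAR_COLUMN: year - year_origin}
        row[TEMPERATURE_COLUMN] = seasonal_average(
            temperature, WINDOWS["Apr-May"], year
        )
        for col, index_name, window in COVARIATE_PLAN:
            if index_name not in indices:
                raise ClimateDataError(f"no monthly series for index {index_name!r}")
            row[col] = seasonal_average(indices[index_name], WINDOWS[window], year)
        rows[year] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table[list(COVARIATE_COLUMNS)]


def standardize(column) -> pd.Series | np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    x = np.asarray(column, dtype=float)
    if np.unique(x).size < 2:
        raise AnalysisError("standardize: fewer than 2 distinct values")
    sd = x.std(ddof=1)
    z = (x - x.mean()) / sd
    if isinstance(column, pd.Series):
        return pd.Series(z, index=column.index, name=column.name)
    return z


def standardize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize every column of a covariate table."""
    return table.apply(standardize, axis=0)


def ljung_box(series, max_lag: int = 10) -> LjungBoxResult:
    """Ljung-Box portmanteau test of no autocorrelation up to ``max_lag``.

    Q = n(n+2) * sum_{k<=m} r_k^2/(n-k) with r_k the lag-k autocorrelation
    of the demeaned series; the p-value is chi-square with m degrees of
    freedom. Q is invariant to adding a constant or rescaling.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= max_lag + 1:
        raise AnalysisError(
            f"series length {n} too short for Ljung-Box with lag {max_lag}"
        )
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0:
        raise AnalysisError("Ljung-Box: constant series")
    q = 0.0
    for k in range(1, max_lag + 1):
        r_k = float(np.dot(xc[:-k], xc[k:])) / denom
        q += r_k * r_k / (n - k)
    q *= n * (n + 2)
    p = float(stats.chi2.sf(q, df=max_lag))
    return LjungBoxResult(chi_square=float(q), p_value=p, max_lag=max_lag)


def correlation_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p for every column pair."""
    cols = list(table.columns)
    n = len(table)
    if n < 3:
        raise AnalysisError("correlation matrix needs at least 3 rows")
    for c in cols:
        if np.unique(table[c].to_numpy()).size < 2:
            raise AnalysisError(f"zero-variance column {c!r}")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            res = stats.pearsonr(table[a], table[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def screening_table(
    covariates: pd.DataFrame, aa_gapless, max_lag: int = 10
) -> pd.DataFrame:
    """Ljung-Box screen of every covariate plus the (gap-filled) AA series."""
    rows = []
    for col in covariates.columns:
        res = ljung_box(covariates[col].to_numpy(), max_lag)
        rows.append(dict(variable=col, chi_square=res.chi_square, p=res.p_value))
    res = ljung_box(np.asarray(aa_gapless, dtype=float), max_lag)
    rows.append(dict(variable="AA", chi_square=res.chi_square, p=res.p_value))
    return pd.DataFrame(rows)
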