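"""Daily ringing-count archives: reading, imputation and low-count filtering.

The analysis window is the fixed 45-day spring period 1 April – 15 May
(ordinal day 1 = 1 April, day 45 = 15 May). A date absent from the input
inside that window is *missing* (mist-netting suspended) and is later
imputed; an explicit zero row is a true zero catch.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np
import pandas as pd

from .errors import CatchDataError

WINDOW_DAYS = 45
#: month/day of the first window day (1 April)
WINDOW_START = (4, 1)


def ordinal_day(date: _dt.date) -> int | None:
    """Ordinal day within the spring window (1 = 1 Apr .. 45 = 15 May), or None."""
    start = _dt.date(date.year, *WINDOW_START)
    off = (date - start).days + 1
    return off if 1 <= off <= WINDOW_DAYS else None


def day_to_date(year: int, day: int) -> _dt.date:
    """Inverse of :func:`ordinal_day` for a given year."""
    if not 1 <= day <= WINDOW_DAYS:
        raise ValueError(f"ordinal day {day} outside 1..{WINDOW_DAYS}")
    return _dt.date(year, *WINDOW_START) + _dt.timedelta(days=day - 1)


@dataclasses.dataclass
class SpringSeries:
    """One year's daily counts over the 45-day spring window.

    ``counts`` is a float array of length 45; NaN marks a day that is still
    missing (pre-imputation). Imputed values are real-valued means and are
    flagged in ``imputed_days``.
    """

    year: int
    counts: np.ndarray
    imputed_days: set[int] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (WINDOW_DAYS,):
            raise CatchDataError(
                f"year {self.year}: expected {WINDOW_DAYS} daily values, "
                f"got shape {self.counts.shape}"
            )
        obs = self.counts[~np.isnan(self.counts)]
        if (obs < 0).any():
            raise CatchDataError(f"year {self.year}: negative count")

    @property
    def missing_days(self) -> set[int]:
        return {int(d) + 1 for d in np.flatnonzero(np.isnan(self.counts))}

    @property
    def total(self) -> float:
        return float(np.nansum(self.counts))

    def copy(self) -> "SpringSeries":
        return SpringSeries(self.year, self.counts.copy(), set(self.imputed_days))


@dataclasses.dataclass
class CatchArchive:
    """Multi-year archive of spring series for one ringing station."""

    station_id: str
    series: dict[int, SpringSeries]
    excluded_years: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    @property
    def years(self) -> set[int]:
        return set(self.series)

    def copy(self) -> "CatchArchive":
        return CatchArchive(
            self.station_id,
            {y: s.copy() for y, s in self.series.items()},
            list(self.excluded_years),
        )

    def summary(self) -> pd.DataFrame:
        """Per-year totals, imputed-day counts and inclusion status."""
        rows = []
        for y in sorted(self.series):
            s = self.series[y]
            rows.append(
                dict(year=y, total=s.total, n_imputed_days=len(s.imputed_days),
                     n_missing_days=len(s.missing_days), status="included")
            )
        for y, reason in self.excluded_years:
            rows.append(dict(year=y, total=np.nan, n_imputed_days=0,
                             n_missing_days=0, status=f"excluded:{reason}"))
        return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def read_daily_catches(source, station_id: str = "station") -> CatchArchive:
    """Read (date, count) rows into a :class:`CatchArchive`.

    ``source`` is a path to delimited text with header columns ``date``
    (ISO 8601) and ``count``, or an equivalent DataFrame. Rows outside the
    1 Apr – 15 May window are dropped; in-window dates absent from the input
    are recorded as missing.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if not {"date", "count"}.issubset(df.columns):
        raise CatchDataError("input must have 'date' and 'count' columns")

    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(dates.isna().to_numpy())
    if bad.size:
        raise CatchDataError(
            f"unparseable date in row {bad[0] + 2}: {df['date'].iloc[bad[0]]!r}"
        )
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = np.flatnonzero(counts.isna().to_numpy())
    if bad.size:
        raise CatchDataError(
            f"non-numeric count in row {bad[0] + 2}: {df['count'].iloc[bad[0]]!r}"
        )
    if (counts < 0).any():
        row = int(np.flatnonzero((counts < 0).to_numpy())[0])
        raise CatchDataError(f"negative count in row {row + 2}")

    dup = df["date"].astype(str).duplicated()
    if dup.any():
        raise CatchDataError(
            f"duplicate date {df['date'][dup].iloc[0]!r} in input"
        )

    series: dict[int, SpringSeries] = {}
    for date, count in zip(dates.dt.date, counts):
        day = ordinal_day(date)
        if day is None:
            continue
        s = series.get(date.year)
        if s is None:
            s = series[date.year] = SpringSeries(
                date.year, np.full(WINDOW_DAYS, np.nan)
            )
        s.counts[day - 1] = float(count)
    return CatchArchive(station_id, series)


def impute_missing_days(
    archive: CatchArchive, half_window_years: int = 6
) -> CatchArchive:
    """Fill missing days with same-date means from neighbouring years.

    A missing (year, day) cell is replaced by the mean observed count on
    that ordinal day over the years within ±``half_window_years`` (the focal
    year excluded; the window truncates at the archive edges). Only values
    observed in the input — never previously imputed ones — act as donors.
    """
    excluded = {y for y, _ in archive.excluded_years}
    out = archive.copy()
    for year in sorted(out.series):
        if year in excluded:
            raise CatchDataError(f"imputation requested on excluded year {year}")
        s = out.series[year]
        for day in sorted(s.missing_days):
            donors = []
            for dy in range(year - half_window_years, year + half_window_years + 1):
                if dy == year or dy not in archive.series:
                    continue
                other = archive.series[dy]
                if day in other.missing_days or day in other.imputed_days:
                    continue
                donors.append(other.counts[day - 1])
            if not donors:
                raise CatchDataError(
                    f"no donor years for missing day {day} of year {year} "
                    f"within +/-{half_window_years} years"
                )
            s.counts[day - 1] = float(np.mean(donors))
            s.imputed_days.add(day)
    return out


def filter_low_count_years(archive: CatchArchive, min_total: int = 31) -> CatchArchive:
    """Exclude springs whose final total is below ``min_total`` birds.

    The default keeps years with at least 31 birds, so a year totalling
    exactly 31 is retained.
    """
    out = archive.copy()
    for year in sorted(out.series):
        if out.series[year].total < min_total:
            del out.series[year]
            out.excluded_years.append((year, "low_total"))
    return out
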