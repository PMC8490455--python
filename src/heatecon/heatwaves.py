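"""TX90p heatwave detection, event catalogues and WBDD severity.

A heatwave is a run of at least 3 consecutive days on which the daily maximum
temperature exceeds its calendar-day 90th percentile. Thresholds are
ETCCDI-style: for each calendar day, the percentile is taken over all values
falling in a centered window (default 15 days) pooled across every year of
the reference period (default use: 1981–2010-style 30-year spans; any span of
at least two full years is accepted). Feb 29 uses Feb 28's threshold.

Severity is measured in Wet Bulb Degree-Days (WBDD): on every heatwave day,
the mean over working hours (9–17 h) of the WBGT excess over 26 °C, summed
over the event/year. Only heatwave days contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, CoverageError, InsufficientDataError

#: default percentile of the TX90p rule
PERCENTILE = 90.0
#: minimum run length, in days, for an exceedance run to count as a heatwave
MIN_DURATION = 3
#: WBGT threshold (°C) above which degree-days accumulate
WBDD_THRESHOLD = 26.0
#: working day, half-open hour interval [9, 17)
WORKING_HOURS = (9, 17)
SUMMER_MONTHS = (6, 7, 8)


def _calendar_index(dates: pd.DatetimeIndex) -> np.ndarray:
    """Map dates to a 0..364 calendar-day index; Feb 29 maps to Feb 28."""
    doy = dates.dayofyear.to_numpy().copy()
    leap = dates.is_leap_year
    after_feb28 = doy > 59  # day 59 is Feb 28 in leap years
    doy[leap & after_feb28] -= 1
    return doy - 1


def _check_daily(series: pd.Series) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(series.index)
    if len(idx) == 0 or not (idx[1:] - idx[:-1] == pd.Timedelta("1D")).all():
        raise AlignmentError("series must be contiguous daily")
    if series.isna().any():
        raise InsufficientDataError("series contains missing values")
    return idx


@dataclass
class ThresholdSeries:
    """Calendar-day percentile thresholds for one region."""

    region: str
    values: np.ndarray  # length 365, °C
    reference_period: tuple[int, int]
    window_days: int
    percentile: float = PERCENTILE

    def for_dates(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.values[_calendar_index(dates)]


@dataclass
class HeatwaveEvent:
    region: str
    start: pd.Timestamp
    duration: int  # days
    summer: bool  # start month in JJA
    severity: float = np.nan  # WBDD, °C·day; filled by compute_wbdd

    @property
    def days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.duration, freq="D")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(days=self.duration - 1)


@dataclass
class HeatwaveCatalogue:
    """All detected events, sorted by (region, start); non-overlapping within a region."""

    events: list[HeatwaveEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def for_region(self, region: str) -> list[HeatwaveEvent]:
        return [e for e in self.events if e.region == region]

    def event_days(self, region: str) -> pd.DatetimeIndex:
        days = [d for e in self.for_region(region) for d in e.days]
        return pd.DatetimeIndex(sorted(days))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [e.region for e in self.events],
                "start": [e.start for e in self.events],
                "duration": [e.duration for e in self.events],
                "summer": [e.summer for e in self.events],
                "wbdd": [e.severity for e in self.events],
            }
        )

    @staticmethod
    def merge(*catalogues: "HeatwaveCatalogue") -> "HeatwaveCatalogue":
        events = [e for c in catalogues for e in c.events]
        events.sort(key=lambda e: (e.region, e.start))
        return HeatwaveCatalogue(events)


def compute_thresholds(
    reference: pd.Series,
    window_days: int = 15,
    percentile: float = PERCENTILE,
    region: str | None = None,
) -> ThresholdSeries:
    """Calendar-day percentile thresholds from a reference daily-Tmax series.

    For calendar day *d*, the threshold is the ``percentile``-th percentile
    (linear interpolation between order statistics) of all reference values
    whose calendar day lies within ``window_days`` centered on *d*, pooled
    across all reference years.
    """
    if window_days < 1 or window_days % 2 == 0:
        raise ConfigError("window_days must be a positive odd integer")
    idx = _check_daily(reference)
    years = np.unique(idx.year)
    full_years = [y for y in years if (idx.year == y).sum() >= 365]
    if len(full_years) < 2:
        raise InsufficientDataError("reference must cover at least 2 full years")

    cal = _calendar_index(idx)
    values = reference.to_numpy()
    pooled: list[list[float]] = [[] for _ in range(365)]
    for c, v in zip(cal, values):
        pooled[c].append(v)
    half = window_days // 2
    out = np.empty(365)
    for d in range(365):
        window_vals: list[float] = []
        for off in range(-half, half + 1):
            window_vals.extend(pooled[(d + off) % 365])
        out[d] = np.percentile(window_vals, percentile)  # linear (type 7)
    return ThresholdSeries(
        region=region or str(reference.name or ""),
        values=out,
        reference_period=(int(years.min()), int(years.max())),
        window_days=window_days,
        percentile=percentile,
    )


def detect_events(
    series: pd.Series,
    thresholds: ThresholdSeries,
    min_duration: int = MIN_DURATION,
    region: str | None = None,
) -> HeatwaveCatalogue:
    """Detect heatwaves in a daily-Tmax series: maximal exceedance runs ≥ ``min_duration``.

    Exceedance is strict (Tmax > threshold). Runs are not merged across
    non-exceedance gap days.
    """
    idx = _check_daily(series)
    thr = thresholds.for_dates(idx)
    exceed = series.to_numpy() > thr

    events: list[HeatwaveEvent] = []
    rid = region or thresholds.region or str(series.name or "")
    n = len(exceed)
    i = 0
    while i < n:
        if exceed[i]:
            j = i
            while j + 1 < n and exceed[j + 1]:
                j += 1
            length = j - i + 1
            if length >= min_duration:
                start = idx[i]
                events.append(
                    HeatwaveEvent(
                        region=rid,
                        start=start,
                        duration=length,
                        summer=start.month in SUMMER_MONTHS,
                    )
                )
            i = j + 1
        else:
            i += 1
    return HeatwaveCatalogue(events)


def catalogue_stats(
    catalogue: HeatwaveCatalogue,
    regions: list[str],
    dates: pd.DatetimeIndex | None = None,
) -> dict:
    """Catalogue summary: yearly counts, duration by summer class, area affected.

    Returns a dict with

    * ``counts``: events per start-year (pd.Series);
    * ``duration``: mean/median duration split by summer (JJA start) vs not;
    * ``area_affected``: daily percentage of regions with an active event
      (over ``dates``, or the catalogue's own span).
    """
    if not regions:
        raise ConfigError("region list must be non-empty")
    frame = catalogue.to_frame()
    if dates is None:
        if len(frame):
            dates = pd.date_range(
                frame.start.min(), max(e.end for e in catalogue.events), freq="D"
            )
        else:
            dates = pd.DatetimeIndex([])

    if len(frame):
        counts = frame.start.dt.year.value_counts().sort_index()
        duration = (
            frame.groupby("summer")["duration"].agg(["count", "mean", "median"]).reindex(
                [True, False]
            )
        )
    else:
        counts = pd.Series(dtype=int)
        duration = pd.DataFrame(columns=["count", "mean", "median"], index=[True, False])

    active = pd.DataFrame(False, index=dates, columns=regions)
    for e in catalogue.events:
        if e.region in active.columns:
            days = e.days.intersection(dates)
            active.loc[days, e.region] = True
    area = active.mean(axis=1) * 100.0 if len(dates) else pd.Series(dtype=float)
    area.name = "pct_regions_affected"
    return {"counts": counts, "duration": duration, "area_affected": area}


def compute_wbdd(
    wbgt_sun: pd.DataFrame | pd.Series,
    catalogue: HeatwaveCatalogue,
    working_hours: tuple[int, int] = WORKING_HOURS,
    threshold: float = WBDD_THRESHOLD,
) -> pd.DataFrame:
    """Wet Bulb Degree-Days per region and year; also fills event severities.

    WBDD = Σ over heatwave days of mean over working hours of
    max(0, WBGT_h − threshold). Hours outside heatwave days contribute
    nothing. ``wbgt_sun`` is an hourly frame (time × region) or a single
    hourly series whose name is the region id.
    """
    if isinstance(wbgt_sun, pd.Series):
        wbgt_sun = wbgt_sun.to_frame(name=str(wbgt_sun.name or ""))
    idx = pd.DatetimeIndex(wbgt_sun.index)
    h0, h1 = working_hours
    work = wbgt_sun[(idx.hour >= h0) & (idx.hour < h1)]
    wdates = pd.DatetimeIndex(work.index).normalize()
    daily_exc = np.maximum(work - threshold, 0.0).groupby(wdates).mean()
    n_hours = work.groupby(wdates).size()
    if len(n_hours) and (n_hours != (h1 - h0)).any():
        raise CoverageError("incomplete working-hour coverage in WBGT series")

    records = []
    for e in catalogue.events:
        if e.region not in daily_exc.columns:
            raise CoverageError(f"no WBGT series for region {e.region!r}")
        missing = e.days.difference(daily_exc.index)
        if len(missing):
            raise CoverageError(f"WBGT series missing heatwave days {list(missing.date)}")
        e.severity = float(daily_exc.loc[e.days, e.region].sum())
        records.append({"region": e.region, "year": e.start.year, "wbdd": e.severity})
    if not records:
        return pd.DataFrame(columns=["wbdd"], index=pd.MultiIndex.from_arrays([[], []], names=["region", "year"]))
    df = pd.DataFrame(records).groupby(["region", "year"]).sum()
    return df


def daily_tmax(field) -> "xr.DataArray":  # noqa: F821
    """Per-cell daily maximum air temperature from an hourly field."""
    return field["tas"].resample(time="1D").max()
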