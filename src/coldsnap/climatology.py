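"""Day-of-year reference climatology and daily temperature anomalies.

The climatology ("climate values") is built in two fixed steps: first a
centered rolling mean of the continuous daily series (default window 31
days), then an average of the rolled values for each day of the year
across the reference years.  The order matters slightly and is pinned by
tests.  Anomalies subtract the profile value for each date's calendar day
from the *raw* daily value — smoothing enters only through the profile.

Leap days: 29 February contributes to rolling windows like any other day,
but the profile is indexed on the 365 calendar days of a common year; when
anomalies are computed, 29 February borrows the 28 February profile value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coldsnap.io import DailySeries, ValidationError

logger = logging.getLogger(__name__)

# (month, day) -> day-of-year 1..365 on a common (non-leap) calendar
_COMMON_DAYS = pd.date_range("2001-01-01", "2001-12-31", freq="D")
_MD_TO_DOY = {(d.month, d.day): i + 1 for i, d in enumerate(_COMMON_DAYS)}


@dataclass
class ClimatologyProfile:
    """Per-day-of-year reference means of Tmax and Tmin.

    ``clim_tmax`` / ``clim_tmin`` are length-365 arrays (°C) indexed by
    common-calendar day of year 1..365.
    """

    clim_tmax: np.ndarray = field(repr=False)
    clim_tmin: np.ndarray = field(repr=False)
    reference_period: tuple[int, int]
    window_days: int = 31

    def __post_init__(self) -> None:
        self.clim_tmax = np.asarray(self.clim_tmax, dtype=float)
        self.clim_tmin = np.asarray(self.clim_tmin, dtype=float)
        for name, arr in (("clim_tmax", self.clim_tmax), ("clim_tmin", self.clim_tmin)):
            if arr.shape != (365,):
                raise ValidationError(f"{name} must have exactly 365 entries")
            if not np.isfinite(arr).all():
                raise ValidationError(f"{name} contains non-finite values")

    @property
    def day_of_year(self) -> np.ndarray:
        return np.arange(1, 366)

    def value_for(self, date: pd.Timestamp) -> tuple[float, float]:
        """Profile (tmax, tmin) for a calendar date; Feb 29 maps to Feb 28."""
        md = (date.month, date.day)
        if md == (2, 29):
            md = (2, 28)
        i = _MD_TO_DOY[md] - 1
        return float(self.clim_tmax[i]), float(self.clim_tmin[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"clim_tmax": self.clim_tmax, "clim_tmin": self.clim_tmin},
            index=pd.Index(self.day_of_year, name="day_of_year"),
        )


@dataclass
class AnomalySeries:
    """Daily Tmax/Tmin departures from a climatology profile.

    ``data`` shares the index and missing-value structure of the source
    series and carries columns tmax, tmin, tmax_anom, tmin_anom.
    """

    site_id: str
    data: pd.DataFrame = field(repr=False)
    profile_used: ClimatologyProfile | None = None

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def tmax_anom(self) -> pd.Series:
        return self.data["tmax_anom"]

    @property
    def tmin_anom(self) -> pd.Series:
        return self.data["tmin_anom"]

    def __len__(self) -> int:
        return len(self.data)

    def slice_years(self, start_year: int, end_year: int) -> "AnomalySeries":
        sub = self.data.loc[f"{start_year}-01-01" : f"{end_year}-12-31"]
        if sub.empty:
            raise ValidationError(f"no anomaly data in {start_year}-{end_year}")
        return AnomalySeries(self.site_id, sub.copy(), self.profile_used)


def build_profile(
    series: DailySeries,
    reference_period: tuple[int, int] = (1971, 2000),
    window_days: int = 31,
    max_missing_fraction: float = 1 / 3,
) -> ClimatologyProfile:
    """Build the day-of-year climatology from a reference period.

    Step 1: centered rolling mean of width ``window_days`` over the
    continuous daily series (windows reach into adjacent years where the
    series provides them; a window is invalid if more than
    ``max_missing_fraction`` of its days are missing).  Step 2: average
    the rolled values for each day of the year over the reference years.

    Raises
    ------
    ValidationError
        If the reference period is not fully covered by the series, if
        ``window_days`` is even or < 1, or if any day of year ends up
        with zero valid contributions.
    """
    start_year, end_year = reference_period
    if window_days < 1 or window_days % 2 == 0:
        raise ValidationError("window_days must be an odd integer >= 1")
    ref_start = pd.Timestamp(year=start_year, month=1, day=1)
    ref_end = pd.Timestamp(year=end_year, month=12, day=31)
    if series.dates[0] > ref_start or series.dates[-1] < ref_end:
        raise ValidationError(
            f"reference period {start_year}-{end_year} not covered by series "
            f"({series.dates[0].date()}..{series.dates[-1].date()})"
        )
    min_periods = int(np.ceil(window_days * (1.0 - max_missing_fraction)))
    logger.debug(
        "rolling window %d days, min %d valid days per window", window_days, min_periods
    )
    rolled = series.data.rolling(window_days, center=True, min_periods=min_periods).mean()
    ref = rolled.loc[ref_start:ref_end]
    md = list(zip(ref.index.month, ref.index.day))
    keep = [m_d != (2, 29) for m_d in md]
    ref = ref[keep]
    doy = np.array([_MD_TO_DOY[m_d] for m_d, k in zip(md, keep) if k])
    grouped = ref.groupby(doy).mean()
    counts = ref.groupby(doy).count()
    if len(grouped) < 365 or (counts == 0).any().any():
        empty = sorted(set(range(1, 366)) - set(grouped.dropna().index))
        raise ValidationError(
            f"day(s) of year with zero valid contributions in reference period: {empty[:5]}..."
        )
    return ClimatologyProfile(
        clim_tmax=grouped["tmax"].to_numpy(),
        clim_tmin=grouped["tmin"].to_numpy(),
        reference_period=(start_year, end_year),
        window_days=window_days,
    )


def compute_anomalies(series: DailySeries, profile: ClimatologyProfile) -> AnomalySeries:
    """Subtract the profile value for each calendar day from the raw series.

    Missing raw values propagate to missing anomalies; 29 February uses
    the 28 February profile value.
    """
    idx = series.dates
    feb28 = _MD_TO_DOY[(2, 28)]
    # (2, 29) is absent from the common-calendar map, so it falls back to Feb 28
    doy = np.array([_MD_TO_DOY.get((m, d), feb28) for m, d in zip(idx.month, idx.day)])
    pos = doy - 1
    out = series.data.copy()
    out["tmax_anom"] = series.tmax.to_numpy() - profile.clim_tmax[pos]
    out["tmin_anom"] = series.tmin.to_numpy() - profile.clim_tmin[pos]
    return AnomalySeries(series.site_id, out, profile)
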