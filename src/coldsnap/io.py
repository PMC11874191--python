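"""Reading and writing daily temperature series and event tables.

Daily series are carried as a :class:`DailySeries`: a pandas DataFrame on a
gap-free daily ``DatetimeIndex`` with float columns ``tmax`` and ``tmin``
(°C), where ``NaN`` marks a missing value.  Validation enforces the
calendar (strictly increasing, one row per calendar day, gaps made
explicit) and the physical ordering ``tmin <= tmax`` (violating rows are
masked on both variables and counted via logging, never silently kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from coldsnap.climatology import AnomalySeries
    from coldsnap.events import ColdEvent

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["site", "start", "end", "duration_days", "min_tmax_anom", "min_tmin_anom"]


class ValidationError(ValueError):
    """Raised when an input file or series violates a hard contract."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping for delimited daily-temperature files.

    National met services and climate-model exports disagree on headers;
    a dialect names the date and temperature columns, the delimiter and
    the temperature unit (``C`` or ``K``; Kelvin input is converted).
    """

    date_col: str = "date"
    tmax_col: str = "tmax"
    tmin_col: str = "tmin"
    sep: str = ","
    unit: str = "C"

    def __post_init__(self) -> None:
        if self.unit not in ("C", "K"):
            raise ValidationError(f"unsupported temperature unit {self.unit!r}")


#: Built-in dialect for plain ``date,tmax,tmin`` CSV files.
GENERIC_DIALECT = Dialect()


@dataclass
class DailySeries:
    """A dated daily Tmax/Tmin record for one site or model run.

    ``data`` is indexed by a complete daily ``DatetimeIndex`` (proleptic
    Gregorian, real leap days); missing observations are ``NaN``.
    """

    site_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def tmax(self) -> pd.Series:
        return self.data["tmax"]

    @property
    def tmin(self) -> pd.Series:
        return self.data["tmin"]

    def __len__(self) -> int:
        return len(self.data)

    def slice_years(self, start_year: int, end_year: int) -> "DailySeries":
        """Return the sub-series covering calendar years start..end inclusive."""
        sub = self.data.loc[f"{start_year}-01-01" : f"{end_year}-12-31"]
        if sub.empty:
            raise ValidationError(
                f"series {self.site_id!r} has no data in {start_year}-{end_year}"
            )
        return DailySeries(self.site_id, sub.copy())


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    if not {"tmax", "tmin"} <= set(frame.columns):
        raise ValidationError("daily frame needs 'tmax' and 'tmin' columns")
    frame = frame[["tmax", "tmin"]].astype(float).copy()
    idx = pd.DatetimeIndex(frame.index)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"duplicate date in series: {dup.date()}")
    frame.index = idx
    frame = frame.sort_index()
    # gaps become explicit missing rows
    full = pd.date_range(frame.index[0], frame.index[-1], freq="D")
    n_gaps = len(full) - len(frame)
    if n_gaps:
        logger.info("inserted %d explicit missing day(s) to close calendar gaps", n_gaps)
        frame = frame.reindex(full)
    frame.index.name = "date"
    if len(frame) < 365:
        # climatology needs a full year; short series are fine for toy use
        logger.warning("series spans only %d days (< 1 full year)", len(frame))
    bad = (frame["tmin"] > frame["tmax"]).to_numpy().nonzero()[0]
    if bad.size:
        logger.warning("masked %d row(s) with tmin > tmax", bad.size)
        frame.iloc[bad, :] = np.nan
    return frame


def read_daily_series(path, dialect: Dialect = GENERIC_DIALECT, site_id: str | None = None) -> DailySeries:
    """Read a delimited daily Tmax/Tmin file into a validated DailySeries.

    Parameters
    ----------
    path
        Delimited-text file with a date column and two temperature columns.
    dialect
        Column mapping and unit; defaults to ``date,tmax,tmin`` in °C.
    site_id
        Site label; defaults to the file stem.

    Raises
    ------
    ValidationError
        On unparseable dates (the offending row is named), on a variable
        with no valid values at all, or on calendar violations.
    """
    raw = pd.read_csv(path, sep=dialect.sep)
    for col in (dialect.date_col, dialect.tmax_col, dialect.tmin_col):
        if col not in raw.columns:
            raise ValidationError(f"column {col!r} not found in {path}")
    dates = pd.to_datetime(raw[dialect.date_col], format="ISO8601", errors="coerce")
    if dates.isna().any():
        row = int(dates.isna().idxmax())
        raise ValidationError(
            f"unparseable date {raw[dialect.date_col].iloc[row]!r} at data row {row + 1} of {path}"
        )
    frame = pd.DataFrame(
        {
            "tmax": pd.to_numeric(raw[dialect.tmax_col], errors="coerce").to_numpy(),
            "tmin": pd.to_numeric(raw[dialect.tmin_col], errors="coerce").to_numpy(),
        },
        index=pd.DatetimeIndex(dates),
    )
    if dialect.unit == "K":
        frame -= 273.15
    for var in ("tmax", "tmin"):
        if frame[var].isna().all():
            raise ValidationError(f"variable {var!r} is entirely missing in {path}")
    if site_id is None:
        site_id = _stem(path)
    return DailySeries(site_id, frame)


def read_gridpoint_netcdf(
    path,
    latitude: float,
    longitude: float,
    tmax_var: str = "tasmax",
    tmin_var: str = "tasmin",
    site_id: str | None = None,
) -> DailySeries:
    """Extract the nearest land grid point from a netCDF model file.

    A grid cell counts as land if its Tmax series is not entirely missing.
    Kelvin input (the CF convention for air temperature) is detected from
    the variable's ``units`` attribute and converted to °C.
    """
    import xarray as xr  # optional dependency

    ds = xr.open_dataset(path)
    try:
        da_x, da_n = ds[tmax_var], ds[tmin_var]
        lat_name = "lat" if "lat" in da_x.dims else "latitude"
        lon_name = "lon" if "lon" in da_x.dims else "longitude"
        land = da_x.notnull().any("time")
        dist2 = (ds[lat_name] - latitude) ** 2 + (ds[lon_name] - longitude) ** 2
        dist2 = dist2.broadcast_like(land).where(land)
        flat = int(dist2.argmin())
        iy, ix = np.unravel_index(flat, dist2.shape)
        sel = {lat_name: int(iy), lon_name: int(ix)}
        tmax = da_x.isel(sel).to_series()
        tmin = da_n.isel(sel).to_series()
        if str(da_x.attrs.get("units", "")).lower() in ("k", "kelvin"):
            tmax, tmin = tmax - 273.15, tmin - 273.15
        frame = pd.DataFrame({"tmax": tmax, "tmin": tmin})
        frame.index = pd.DatetimeIndex(frame.index).normalize()
        return DailySeries(site_id or _stem(path), frame)
    finally:
        ds.close()


def write_events(events: Sequence["ColdEvent"], path) -> None:
    """Write detected events to CSV, one row per event.

    Events must be sorted by start date and non-overlapping; an empty list
    produces a header-only file.  Round-trips losslessly through
    :func:`read_events`.
    """
    rows = []
    prev_end = None
    for ev in events:
        if prev_end is not None and ev.start <= prev_end:
            raise ValidationError(
                f"events overlap or are unsorted at {ev.start.date()} (previous end {prev_end.date()})"
            )
        prev_end = ev.end
        rows.append(
            {
                "site": ev.site_id,
                "start": ev.start.date().isoformat(),
                "end": ev.end.date().isoformat(),
                "duration_days": ev.duration,
                "min_tmax_anom": ev.min_tmax_anom,
                "min_tmin_anom": ev.min_tmin_anom,
            }
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> list["ColdEvent"]:
    """Read an event table written by :func:`write_events`."""
    from coldsnap.events import ColdEvent

    table = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"event table {path} lacks columns {sorted(missing)}")
    return [
        ColdEvent(
            site_id=str(r.site),
            start=pd.Timestamp(r.start),
            end=pd.Timestamp(r.end),
            duration=int(r.duration_days),
            min_tmax_anom=float(r.min_tmax_anom),
            min_tmin_anom=float(r.min_tmin_anom),
        )
        for r in table.itertuples()
    ]


def write_daily_series(series: DailySeries, path) -> None:
    """Write a DailySeries as generic ``date,tmax,tmin`` CSV."""
    out = series.data.copy()
    out.index = out.index.strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path)


def write_anomalies(anoms: "AnomalySeries", path) -> None:
    """Write an anomaly table (date, tmax, tmin, tmax_anom, tmin_anom) as CSV."""
    out = anoms.data[["tmax", "tmin", "tmax_anom", "tmin_anom"]].copy()
    out.index = out.index.strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path)


def _stem(path) -> str:
    from pathlib import Path

    return Path(path).stem
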