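"""Shared fixtures and independent oracles for the test suite.

The brute-force event scanner here is deliberately written as a plain
day-by-day Python loop, independent of the vectorised implementation it
cross-checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coldsnap.climatology import AnomalySeries

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_anomalies(
    start: str,
    tmax_anom,
    tmin_anom=None,
    site: str = "test",
) -> AnomalySeries:
    """Build an AnomalySeries directly from anomaly arrays (tmin defaults to tmax)."""
    tmax_anom = np.asarray(tmax_anom, dtype=float)
    tmin_anom = tmax_anom if tmin_anom is None else np.asarray(tmin_anom, dtype=float)
    idx = pd.date_range(start, periods=len(tmax_anom), freq="D")
    data = pd.DataFrame(
        {
            "tmax": tmax_anom + 10.0,
            "tmin": tmin_anom + 5.0,
            "tmax_anom": tmax_anom,
            "tmin_anom": tmin_anom,
        },
        index=idx,
    )
    return AnomalySeries(site, data)


def brute_force_events(
    dates,
    tmax_anom,
    tmin_anom,
    threshold: float = -4.0,
    min_duration: int = 4,
    months=frozenset({1, 2, 3}),
):
    """Day-by-day reference scanner: list of (start, end) inclusive date pairs.

    A day qualifies iff both anomalies are present, both strictly below
    the threshold, and the month is allowed; maximal qualifying runs of
    at least ``min_duration`` days are reported.
    """
    qualifies = []
    for d, x, n in zip(dates, tmax_anom, tmin_anom):
        ok = (
            x == x  # not NaN
            and n == n
            and x < threshold
            and n < threshold
            and d.month in months
        )
        qualifies.append(bool(ok))
    out = []
    i, n_days = 0, len(qualifies)
    while i < n_days:
        if qualifies[i]:
            j = i
            while j + 1 < n_days and qualifies[j + 1]:
                j += 1
            if j - i + 1 >= min_duration:
                out.append((dates[i], dates[j]))
            i = j + 1
        else:
            i += 1
    return out


@pytest.fixture
def write_daily_csv(tmp_path):
    """Write rows of (date, tmax, tmin) to a CSV file and return its path."""

    def _write(rows, name="series.csv", header="date,tmax,tmin"):
        path = tmp_path / name
        lines = [header] + [",".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def year_of_rows():
    """One full 2018 calendar year of plain (date, tmax, tmin) rows."""
    idx = pd.date_range("2018-01-01", "2018-12-31", freq="D")
    return [(d.date().isoformat(), 10.0, 3.0) for d in idx]
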