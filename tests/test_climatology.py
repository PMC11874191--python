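"""Day-of-year climatology construction and anomaly computation.

The rolling-then-group order, the centered window, the leap-day policy
and the linearity of anomalies are all pinned here, with brute-force
windowed averaging as the independent oracle.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldsnap.climatology import AnomalySeries, build_profile, compute_anomalies
from coldsnap.io import DailySeries, ValidationError


def harmonic_series(start_year, end_year, amplitude=8.0, mean=10.0, offset=4.0, period=365.0):
    """Deterministic sinusoidal Tmax/Tmin series (period in days)."""
    idx = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    t = np.arange(len(idx))
    tmax = mean + amplitude * np.cos(2 * np.pi * t / period)
    return DailySeries("harmonic", pd.DataFrame({"tmax": tmax, "tmin": tmax - offset}, index=idx))


def calendar_harmonic_series(start_year, end_year, amplitude=8.0, mean=10.0, offset=4.0):
    """Series exactly periodic on the calendar: each (month, day) repeats every
    year; Feb 29 borrows the Feb 28 value."""
    idx = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    common = pd.date_range("2001-01-01", "2001-12-31", freq="D")
    doy_map = {(d.month, d.day): i for i, d in enumerate(common)}
    doy_map[(2, 29)] = doy_map[(2, 28)]
    doy = np.array([doy_map[(d.month, d.day)] for d in idx])
    tmax = mean + amplitude * np.cos(2 * np.pi * doy / 365.0)
    return DailySeries("cal", pd.DataFrame({"tmax": tmax, "tmin": tmax - offset}, index=idx))


def md_key(index: pd.DatetimeIndex) -> np.ndarray:
    """Sortable 'MM-DD' calendar-day grouping key."""
    return np.array([f"{m:02d}-{d:02d}" for m, d in zip(index.month, index.day)])


def oracle_profile(series: DailySeries, ref, window):
    """Brute-force oracle: explicit windowed means, then day-of-year means."""
    values = {"tmax": {}, "tmin": {}}
    idx = series.dates
    arr = {v: series.data[v].to_numpy() for v in values}
    half = window // 2
    min_valid = int(np.ceil(window * 2 / 3))
    for i, d in enumerate(idx):
        if not (ref[0] <= d.year <= ref[1]) or (d.month, d.day) == (2, 29):
            continue
        lo, hi = max(0, i - half), min(len(idx), i + half + 1)
        for var in values:
            window_vals = arr[var][lo:hi]
            window_vals = window_vals[~np.isnan(window_vals)]
            if len(window_vals) < min_valid:
                continue
            values[var].setdefault((d.month, d.day), []).append(window_vals.mean())
    out = {}
    for var, acc in values.items():
        out[var] = {md: float(np.mean(v)) for md, v in acc.items()}
    return out


class TestBuildProfile:
    def test_constant_series_gives_constant_profile(self):
        idx = pd.date_range("1971-01-01", "2000-12-31", freq="D")
        series = DailySeries("const", pd.DataFrame({"tmax": 10.0, "tmin": 3.0}, index=idx))
        profile = build_profile(series, (1971, 2000))
        np.testing.assert_allclose(profile.clim_tmax, 10.0, atol=1e-12)
        np.testing.assert_allclose(profile.clim_tmin, 3.0, atol=1e-12)

    def test_sinusoid_matches_brute_force_windowed_mean(self):
        series = harmonic_series(1970, 1981)
        profile = build_profile(series, (1971, 1980), window_days=31)
        oracle = oracle_profile(series, (1971, 1980), 31)
        common = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        got_tmax = dict(zip(((d.month, d.day) for d in common), profile.clim_tmax))
        for md, expected in oracle["tmax"].items():
            assert got_tmax[md] == pytest.approx(expected, abs=1e-10)

    def test_attenuation_of_annual_harmonic_by_31_day_window(self):
        # centered n-day mean of cos(2πt/T) has gain sin(nπ/T)/(n sin(π/T))
        series = harmonic_series(1970, 1981, amplitude=8.0, mean=10.0)
        profile = build_profile(series, (1971, 1980), window_days=31)
        n, period = 31, 365.0
        gain = np.sin(n * np.pi / period) / (n * np.sin(np.pi / period))
        observed_amp = (profile.clim_tmax.max() - profile.clim_tmax.min()) / 2
        assert observed_amp == pytest.approx(8.0 * gain, rel=1e-3)

    def test_window_one_equals_plain_day_of_year_mean(self):
        series = harmonic_series(1971, 1980)
        profile = build_profile(series, (1971, 1980), window_days=1)
        data = series.data.loc["1971":"1980"]
        keep = ~((data.index.month == 2) & (data.index.day == 29))
        data = data[keep]
        grouped = data.groupby(md_key(data.index)).mean().sort_index()
        np.testing.assert_allclose(profile.clim_tmax, grouped["tmax"].to_numpy(), atol=1e-12)

    def test_profile_stays_within_series_range(self):
        rng = np.random.default_rng(3)
        idx = pd.date_range("1971-01-01", "2000-12-31", freq="D")
        tmax = 10 + 6 * np.cos(2 * np.pi * np.arange(len(idx)) / 365.25) + rng.normal(0, 2, len(idx))
        series = DailySeries("noisy", pd.DataFrame({"tmax": tmax, "tmin": tmax - 4}, index=idx))
        profile = build_profile(series, (1971, 2000))
        assert profile.clim_tmax.max() <= np.nanmax(tmax)
        assert profile.clim_tmax.min() >= np.nanmin(tmax)

    def test_profile_invariant_to_permuting_whole_reference_years(self):
        # day-of-year averaging is order-free, so with window 1 (no windows
        # crossing year boundaries) swapping whole years of data changes nothing
        rng = np.random.default_rng(11)
        idx = pd.date_range("1971-01-01", "1975-12-31", freq="D")
        tmax = 10 + 6 * np.sin(2 * np.pi * np.arange(len(idx)) / 365.25) + rng.normal(0, 2, len(idx))
        data = pd.DataFrame({"tmax": tmax, "tmin": tmax - 4}, index=idx)
        permuted = data.copy()
        # 1973, 1974, 1975 are all common years: cyclically permute their data
        for src, dst in (("1973", "1974"), ("1974", "1975"), ("1975", "1973")):
            permuted.loc[dst] = data.loc[src].to_numpy()
        p1 = build_profile(DailySeries("a", data), (1973, 1975), window_days=1)
        p2 = build_profile(DailySeries("b", permuted), (1973, 1975), window_days=1)
        np.testing.assert_allclose(p1.clim_tmax, p2.clim_tmax, atol=1e-12)
        np.testing.assert_allclose(p1.clim_tmin, p2.clim_tmin, atol=1e-12)

    def test_reference_period_not_covered_is_hard_error(self):
        series = harmonic_series(1980, 1995)
        with pytest.raises(ValidationError, match="not covered"):
            build_profile(series, (1971, 2000))

    def test_even_window_rejected(self):
        series = harmonic_series(1971, 2000)
        with pytest.raises(ValidationError, match="odd"):
            build_profile(series, (1971, 2000), window_days=30)

    def test_day_of_year_with_no_valid_contribution_is_hard_error(self):
        series = harmonic_series(1971, 1980)
        data = series.data.copy()
        # knock out the same 60-day block every year: central windows all invalid
        for year in range(1971, 1981):
            data.loc[f"{year}-05-01":f"{year}-06-29"] = np.nan
        broken = DailySeries("gappy", data)
        with pytest.raises(ValidationError, match="zero valid contributions"):
            build_profile(broken, (1971, 1980))


class TestComputeAnomalies:
    def test_series_equal_to_profile_gives_zero_anomalies(self):
        idx = pd.date_range("1971-01-01", "2000-12-31", freq="D")
        series = DailySeries("const", pd.DataFrame({"tmax": 12.0, "tmin": 5.0}, index=idx))
        profile = build_profile(series, (1971, 2000))
        anoms = compute_anomalies(series, profile)
        np.testing.assert_allclose(anoms.tmax_anom, 0.0, atol=1e-12)
        np.testing.assert_allclose(anoms.tmin_anom, 0.0, atol=1e-12)

    def test_uniform_shift_appears_directly_in_anomalies(self):
        series = harmonic_series(1971, 2000)
        profile = build_profile(series, (1971, 2000))
        shifted = DailySeries("shifted", series.data + 2.0)
        anoms0 = compute_anomalies(series, profile)
        anoms2 = compute_anomalies(shifted, profile)
        np.testing.assert_allclose(
            anoms2.tmax_anom.to_numpy(), anoms0.tmax_anom.to_numpy() + 2.0, atol=1e-12
        )

    @given(c=st.floats(-30, 30, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_anomaly_linearity_in_constant_offsets(self, c):
        series = harmonic_series(1996, 1999)
        profile = build_profile(series, (1997, 1998))
        base = compute_anomalies(series, profile).tmax_anom.to_numpy()
        shifted = compute_anomalies(
            DailySeries("s", series.data + c), profile
        ).tmax_anom.to_numpy()
        np.testing.assert_allclose(shifted, base + c, atol=1e-9)

    def test_zero_mean_anomaly_per_day_of_year_at_window_one(self):
        # with no smoothing the profile IS the day-of-year mean, so anomalies
        # average to zero per calendar day over the reference period; wider
        # windows attenuate the seasonal harmonic and leave a small residual
        rng = np.random.default_rng(5)
        idx = pd.date_range("1971-01-01", "1980-12-31", freq="D")
        tmax = 10 + 8 * np.cos(2 * np.pi * np.arange(len(idx)) / 365.25) + rng.normal(0, 2, len(idx))
        series = DailySeries("s", pd.DataFrame({"tmax": tmax, "tmin": tmax - 4}, index=idx))
        profile = build_profile(series, (1971, 1980), window_days=1)
        anoms = compute_anomalies(series, profile).slice_years(1971, 1980)
        keep = ~((anoms.dates.month == 2) & (anoms.dates.day == 29))
        frame = anoms.data[keep]
        grouped = frame.groupby(md_key(frame.index))
        assert grouped["tmax_anom"].mean().abs().max() < 1e-9

    def test_wide_window_attenuation_bounds_the_mean_anomaly_residual(self):
        # rolling-then-average leaves ~(1-gain)*amplitude of structure in the
        # per-day mean anomaly; for a 31-day window on an annual harmonic the
        # residual is small but nonzero — the order of operations is pinned
        series = calendar_harmonic_series(1970, 1981, amplitude=8.0)
        profile = build_profile(series, (1971, 1980), window_days=31)
        anoms = compute_anomalies(series, profile).slice_years(1971, 1980)
        keep = ~((anoms.dates.month == 2) & (anoms.dates.day == 29))
        frame = anoms.data[keep]
        residual = frame.groupby(md_key(frame.index))["tmax_anom"].mean().abs().max()
        n, period = 31, 365.0
        gain = np.sin(n * np.pi / period) / (n * np.sin(np.pi / period))
        assert 0.5 * (1 - gain) * 8.0 < residual < 2 * (1 - gain) * 8.0

    def test_feb29_uses_feb28_profile_value(self):
        series = harmonic_series(1999, 2001)  # 2000 is a leap year
        profile = build_profile(series, (1999, 2001))
        anoms = compute_anomalies(series, profile)
        raw = series.data.loc["2000-02-29", "tmax"]
        feb28_clim, _ = profile.value_for(pd.Timestamp("2000-02-28"))
        assert anoms.data.loc["2000-02-29", "tmax_anom"] == pytest.approx(raw - feb28_clim)

    def test_masks_propagate_from_series_to_anomalies(self):
        series = harmonic_series(1971, 1975)
        data = series.data.copy()
        data.loc["1973-06-01":"1973-06-10"] = np.nan
        series = DailySeries("gappy", data)
        profile = build_profile(series, (1971, 1975))
        anoms = compute_anomalies(series, profile)
        assert anoms.data.loc["1973-06-01":"1973-06-10", "tmax_anom"].isna().all()
        assert anoms.data.loc["1973-06-11", "tmax_anom"] == pytest.approx(
            series.data.loc["1973-06-11", "tmax"] - profile.value_for(pd.Timestamp("1973-06-11"))[0]
        )
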