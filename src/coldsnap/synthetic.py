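"""Synthetic daily-temperature and plot-record generators with known truth.

The climate generator produces decades of daily Tmax/Tmin as a seasonal
harmonic plus an optional linear trend plus AR(1) weather noise, with
multi-day cold spells of known start, depth and duration injected on
*both* variables as a temperature ceiling (`min(ambient, seasonal −
depth)`) — a cold air mass caps the local temperature, so ambient noise
can deepen a spell but never lift it, and the ground truth for the
both-variable detection criterion is unambiguous.  The seasonal defaults
mimic a hyper-oceanic north-Atlantic site (winter means 3–6 °C, summer
12–15 °C).

The plot generator produces field × treatment × year ecological records:
invaded plots carry logistic canopy curves (leaf area and light
interception) and suppressed resident richness; an event year applies
known multipliers to leaf area, biomass and richness, with the richness
release persisting afterwards and the canopy recovering, while uninvaded
plots are untouched by the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from coldsnap.ecology import PlotRecord
from coldsnap.io import DailySeries, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Spell:
    """One injected cold spell: start date, depth (°C, subtracted) and length."""

    start: pd.Timestamp
    depth: float
    duration: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        if self.duration < 1:
            raise ValidationError("spell duration must be >= 1 day")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(days=self.duration - 1)


@dataclass
class ClimateSimConfig:
    """Configuration of the synthetic daily-temperature generator.

    Seasonal cycle: ``tmax = tmax_mean - tmax_amplitude * cos(2π (doy - coldest_doy)/365.25)``
    and ``tmin = tmax - diurnal_offset`` before noise.  Noise is a shared
    AR(1) process (lag-1 coefficient ``noise_ar1``, marginal std
    ``noise_std``) plus small independent white components per variable,
    so cold excursions hit both variables together the way real cold
    spells do.
    """

    start_year: int = 1957
    end_year: int = 2023
    tmax_mean: float = 10.5  # °C; with amplitude 4.5: winter 6, summer 15
    tmax_amplitude: float = 4.5
    diurnal_offset: float = 3.0  # tmax - tmin; winter tmin ≈ 3 °C
    coldest_doy: int = 15
    noise_std: float = 1.0
    noise_ar1: float = 0.7
    independent_noise_fraction: float = 0.3
    trend_per_decade: float = 0.0  # °C per decade, linear
    spells: Sequence[Spell] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValidationError("noise_std must be >= 0")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValidationError("noise_ar1 must be in [0, 1)")
        if self.end_year < self.start_year:
            raise ValidationError("end_year must be >= start_year")
        self.spells = [s if isinstance(s, Spell) else Spell(*s) for s in self.spells]


def simulate_climate(config: ClimateSimConfig) -> tuple[DailySeries, list[Spell]]:
    """Generate a daily Tmax/Tmin series and return the injected ground truth.

    Reproducible under a fixed seed.  Days where the noise realisation
    would push Tmin above Tmax are clamped (Tmin := Tmax) and counted in
    the log.
    """
    rng = np.random.default_rng(config.seed)
    idx = pd.date_range(
        f"{config.start_year}-01-01", f"{config.end_year}-12-31", freq="D"
    )
    n = len(idx)
    doy = idx.dayofyear.to_numpy()
    seasonal_tmax = config.tmax_mean - config.tmax_amplitude * np.cos(
        2 * np.pi * (doy - config.coldest_doy) / 365.25
    )
    t_days = np.arange(n)
    trend = config.trend_per_decade * t_days / 3652.5

    shared = _ar1(rng, n, config.noise_ar1, config.noise_std)
    ind_sd = config.independent_noise_fraction * config.noise_std
    tmax = seasonal_tmax + trend + shared + rng.normal(0.0, ind_sd, n)
    tmin = seasonal_tmax - config.diurnal_offset + trend + shared + rng.normal(0.0, ind_sd, n)

    truth: list[Spell] = []
    for spell in sorted(config.spells, key=lambda s: s.start):
        if spell.start < idx[0] or spell.end > idx[-1]:
            raise ValidationError(
                f"spell {spell.start.date()} (+{spell.duration}d) outside series span"
            )
        i0 = (spell.start - idx[0]).days
        sl = slice(i0, i0 + spell.duration)
        # a cold air mass acts as a ceiling: ambient weather can deepen the
        # spell but never lift it above `depth` below the seasonal norm,
        # so the injected ground truth stays exact under detection
        tmax[sl] = np.minimum(tmax[sl], seasonal_tmax[sl] + trend[sl] - spell.depth)
        tmin[sl] = np.minimum(
            tmin[sl], seasonal_tmax[sl] - config.diurnal_offset + trend[sl] - spell.depth
        )
        truth.append(spell)

    n_clamped = int((tmin > tmax).sum())
    if n_clamped:
        logger.info("clamped tmin to tmax on %d day(s)", n_clamped)
        tmin = np.minimum(tmin, tmax)

    frame = pd.DataFrame({"tmax": tmax, "tmin": tmin}, index=idx)
    return DailySeries("synthetic", frame), truth


def _ar1(rng: np.random.Generator, n: int, phi: float, marginal_std: float) -> np.ndarray:
    """Stationary AR(1) draw with the given marginal standard deviation."""
    if marginal_std == 0:
        return np.zeros(n)
    innov_sd = marginal_std * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, marginal_std)
    eps = rng.normal(0.0, innov_sd, n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def poisson_spell_config(
    rate_per_decade: float,
    start_year: int,
    end_year: int,
    depth: float = 6.0,
    duration: int = 5,
    seed: int = 0,
    **kwargs,
) -> ClimateSimConfig:
    """Climate config with cold spells injected as a Poisson process.

    Spell count over the series is Poisson with mean
    ``rate_per_decade × years / 10``; starts fall uniformly in the
    January–March windows so every spell can qualify under the default
    seasonal criterion, and spells are re-drawn on collision so they stay
    disjoint.
    """
    rng = np.random.default_rng(seed)
    years = end_year - start_year + 1
    n_spells = rng.poisson(rate_per_decade * years / 10.0)
    occupied: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    spells = []
    attempts = 0
    while len(spells) < n_spells and attempts < 100 * max(n_spells, 1):
        attempts += 1
        year = int(rng.integers(start_year, end_year + 1))
        # keep the whole spell inside Jan 1 .. Mar 31
        offset = int(rng.integers(0, 90 - duration))
        start = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=offset)
        end = start + pd.Timedelta(days=duration - 1)
        # one-day buffer so adjacent spells cannot merge into one run
        if any(start <= e + pd.Timedelta(days=1) and end >= s - pd.Timedelta(days=1) for s, e in occupied):
            continue
        occupied.append((start, end))
        spells.append(Spell(start, depth, duration))
    spells.sort(key=lambda s: s.start)
    return ClimateSimConfig(
        start_year=start_year,
        end_year=end_year,
        spells=spells,
        seed=int(rng.integers(2**31)),
        **kwargs,
    )


@dataclass
class PlotSimConfig:
    """Configuration of the synthetic plot-record generator.

    Canopy curves are logistic in day of year:
    ``asymptote / (1 + exp(-rate (doy - midpoint)))``, sampled biweekly.
    In the event year, invaded plots have their leaf-area asymptote
    multiplied by ``ewe_leaf_area_factor``, shoot and total biomass by
    ``ewe_biomass_factor``, the interception asymptote replaced by
    ``ewe_interception_asymptote`` and the canopy midpoint delayed by
    ``ewe_delay_days``; resident richness is multiplied by
    ``ewe_richness_factor`` in the event year and persists afterwards,
    while the canopy recovers to ``recovery_fraction`` of normal.
    Uninvaded plots never respond to the event.
    """

    n_fields: int = 4
    years: tuple[int, int] = (2016, 2019)
    baseline_richness_invaded: float = 3.0
    baseline_richness_uninvaded: float = 9.0
    canopy_midpoint_doy: float = 120.0
    canopy_rate: float = 0.08  # per day
    leaf_area_asymptote: float = 2.9  # m² per plant in a normal year
    interception_asymptote: float = 0.98
    invaded_total_biomass: float = 1500.0  # g m^-2
    invaded_shoot_fraction: float = 0.6
    uninvaded_total_biomass: float = 600.0
    uninvaded_shoot_fraction: float = 0.5
    ewe_year: int | None = 2018
    ewe_leaf_area_factor: float = 1.0 / 11.0
    ewe_biomass_factor: float = 0.5
    ewe_richness_factor: float = 4.0
    ewe_interception_asymptote: float = 0.55
    ewe_delay_days: float = 90.0
    recovery_fraction: float = 0.95
    noise_cv: float = 0.05  # multiplicative lognormal CV on continuous metrics
    richness_noise: str = "poisson"  # "poisson" | "none"
    sample_interval_days: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ewe_leaf_area_factor", "ewe_biomass_factor", "ewe_richness_factor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0.0 < self.interception_asymptote <= 1.0:
            raise ValidationError("interception_asymptote must be in (0, 1]")
        if not 0.0 < self.ewe_interception_asymptote <= 1.0:
            raise ValidationError("ewe_interception_asymptote must be in (0, 1]")


def simulate_plots(config: PlotSimConfig) -> list[PlotRecord]:
    """Generate plot records for every field × treatment × year."""
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log1p(config.noise_cv**2))  # lognormal(−σ²/2, σ) has mean 1

    def noisy(value: float) -> float:
        if config.noise_cv == 0:
            return value
        return value * rng.lognormal(-0.5 * sigma * sigma, sigma)

    def draw_richness(mean: float) -> int:
        if config.richness_noise == "poisson":
            return int(rng.poisson(mean))
        return int(round(mean))

    records: list[PlotRecord] = []
    sample_doys = np.arange(15, 351, config.sample_interval_days)
    for f in range(1, config.n_fields + 1):
        for year in range(config.years[0], config.years[1] + 1):
            is_ewe = config.ewe_year is not None and year == config.ewe_year
            post_ewe = config.ewe_year is not None and year > config.ewe_year

            # --- invaded plot ---
            la_asym = config.leaf_area_asymptote
            li_asym = config.interception_asymptote
            midpoint = config.canopy_midpoint_doy
            biomass_scale = 1.0
            rich_mean = config.baseline_richness_invaded
            if is_ewe:
                la_asym *= config.ewe_leaf_area_factor
                li_asym = config.ewe_interception_asymptote
                midpoint += config.ewe_delay_days
                biomass_scale = config.ewe_biomass_factor
                rich_mean *= config.ewe_richness_factor
            elif post_ewe:
                la_asym *= config.recovery_fraction
                li_asym *= config.recovery_fraction
                biomass_scale = config.recovery_fraction
                rich_mean *= config.ewe_richness_factor  # release persists

            logistic = 1.0 / (1.0 + np.exp(-config.canopy_rate * (sample_doys - midpoint)))
            leaf_series = [
                (int(d), noisy(la_asym * g)) for d, g in zip(sample_doys, logistic)
            ]
            li_series = [
                (int(d), float(min(1.0, noisy(li_asym * g))))
                for d, g in zip(sample_doys, logistic)
            ]
            n_rich = draw_richness(rich_mean)
            records.append(
                PlotRecord(
                    field_id=f"F{f}",
                    treatment="invaded",
                    year=year,
                    species_present={f"sp{j:02d}" for j in range(n_rich)},
                    shoot_biomass=noisy(
                        config.invaded_total_biomass * config.invaded_shoot_fraction * biomass_scale
                    ),
                    total_biomass=noisy(config.invaded_total_biomass * biomass_scale),
                    leaf_area_series=leaf_series,
                    light_interception_series=li_series,
                )
            )

            # --- uninvaded plot: no canopy curves, no event response ---
            n_rich_u = draw_richness(config.baseline_richness_uninvaded)
            records.append(
                PlotRecord(
                    field_id=f"F{f}",
                    treatment="uninvaded",
                    year=year,
                    species_present={f"sp{j:02d}" for j in range(n_rich_u)},
                    shoot_biomass=noisy(
                        config.uninvaded_total_biomass * config.uninvaded_shoot_fraction
                    ),
                    total_biomass=noisy(config.uninvaded_total_biomass),
                    leaf_area_series=[],
                    light_interception_series=[],
                )
            )
    return records
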