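"""Rule-based detection of multi-day cold events and per-decade rates.

A day qualifies when both the Tmax and the Tmin anomaly lie strictly
below the threshold (default −4 °C) and the date falls in an allowed
month (default January–March).  Maximal runs of consecutive qualifying
days at least ``min_duration`` long (default 4) are events.  Missing
anomaly days never qualify, so a gap conservatively breaks a run; the
month filter applies day-wise, so a run crossing out of the allowed
season is truncated before the length test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coldsnap.climatology import AnomalySeries, build_profile, compute_anomalies
from coldsnap.io import DailySeries, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventCriterion:
    """Threshold/duration/season rule defining a cold extreme event.

    ``anomaly_threshold`` uses strict "less than"; a day at exactly the
    threshold does not qualify.  With ``require_both_variables`` (the
    default) both Tmax and Tmin anomalies must be below threshold; if
    False, either one suffices.
    """

    anomaly_threshold: float = -4.0
    min_duration: int = 4
    allowed_months: frozenset[int] = frozenset({1, 2, 3})
    require_both_variables: bool = True

    def __post_init__(self) -> None:
        if self.min_duration < 1:
            raise ValidationError("min_duration must be >= 1")
        if not np.isfinite(self.anomaly_threshold):
            raise ValidationError("anomaly_threshold must be finite")
        object.__setattr__(self, "allowed_months", frozenset(self.allowed_months))


@dataclass(frozen=True)
class ColdEvent:
    """One detected event: an inclusive date range plus its extremes."""

    site_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration: int
    min_tmax_anom: float
    min_tmin_anom: float

    def __post_init__(self) -> None:
        if self.duration != (self.end - self.start).days + 1:
            raise ValidationError("duration must equal end - start + 1 (inclusive days)")


@dataclass(frozen=True)
class RateSummary:
    """Event count over a year range, expressed per decade."""

    n_events: int
    period: tuple[int, int]
    years: float
    events_per_decade: float

    def __str__(self) -> str:  # presentation-time rounding only
        return (
            f"{self.n_events} events over {self.period[0]}-{self.period[1]} "
            f"({self.years:g} yr): {self.events_per_decade:.1f} per decade"
        )


def qualifying_mask(anoms: AnomalySeries, criterion: EventCriterion = EventCriterion()) -> pd.Series:
    """Boolean per-date mask of days satisfying the cold criterion.

    Missing days are False: a gap can never extend a run.
    """
    thr = criterion.anomaly_threshold
    below_x = anoms.tmax_anom < thr  # NaN compares False
    below_n = anoms.tmin_anom < thr
    below = (below_x & below_n) if criterion.require_both_variables else (below_x | below_n)
    in_season = anoms.dates.month.isin(sorted(criterion.allowed_months))
    return (below & in_season).rename("qualifies")


def detect_events(
    anoms: AnomalySeries, criterion: EventCriterion = EventCriterion()
) -> list[ColdEvent]:
    """Find maximal qualifying runs of at least ``min_duration`` days.

    Runs separated by one or more non-qualifying days are distinct
    events; events come out sorted and non-overlapping, each carrying
    its most negative Tmax and Tmin anomalies.
    """
    mask = qualifying_mask(anoms, criterion).to_numpy()
    events: list[ColdEvent] = []
    for i0, i1 in _runs(mask):
        if i1 - i0 < criterion.min_duration:
            continue
        seg = anoms.data.iloc[i0:i1]
        events.append(
            ColdEvent(
                site_id=anoms.site_id,
                start=anoms.dates[i0],
                end=anoms.dates[i1 - 1],
                duration=i1 - i0,
                min_tmax_anom=float(seg["tmax_anom"].min()),
                min_tmin_anom=float(seg["tmin_anom"].min()),
            )
        )
    logger.info("detected %d event(s) for site %s", len(events), anoms.site_id)
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) spans of consecutive True values."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def event_rate(events: Sequence[ColdEvent], period: tuple[int, int]) -> RateSummary:
    """Summarise events over an inclusive year range as a per-decade rate.

    ``years`` is the inclusive year count (1957–2023 → 67); rounding of
    the per-decade figure happens only at presentation time.
    """
    start_year, end_year = period
    years = end_year - start_year + 1
    if years <= 0:
        raise ValidationError(f"empty period {start_year}-{end_year}")
    for ev in events:
        if not (start_year <= ev.start.year and ev.end.year <= end_year):
            raise ValidationError(
                f"event {ev.start.date()}..{ev.end.date()} outside period {start_year}-{end_year}"
            )
    return RateSummary(
        n_events=len(events),
        period=(start_year, end_year),
        years=float(years),
        events_per_decade=10.0 * len(events) / years,
    )


def scenario_comparison(
    historical: DailySeries,
    scenarios: Mapping[str, DailySeries],
    profile_period: tuple[int, int] = (1971, 2000),
    eval_period: tuple[int, int] = (2071, 2100),
    criterion: EventCriterion = EventCriterion(),
    window_days: int = 31,
) -> pd.DataFrame:
    """Compare event rates between a model-historical run and scenario runs.

    The climatology profile is always built from the model's own
    historical run over ``profile_period`` — never from observations —
    and applied to every scenario series.  The historical run itself is
    evaluated over ``profile_period``; each scenario over ``eval_period``.

    Returns a table with one row per label (historical first) and columns
    label, n_events, start, end, years, events_per_decade.
    """
    profile = build_profile(historical, profile_period, window_days=window_days)

    rows = []

    def _row(label: str, series: DailySeries, period: tuple[int, int]) -> None:
        sub = series.slice_years(*period)
        anoms = compute_anomalies(sub, profile)
        events = detect_events(anoms, criterion)
        rate = event_rate(events, period)
        rows.append(
            {
                "label": label,
                "n_events": rate.n_events,
                "start": period[0],
                "end": period[1],
                "years": rate.years,
                "events_per_decade": rate.events_per_decade,
            }
        )

    _row("historical", historical, profile_period)
    for label, series in scenarios.items():
        first, last = series.dates[0].year, series.dates[-1].year
        if first > eval_period[0] or last < eval_period[1]:
            raise ValidationError(
                f"scenario {label!r} ({first}-{last}) does not cover {eval_period[0]}-{eval_period[1]}"
            )
        _row(label, series, eval_period)
    return pd.DataFrame(rows)
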