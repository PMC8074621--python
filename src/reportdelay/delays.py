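"""Reporting-delay construction: delays in days, threshold indicators,
log-delays, per-district summaries and occurrence-date temporal features.

The delay of an incident is the whole number of calendar days between its
occurrence date and its report date.  Three nested binary indicators mark
reporting within one day, one week and one month; the regression target is
``log(1 + delay)`` so that same-day reports remain defined.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: threshold (in days) for each indicator column
THRESHOLDS = {"d_day": 1, "d_week": 7, "d_month": 30}

HOLIDAY_FLAGS = ["federal", "christian", "muslim", "jewish", "hindu", "celebration"]
SEASONS = ["winter", "spring", "summer", "fall"]
TEMPORAL_COLUMNS = SEASONS + ["weekend"] + HOLIDAY_FLAGS


def load_calendar(path=None) -> pd.DataFrame:
    """Load the holiday calendar (bundled table by default).

    Returns a frame indexed by date with one 0/1 column per holiday flag.
    Coverage runs from Jan 1 of the earliest year to Dec 31 of the latest
    year present in the table; dates in between with no row carry all-zero
    flags.
    """
    if path is None:
        with resources.files("reportdelay.data").joinpath("holidays.csv").open() as fh:
            cal = pd.read_csv(fh, parse_dates=["date"])
    else:
        cal = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in HOLIDAY_FLAGS if c not in cal.columns]
    if missing:
        raise ValueError(f"calendar table missing flag columns: {missing}")
    return cal.set_index("date")[HOLIDAY_FLAGS].astype(np.int8)


def calendar_coverage(calendar: pd.DataFrame) -> tuple[pd.Timestamp, pd.Timestamp]:
    years = calendar.index.year
    return (pd.Timestamp(int(years.min()), 1, 1), pd.Timestamp(int(years.max()), 12, 31))


def compute_delay(occurrence_date, report_date):
    """Whole-day delay between occurrence and report (vectorised).

    Returns an integer array alongside a boolean validity mask: a report
    dated before its occurrence signals a recording error and is flagged
    invalid rather than clamped.
    """
    occ = pd.to_datetime(occurrence_date)
    rep = pd.to_datetime(report_date)
    scalar = np.ndim(occ) == 0
    occ = pd.DatetimeIndex([occ]) if scalar else pd.DatetimeIndex(occ)
    rep = pd.DatetimeIndex([rep]) if scalar else pd.DatetimeIndex(rep)
    delta = (rep.normalize() - occ.normalize()).days
    valid = delta >= 0
    if scalar:
        return int(delta[0]), bool(valid[0])
    return np.asarray(delta), np.asarray(valid)


def binarize_delay(delay_days):
    """Nested indicators (d_day, d_week, d_month) for a delay in days."""
    dt = np.asarray(delay_days)
    if np.any(dt < 0):
        raise ValueError("negative delay")
    return tuple((dt <= THRESHOLDS[c]).astype(np.int8) for c in THRESHOLDS)


def log_delay(delay_days):
    """log(1 + delay): 0 at a same-day report, strictly increasing."""
    dt = np.asarray(delay_days, dtype=float)
    if np.any(dt < 0):
        raise ValueError("negative delay")
    return np.log1p(dt)


def add_delay_columns(events: pd.DataFrame) -> pd.DataFrame:
    """Derive delay_days, the three indicators and log_delay on an event table.

    Rows with a report date before the occurrence date are dropped with a
    logged count (they indicate data errors, not long delays).
    """
    delta, valid = compute_delay(events["occurrence_date"], events["report_date"])
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("dropping %d events with report date before occurrence", n_bad)
    out = events.loc[valid].copy()
    out["delay_days"] = delta[valid].astype(int)
    d_day, d_week, d_month = binarize_delay(out["delay_days"].to_numpy())
    out["d_day"], out["d_week"], out["d_month"] = d_day, d_week, d_month
    out["log_delay"] = log_delay(out["delay_days"].to_numpy())
    return out


def filter_events(
    events: pd.DataFrame,
    offence_classes: Iterable[str] | None = None,
    premises_classes: Iterable[str] | None = None,
    report_window: tuple | None = None,
) -> pd.DataFrame:
    """Restrict an event table to given offence/premises classes and a
    report-date window (inclusive on both ends).

    Criteria left as ``None`` pass everything.  An empty result is a
    warning, not an error.
    """
    mask = pd.Series(True, index=events.index)
    if offence_classes is not None:
        mask &= events["offence"].isin(set(offence_classes))
    if premises_classes is not None:
        mask &= events["premises"].isin(set(premises_classes))
    if report_window is not None:
        lo, hi = (pd.Timestamp(report_window[0]), pd.Timestamp(report_window[1]))
        rep = pd.to_datetime(events["report_date"])
        mask &= (rep >= lo) & (rep <= hi)
    out = events.loc[mask]
    logger.info("filter_events: %d of %d records retained", len(out), len(events))
    if out.empty:
        logger.warning("filter_events produced an empty table")
    return out


def area_summaries(events: pd.DataFrame, district_ids: Sequence) -> pd.DataFrame:
    """Per-district event count, reporting proportions and median delay.

    p^{day}_j is the mean of d_day over events in district j (likewise week
    and month); the median delay is over raw integer days.  Districts with
    no events carry NaN summaries and are excluded from areal tests.
    """
    known = set(district_ids)
    unknown = set(events["district_id"]) - known
    if unknown:
        raise KeyError(f"events reference unknown district ids: {sorted(unknown)!r}")
    grouped = events.groupby("district_id")
    agg = grouped.agg(
        n=("delay_days", "size"),
        p_day=("d_day", "mean"),
        p_week=("d_week", "mean"),
        p_month=("d_month", "mean"),
        median_delay=("delay_days", "median"),
        mean_log_delay=("log_delay", "mean"),
    )
    out = agg.reindex(district_ids)
    out["n"] = out["n"].fillna(0).astype(int)
    n_empty = int((out["n"] == 0).sum())
    if n_empty:
        logger.info("area_summaries: %d districts have no events", n_empty)
    return out


def ensure_temporal_features(events: pd.DataFrame, calendar=None) -> pd.DataFrame:
    """Attach any missing occurrence-date temporal flags (idempotent)."""
    missing = [c for c in TEMPORAL_COLUMNS if c not in events.columns]
    if not missing:
        return events
    tf = temporal_features(events["occurrence_date"], calendar)
    tf.index = events.index
    return pd.concat([events, tf[missing]], axis=1)


def _season_of(month: np.ndarray) -> np.ndarray:
    # meteorological seasons: DJF / MAM / JJA / SON
    return np.select(
        [np.isin(month, (12, 1, 2)), np.isin(month, (3, 4, 5)), np.isin(month, (6, 7, 8))],
        ["winter", "spring", "summer"],
        default="fall",
    )


def temporal_features(dates, calendar: pd.DataFrame | None = None) -> pd.DataFrame:
    """Binary temporal flags of occurrence dates: season (exactly one of
    four), weekend, and the six holiday-calendar flags.

    Raises if any date falls outside the calendar's coverage years, since
    absent rows would silently read as "no holiday".
    """
    if calendar is None:
        calendar = load_calendar()
    idx = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    lo, hi = calendar_coverage(calendar)
    if len(idx) and (idx.min() < lo or idx.max() > hi):
        raise ValueError(
            f"dates outside calendar coverage {lo.date()}..{hi.date()}; "
            "extend the calendar table to the required years"
        )
    out = pd.DataFrame(index=range(len(idx)))
    season = _season_of(idx.month.to_numpy())
    for s in SEASONS:
        out[s] = (season == s).astype(np.int8)
    out["weekend"] = (idx.dayofweek >= 5).astype(np.int8)
    flags = calendar.reindex(idx).fillna(0).astype(np.int8)
    for c in HOLIDAY_FLAGS:
        out[c] = flags[c].to_numpy()
    return out
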