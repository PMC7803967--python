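"""Daily counts, inter-species correlation and departure/return schedules.

The per-day count is the maximum number of simultaneous detections in any
single frame of that day.  Departure and return times are the argmax of
the backward 1-hour moving average of frame counts within the morning and
evening halves of the recording window.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "frame_counts",
    "daily_count",
    "pearson",
    "backward_moving_average",
    "departure_return",
    "schedule_tests",
    "ScheduleTestReport",
]

MORNING_WINDOW = (dt.time(4, 0), dt.time(12, 0))
EVENING_WINDOW = (dt.time(12, 0), dt.time(20, 0))


def _filtered(records: pd.DataFrame, species, score_threshold: float) -> pd.DataFrame:
    out = records[records["score"] >= score_threshold]
    if species is not None:
        out = out[out["species"] == species]
    return out


def frame_counts(
    records: pd.DataFrame,
    species: str | None = None,
    score_threshold: float = 0.5,
    frame_index: pd.DatetimeIndex | None = None,
) -> pd.Series:
    """Per-frame detection counts, indexed by timestamp.

    Only frames that produced at least one record appear unless
    ``frame_index`` supplies the full frame grid (absent frames then count
    as zero).
    """
    sel = _filtered(records, species, score_threshold)
    counts = sel.groupby("timestamp").size().sort_index()
    if frame_index is not None:
        counts = counts.reindex(frame_index, fill_value=0)
    counts.index = pd.DatetimeIndex(counts.index)
    return counts.astype(int)


def daily_count(
    records: pd.DataFrame,
    species: str | None = None,
    score_threshold: float = 0.5,
) -> pd.Series:
    """Per-day max of the per-frame count; days with no frames are absent."""
    counts = frame_counts(records, species, score_threshold)
    if counts.empty:
        return pd.Series(dtype=int)
    return counts.groupby(counts.index.date).max()


def pearson(series_a: pd.Series, series_b: pd.Series) -> float:
    """Pearson correlation of two day-aligned series."""
    joined = pd.concat([series_a, series_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 aligned days")
    a = joined.iloc[:, 0].to_numpy(float)
    b = joined.iloc[:, 1].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance series")
    return float(np.corrcoef(a, b)[0, 1])


def backward_moving_average(series: pd.Series, window: str = "1h") -> pd.Series:
    """Mean over timestamps in ``(t - window, t]`` at each point.

    Points whose backward window is only partially populated use the
    available samples.
    """
    series = series.sort_index()
    return series.rolling(window, closed="right", min_periods=1).mean()


def departure_return(
    day_series: pd.Series,
    window: str = "1h",
    morning: tuple = MORNING_WINDOW,
    evening: tuple = EVENING_WINDOW,
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Departure and return times for one day of frame counts.

    Departure is the argmax of the smoothed series within the morning
    window, return the argmax within the evening window; ties resolve to
    the earliest time.
    """
    smoothed = backward_moving_average(day_series, window)
    morning_part = smoothed.between_time(morning[0], morning[1], inclusive="left")
    evening_part = smoothed.between_time(evening[0], evening[1], inclusive="both")
    if morning_part.empty or evening_part.empty:
        raise ValueError("day does not cover both morning and evening windows")
    return morning_part.idxmax(), evening_part.idxmax()


@dataclass
class ScheduleTestReport:
    ht1_t: float
    ht1_p: float
    ht1_reject: bool
    ht2_t: float
    ht2_p: float
    ht2_reject: bool
    n_pairs: int
    degenerate: bool
    alpha: float = 0.05


def _minutes(times: pd.Series) -> np.ndarray:
    idx = pd.DatetimeIndex(times)
    return (idx.hour * 60 + idx.minute + idx.second / 60.0).to_numpy(float)


def schedule_tests(
    departures_g: pd.Series,
    departures_l: pd.Series,
    returns_g: pd.Series,
    returns_l: pd.Series,
    alpha: float = 0.05,
) -> ScheduleTestReport:
    """Paired t-tests on the two-species schedule, day-aligned.

    HT1 (two-tailed): departure times of the two species are equal.
    HT2 (one-tailed): the great egrets return at the same time as or later
    than the little egrets; the alternative is that they return earlier.
    Times are compared in minutes since midnight.
    """
    dep = pd.concat([departures_g, departures_l], axis=1, join="inner").dropna()
    ret = pd.concat([returns_g, returns_l], axis=1, join="inner").dropna()
    n = min(len(dep), len(ret))
    if n < 3:
        raise ValueError("need at least 3 complete day pairs")

    dep_g, dep_l = _minutes(dep.iloc[:, 0]), _minutes(dep.iloc[:, 1])
    ret_g, ret_l = _minutes(ret.iloc[:, 0]), _minutes(ret.iloc[:, 1])

    degenerate = False
    d1 = dep_g - dep_l
    if np.std(d1, ddof=1) == 0:
        degenerate = True
        t1, p1 = (0.0, 1.0) if np.allclose(d1, 0) else (np.inf, 0.0)
    else:
        t1, p1 = stats.ttest_rel(dep_g, dep_l)
    d2 = ret_g - ret_l
    if np.std(d2, ddof=1) == 0:
        degenerate = True
        t2, p2 = (0.0, 1.0) if np.allclose(d2, 0) else (
            (-np.inf, 0.0) if d2.mean() < 0 else (np.inf, 1.0)
        )
    else:
        t2, p2 = stats.ttest_rel(ret_g, ret_l, alternative="less")
    return ScheduleTestReport(
        ht1_t=float(t1), ht1_p=float(p1), ht1_reject=bool(p1 < alpha),
        ht2_t=float(t2), ht2_p=float(p2), ht2_reject=bool(p2 < alpha),
        n_pairs=int(len(dep)), degenerate=degenerate, alpha=alpha,
    )


def daily_schedule(
    records: pd.DataFrame,
    species: str,
    score_threshold: float = 0.5,
    window: str = "1h",
    frame_index: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Departure/return per day for one species, as a two-column frame."""
    counts = frame_counts(records, species, score_threshold, frame_index)
    out = []
    for day, day_counts in counts.groupby(counts.index.date):
        try:
            dep, ret = departure_return(day_counts, window)
        except ValueError:
            continue
        out.append({"date": day, "departure": dep, "return": ret})
    return pd.DataFrame(out).set_index("date") if out else pd.DataFrame(
        columns=["departure", "return"]
    )
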