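"""Calcium transient detection and event statistics.

Events are threshold crossings of the z-scored ΔF/F trace (3 Z above the
mean for state analyses; 2 Z for pharmacology contrasts).  Each maximal
contiguous suprathreshold excursion yields one event whose peak is the
excursion maximum and whose onset is found by walking backward from the
peak to the 20%-of-maximum crossing (linearly interpolated).  To keep
frame-rate noise from spawning spurious crossings, the trace is
pre-smoothed with a Gaussian matched to the indicator rise time and an
excursion must stay above threshold for ``min_samples`` consecutive
frames; both guards are configurable (σ = 0, min_samples = 1 recovers the
bare threshold-crossing rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from hippostate.states import StateInterval

__all__ = [
    "CalciumEvent",
    "EventDetectionConfig",
    "detect_events",
    "detect_events_matrix",
    "detection_delay",
    "event_rates",
    "burst_fraction",
    "events_to_frame",
]


@dataclass(frozen=True)
class CalciumEvent:
    """One detected calcium transient."""

    cell_id: int
    onset_time: float  # 20%-of-max crossing, s
    peak_time: float
    amplitude: float  # peak z-value
    threshold_used: float

    def __post_init__(self) -> None:
        if self.onset_time > self.peak_time:
            raise ValueError("onset must not follow the peak")


@dataclass
class EventDetectionConfig:
    """Detection parameters.

    threshold_z: 3 for behavioral-state analyses, 2 for drug contrasts.
    onset_fraction: amplitude fraction defining the event start (0.2).
    min_samples: consecutive suprathreshold frames required (noise guard;
        set to 1 for the bare threshold-crossing rule).
    smooth_sigma_s: Gaussian pre-smoothing of the trace.  The default
        (100 ms, two frames) is matched to the indicator's rise-to-peak
        time so that frame-rate noise is suppressed without blurring the
        transient; set to 0 to disable.
    robust: z-score with median/MAD instead of mean/SD.
    """

    threshold_z: float = 3.0
    onset_fraction: float = 0.2
    min_samples: int = 2
    smooth_sigma_s: float = 0.1
    robust: bool = False

    def __post_init__(self) -> None:
        if self.threshold_z <= 0:
            raise ValueError("threshold_z must be positive")
        if not 0 < self.onset_fraction < 1:
            raise ValueError("onset_fraction must be in (0, 1)")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def zscore_trace(trace: np.ndarray, robust: bool = False) -> np.ndarray:
    """Z-score a trace against its full-recording mean/SD (or median/MAD)."""
    trace = np.asarray(trace, dtype=float)
    if robust:
        center = np.median(trace)
        scale = 1.4826 * np.median(np.abs(trace - center))
    else:
        center = trace.mean()
        scale = trace.std()
    if scale == 0:
        raise ValueError("zero-variance trace cannot be z-scored")
    return (trace - center) / scale


def detect_events(
    trace: np.ndarray,
    frame_rate: float,
    config: EventDetectionConfig | None = None,
    cell_id: int = 0,
    start_time: float = 0.0,
) -> list[CalciumEvent]:
    """Detect calcium transients on one ΔF/F trace."""
    config = config or EventDetectionConfig()
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must have at least 2 samples")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    if config.smooth_sigma_s > 0:
        trace = gaussian_filter1d(trace, config.smooth_sigma_s * frame_rate,
                                  mode="reflect")
    z = zscore_trace(trace, robust=config.robust)

    above = z > config.threshold_z
    if not above.any():
        return []
    padded = np.diff(np.concatenate([[0], above.astype(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)

    events: list[CalciumEvent] = []
    for i0, i1 in zip(starts, ends):
        if i1 - i0 < config.min_samples:
            continue
        peak = i0 + int(np.argmax(z[i0:i1]))
        amp = float(z[peak])
        level = config.onset_fraction * amp
        # walk backward from the peak to the first crossing of the level
        j = peak
        while j > 0 and z[j - 1] > level:
            j -= 1
        if j == 0 and z[0] > level:
            onset_idx = 0.0
        else:
            lo, hi = z[j - 1], z[j]
            frac = (level - lo) / (hi - lo) if hi != lo else 0.0
            onset_idx = (j - 1) + frac
        events.append(
            CalciumEvent(
                cell_id=cell_id,
                onset_time=start_time + onset_idx / frame_rate,
                peak_time=start_time + peak / frame_rate,
                amplitude=amp,
                threshold_used=config.threshold_z,
            )
        )
    return events


def detect_events_matrix(
    fluor, config: EventDetectionConfig | None = None
) -> list[CalciumEvent]:
    """Detect events on every trace of a FluorescenceMatrix."""
    events: list[CalciumEvent] = []
    for i, cid in enumerate(fluor.cell_ids):
        events.extend(
            detect_events(
                fluor.traces[i],
                fluor.frame_rate,
                config,
                cell_id=cid,
                start_time=fluor.start_time,
            )
        )
    return sorted(events, key=lambda e: (e.cell_id, e.onset_time))


def detection_delay(
    trace: np.ndarray,
    frame_rate: float,
    events: list[CalciumEvent],
    start_z: float = 0.5,
    start_time: float = 0.0,
    robust: bool = False,
) -> dict:
    """Mean delay between transient start and detected onset.

    The transient start is the last sample at or below ``start_z`` before
    the onset crossing.  Events with no such sample are skipped and counted.
    Returns {'mean', 'se', 'n', 'n_skipped'}.
    """
    if not events:
        raise ValueError("no events to average")
    z = zscore_trace(trace, robust=robust)
    delays: list[float] = []
    skipped = 0
    for ev in events:
        onset_idx = (ev.onset_time - start_time) * frame_rate
        j = int(np.floor(onset_idx))
        while j >= 0 and z[j] > start_z:
            j -= 1
        if j < 0:
            skipped += 1
            continue
        delays.append(ev.onset_time - (start_time + j / frame_rate))
    if not delays:
        raise ValueError("no events with a defined transient start")
    arr = np.array(delays)
    se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
    return {"mean": float(arr.mean()), "se": float(se), "n": len(arr),
            "n_skipped": skipped}


def _check_non_overlapping(intervals: list[StateInterval]) -> None:
    ivs = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs[:-1], ivs[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping intervals: ({a.start}, {a.end}) and "
                f"({b.start}, {b.end})"
            )


def event_rates(
    events: list[CalciumEvent], intervals: list[StateInterval]
) -> pd.DataFrame:
    """Per-cell, per-state event rates (onset-in-interval counts / duration).

    Labels with zero total duration are excluded.  Returns a tidy frame
    with columns cell_id, state, n_events, duration_s, rate_hz.
    """
    _check_non_overlapping(intervals)
    durations: dict[str, float] = {}
    for iv in intervals:
        durations[iv.label] = durations.get(iv.label, 0.0) + iv.duration
    cells = sorted({ev.cell_id for ev in events})
    rows = []
    for label, dur in durations.items():
        if dur <= 0:
            continue
        label_ivs = [iv for iv in intervals if iv.label == label]
        for cid in cells:
            onsets = np.array(
                [ev.onset_time for ev in events if ev.cell_id == cid]
            )
            n = sum(
                int(np.sum((onsets >= iv.start) & (onsets < iv.end)))
                for iv in label_ivs
            )
            rows.append(
                {"cell_id": cid, "state": label, "n_events": n,
                 "duration_s": dur, "rate_hz": n / dur}
            )
    return pd.DataFrame(rows, columns=["cell_id", "state", "n_events",
                                       "duration_s", "rate_hz"])


def burst_fraction(
    events: list[CalciumEvent],
    speed_times: np.ndarray,
    speed: np.ndarray,
    rate_threshold: float = 0.5,
    speed_threshold: float = 0.5,
) -> dict:
    """Fraction of burst events coinciding with movement.

    The instantaneous rate of an event is 1 / (interval to the previous
    event of the same cell); events above ``rate_threshold`` are burst
    members.  Returns the fraction of burst members whose onset coincides
    with speed > ``speed_threshold`` and the complementary fraction.
    """
    by_cell: dict[int, list[float]] = {}
    for ev in sorted(events, key=lambda e: e.onset_time):
        by_cell.setdefault(ev.cell_id, []).append(ev.onset_time)
    burst_onsets: list[float] = []
    for onsets in by_cell.values():
        for prev, cur in zip(onsets[:-1], onsets[1:]):
            if 1.0 / (cur - prev) > rate_threshold:
                burst_onsets.append(cur)
    if not burst_onsets:
        return {"n_bursts": 0, "fraction_moving": np.nan,
                "fraction_immobile": np.nan}
    sp = np.interp(np.array(burst_onsets), np.asarray(speed_times, float),
                   np.asarray(speed, float))
    moving = float(np.mean(sp > speed_threshold))
    return {"n_bursts": len(burst_onsets), "fraction_moving": moving,
            "fraction_immobile": 1.0 - moving}


def events_to_frame(events: list[CalciumEvent]) -> pd.DataFrame:
    """Events as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {"cell_id": ev.cell_id, "onset_s": ev.onset_time,
             "peak_s": ev.peak_time, "amplitude_z": ev.amplitude,
             "threshold_z": ev.threshold_used}
            for ev in events
        ],
        columns=["cell_id", "onset_s", "peak_s", "amplitude_z", "threshold_z"],
    )
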