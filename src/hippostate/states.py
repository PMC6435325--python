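"""Behavioral-state scoring from speed, LFP band power, and context.

Four states are scored.  On the linear track, running (RUN) is speed
> 3 cm/s; track immobility is scored as quiet wakefulness (QW).  In the
sleep box, immobility (< 0.5 cm/s) sustained for at least 3 min marks the
transition into sleep: the scorer places sleep onset at the 3-min mark of
a continuous immobility run, labels the immobile lead-in as QW, and labels
the sleep portion SWS except where a sustained (>= 10 s) elevation of the
theta/delta power ratio arising out of SWS marks REM.  Immobility runs
shorter than 3 min are wakeful (QW) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "StateInterval",
    "StateConfig",
    "compute_speed",
    "score_track",
    "score_track_run",
    "score_sleepbox_states",
    "intervals_to_labels",
    "label_at",
]

STATE_LABELS = ("RUN", "QW", "SWS", "REM")


@dataclass(frozen=True)
class StateInterval:
    """A labeled behavioral epoch [start, end) in seconds."""

    label: str
    start: float
    end: float
    context: str = "sleepbox"  # "track" or "sleepbox"

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}")
        if not self.end > self.start:
            raise ValueError("interval end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StateConfig:
    """Thresholds for state scoring.

    run_speed / immobile_speed are the movement thresholds in cm/s;
    sws_min_immobility is the continuous-immobility requirement (s) before
    sleep onset; rem_min_duration is the minimum REM epoch length (s);
    theta_delta_ratio is the band-power ratio marking REM, evaluated over
    power_window-second sliding windows.
    """

    run_speed: float = 3.0
    immobile_speed: float = 0.5
    sws_min_immobility: float = 180.0
    rem_min_duration: float = 10.0
    theta_band: tuple[float, float] = (5.0, 12.0)
    delta_band: tuple[float, float] = (0.5, 4.0)
    theta_delta_ratio: float = 2.0
    power_window: float = 10.0

    def __post_init__(self) -> None:
        if not self.run_speed > self.immobile_speed > 0:
            raise ValueError("need run_speed > immobile_speed > 0")


def compute_speed(
    position: np.ndarray, timestamps: np.ndarray, smooth: float = 0.5
) -> np.ndarray:
    """Speed (cm/s) from tracked position: |centered finite difference|,
    then a `smooth`-second moving average."""
    position = np.asarray(position, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if position.shape != timestamps.shape:
        raise ValueError("position and timestamps must have the same shape")
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    speed = np.abs(np.gradient(position, timestamps))
    dt = float(np.median(np.diff(timestamps)))
    win = max(1, int(round(smooth / dt)))
    return uniform_filter1d(speed, size=win, mode="nearest")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs [i0, i1) where boolean mask is True."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    ends = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _run_time(t: np.ndarray, i0: int, i1: int) -> tuple[float, float]:
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    end = t[i1 - 1] + dt if i1 == len(t) else t[i1]
    return float(t[i0]), float(end)


def score_track_run(
    timestamps: np.ndarray, speed: np.ndarray, config: StateConfig | None = None
) -> list[StateInterval]:
    """Maximal intervals with speed above the run threshold, labeled RUN."""
    config = config or StateConfig()
    speed = np.asarray(speed, dtype=float)
    out = []
    for i0, i1 in _runs(speed > config.run_speed):
        s, e = _run_time(np.asarray(timestamps, float), i0, i1)
        out.append(StateInterval("RUN", s, e, context="track"))
    return out


def score_track(
    timestamps: np.ndarray, speed: np.ndarray, config: StateConfig | None = None
) -> list[StateInterval]:
    """Score a track period: RUN above threshold, QW elsewhere."""
    config = config or StateConfig()
    t = np.asarray(timestamps, dtype=float)
    speed = np.asarray(speed, dtype=float)
    run = speed > config.run_speed
    out = []
    for label, mask in (("RUN", run), ("QW", ~run)):
        for i0, i1 in _runs(mask):
            s, e = _run_time(t, i0, i1)
            out.append(StateInterval(label, s, e, context="track"))
    return sorted(out, key=lambda iv: iv.start)


def score_sleepbox_states(
    timestamps: np.ndarray,
    speed: np.ndarray,
    theta_power: np.ndarray,
    delta_power: np.ndarray,
    swr_times: np.ndarray | None = None,
    config: StateConfig | None = None,
) -> list[StateInterval]:
    """Score QW / SWS / REM in the sleep box.

    All series must share the clock of ``timestamps``.  ``swr_times`` is
    accepted for provenance (SWRs accompany SWS) but the discrimination is
    carried by immobility duration and the theta/delta ratio, since SWRs
    occur in quiet wakefulness as well.
    """
    config = config or StateConfig()
    t = np.asarray(timestamps, dtype=float)
    speed = np.asarray(speed, dtype=float)
    theta_power = np.asarray(theta_power, dtype=float)
    delta_power = np.asarray(delta_power, dtype=float)
    if not (len(t) == len(speed) == len(theta_power) == len(delta_power)):
        raise ValueError("speed and power series must share the timestamp clock")

    n = len(t)
    labels = np.full(n, "", dtype=object)
    immobile = speed < config.immobile_speed
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta_power > 0, theta_power / delta_power, np.inf)

    for i0, i1 in _runs(immobile):
        s, e = _run_time(t, i0, i1)
        if e - s < config.sws_min_immobility:
            labels[i0:i1] = "QW"
            continue
        # sleep onset after the prolonged-immobility criterion is met
        onset = s + config.sws_min_immobility
        pre = (t >= s) & (t < onset)
        labels[i0:i1][pre[i0:i1]] = "QW"
        sleep = np.zeros(n, dtype=bool)
        sleep[i0:i1] = t[i0:i1] >= onset
        sleep_idx = np.flatnonzero(sleep)
        if len(sleep_idx) == 0:
            continue
        labels[sleep_idx] = "SWS"
        # REM: sustained high theta/delta arising out of SWS
        high = ratio[sleep_idx] >= config.theta_delta_ratio
        for j0, j1 in _runs(high):
            if j0 == 0:
                continue  # must arise out of SWS, not at sleep onset
            rs, re = _run_time(t, sleep_idx[j0], sleep_idx[j1 - 1] + 1)
            if re - rs >= config.rem_min_duration:
                labels[sleep_idx[j0]: sleep_idx[j1 - 1] + 1] = "REM"

    intervals: list[StateInterval] = []
    for i0, i1 in _runs(labels != ""):
        j = i0
        while j < i1:
            k = j
            while k < i1 and labels[k] == labels[j]:
                k += 1
            s, e = _run_time(t, j, k)
            intervals.append(StateInterval(str(labels[j]), s, e, context="sleepbox"))
            j = k
    return intervals


def intervals_to_labels(
    intervals: list[StateInterval], timestamps: np.ndarray
) -> np.ndarray:
    """Per-sample label array ('' where no interval covers the sample)."""
    t = np.asarray(timestamps, dtype=float)
    out = np.full(len(t), "", dtype=object)
    for iv in intervals:
        out[(t >= iv.start) & (t < iv.end)] = iv.label
    return out


def label_at(intervals: list[StateInterval], time: float) -> str:
    """Label covering a time point, or ''."""
    for iv in intervals:
        if iv.start <= time < iv.end:
            return iv.label
    return ""
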