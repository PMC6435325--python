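"""Sharp-wave ripple (SWR) detection and singlet/train classification.

SWRs are detected on the z-scored ripple-band power envelope with a 3 Z
threshold; event boundaries are extended outward to where power returns to
the recording mean (zero crossing of the z-series), excursions whose
suprathreshold core lasts < 20 ms are discarded, and events whose extended
boundaries touch are merged.  Consecutive SWRs separated by end-to-start
gaps < 1 s form trains; events isolated by >= 1 s are singlets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hippostate.states import StateInterval

__all__ = ["SwrEvent", "SwrTrain", "detect_swr", "group_trains", "swr_rate",
           "swr_to_frame"]


@dataclass
class SwrEvent:
    """One detected sharp-wave ripple interval (mean-to-mean extent)."""

    start: float
    end: float
    peak_power: float  # peak z of ripple power
    peak_time: float = np.nan
    train_id: int | None = None
    position_in_train: int | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SwrTrain:
    """Two or more SWRs with consecutive end-to-start gaps < 1 s."""

    train_id: int
    events: list[SwrEvent] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.events)

    @property
    def last(self) -> SwrEvent:
        return self.events[-1]


def detect_swr(
    power_z: np.ndarray,
    rate: float,
    threshold: float = 3.0,
    min_duration: float = 0.020,
    start_time: float = 0.0,
) -> list[SwrEvent]:
    """Detect SWRs on a z-scored ripple power series.

    ``power_z`` must already be z-scored (mean ~ 0); an input whose mean
    deviates from 0 by more than 0.1 is rejected.  The 20 ms minimum
    duration applies to the suprathreshold core, before boundary extension.
    """
    power_z = np.asarray(power_z, dtype=float)
    if abs(power_z.mean()) > 0.1:
        raise ValueError("power series does not look z-scored (|mean| > 0.1)")
    above = power_z >= threshold
    if not above.any():
        return []
    padded = np.diff(np.concatenate([[0], above.astype(np.int8), [0]]))
    core_starts = np.flatnonzero(padded == 1)
    core_ends = np.flatnonzero(padded == -1)

    min_core = int(np.ceil(min_duration * rate))
    nonpos = power_z <= 0
    raw: list[tuple[int, int, int]] = []
    for i0, i1 in zip(core_starts, core_ends):
        if i1 - i0 < min_core:
            continue
        # extend outward to where power returns to the mean (z = 0)
        before = np.flatnonzero(nonpos[:i0])
        j0 = int(before[-1]) if len(before) else 0
        after = np.flatnonzero(nonpos[i1:])
        j1 = i1 + int(after[0]) if len(after) else len(power_z) - 1
        peak = i0 + int(np.argmax(power_z[i0:i1]))
        raw.append((j0, j1, peak))

    # merge events whose extended boundaries overlap or touch
    events: list[SwrEvent] = []
    for j0, j1, peak in raw:
        if events and j0 <= (events[-1].end - start_time) * rate:
            prev = events[-1]
            prev.end = start_time + j1 / rate
            if power_z[peak] > prev.peak_power:
                prev.peak_power = float(power_z[peak])
                prev.peak_time = start_time + peak / rate
        else:
            events.append(
                SwrEvent(
                    start=start_time + j0 / rate,
                    end=start_time + j1 / rate,
                    peak_power=float(power_z[peak]),
                    peak_time=start_time + peak / rate,
                )
            )
    return events


def group_trains(
    events: list[SwrEvent],
    max_gap: float = 1.0,
    gap_mode: str = "end_to_start",
) -> tuple[list[SwrEvent], list[SwrTrain]]:
    """Split SWRs into singlets and trains.

    The gap between consecutive events is next.start - previous.end
    (``gap_mode='end_to_start'``) or next.start - previous.start
    (``'onset_to_onset'``).  Chains whose internal gaps are all < max_gap
    form trains; isolated events are singlets.  Annotates train_id /
    position_in_train on the events in place.
    """
    events = sorted(events, key=lambda e: e.start)
    for a, b in zip(events[:-1], events[1:]):
        if b.start < a.end:
            raise ValueError("events overlap; cannot group into trains")
    if gap_mode not in ("end_to_start", "onset_to_onset"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")

    singlets: list[SwrEvent] = []
    trains: list[SwrTrain] = []
    chain: list[SwrEvent] = []

    def flush(chain: list[SwrEvent]) -> None:
        if len(chain) >= 2:
            tid = len(trains)
            for k, ev in enumerate(chain):
                ev.train_id = tid
                ev.position_in_train = k
            trains.append(SwrTrain(train_id=tid, events=list(chain)))
        elif chain:
            chain[0].train_id = None
            chain[0].position_in_train = None
            singlets.append(chain[0])

    for ev in events:
        if chain:
            ref = chain[-1].end if gap_mode == "end_to_start" else chain[-1].start
            if ev.start - ref < max_gap:
                chain.append(ev)
                continue
            flush(chain)
        chain = [ev]
    flush(chain)
    return singlets, trains


def swr_rate(
    events: list[SwrEvent], intervals: list[StateInterval]
) -> pd.DataFrame:
    """SWR rate per state label: event starts in the label's intervals
    divided by the label's total duration."""
    ivs = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs[:-1], ivs[1:]):
        if b.start < a.end:
            raise ValueError("intervals overlap")
    starts = np.array([ev.start for ev in events])
    rows = []
    for label in sorted({iv.label for iv in intervals}):
        label_ivs = [iv for iv in intervals if iv.label == label]
        dur = sum(iv.duration for iv in label_ivs)
        if dur <= 0:
            continue
        n = sum(
            int(np.sum((starts >= iv.start) & (starts < iv.end)))
            for iv in label_ivs
        )
        rows.append({"state": label, "n_events": n, "duration_s": dur,
                     "rate_hz": n / dur})
    return pd.DataFrame(rows, columns=["state", "n_events", "duration_s",
                                       "rate_hz"])


def swr_to_frame(events: list[SwrEvent]) -> pd.DataFrame:
    """SWR events as a tidy DataFrame (ripples.csv layout)."""
    return pd.DataFrame(
        [
            {"start_s": ev.start, "end_s": ev.end, "peak_z": ev.peak_power,
             "train_id": ev.train_id if ev.train_id is not None else -1,
             "position_in_train": (ev.position_in_train
                                   if ev.position_in_train is not None else -1)}
            for ev in events
        ],
        columns=["start_s", "end_s", "peak_z", "train_id", "position_in_train"],
    )
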