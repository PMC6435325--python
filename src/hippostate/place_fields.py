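"""Directional spatial tuning, spatial information, and place-cell testing.

Tuning curves use 3 cm position bins and only samples where the animal
runs (> 3 cm/s) in the curve's direction.  Spatial information is the
standard bits-per-event statistic

    SI = Σ_i p_i (λ_i / λ̄) log2(λ_i / λ̄),

with p_i the occupancy share of bin i, λ_i its event rate and
λ̄ = Σ p_i λ_i the occupancy-weighted mean rate.  Significance is a Monte
Carlo test: each shuffle reassigns the cell's run-period events to times
drawn uniformly from the run samples (preserving occupancy), rebuilds the
curve and recomputes SI; p = (1 + #{SI_shuffle >= SI_obs}) / (1 + n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TuningCurve", "tuning_curve", "spatial_information",
           "place_cell_test", "run_mask"]

DIRECTIONS = ("rightward", "leftward")


@dataclass
class TuningCurve:
    """Directional spatial rate map for one cell."""

    direction: str
    bin_edges: np.ndarray  # cm
    occupancy: np.ndarray  # s per bin
    event_counts: np.ndarray
    rate: np.ndarray  # events/s; NaN where occupancy is 0
    spatial_info: float = np.nan  # bits/event
    p_value: float = np.nan

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def run_mask(
    speed: np.ndarray,
    velocity: np.ndarray,
    direction: str,
    run_speed: float = 3.0,
) -> np.ndarray:
    """Samples where the animal runs (> run_speed cm/s) in ``direction``."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    sign = 1.0 if direction == "rightward" else -1.0
    return (np.asarray(speed) > run_speed) & (sign * np.asarray(velocity) > 0)


def _accumulate(
    event_times: np.ndarray,
    timestamps: np.ndarray,
    position: np.ndarray,
    mask: np.ndarray,
    edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(occupancy s, event counts, run-sample indices of the events)."""
    dt = float(np.median(np.diff(timestamps)))
    nbins = len(edges) - 1
    bin_of = np.clip(np.digitize(position, edges) - 1, 0, nbins - 1)
    occupancy = np.bincount(bin_of[mask], minlength=nbins) * dt

    ev = np.asarray(event_times, dtype=float)
    idx = np.clip(np.searchsorted(timestamps, ev), 0, len(timestamps) - 1)
    keep = mask[idx]
    counts = np.bincount(bin_of[idx[keep]], minlength=nbins).astype(float)
    return occupancy.astype(float), counts, idx[keep]


def tuning_curve(
    event_times: np.ndarray,
    timestamps: np.ndarray,
    position: np.ndarray,
    speed: np.ndarray,
    direction: str,
    track_length: float = 200.0,
    bin: float = 3.0,
    run_speed: float = 3.0,
    velocity: np.ndarray | None = None,
) -> TuningCurve:
    """Directional spatial tuning curve from event onsets during running.

    Events whose onset falls on a non-run sample (immobility or the wrong
    direction) are excluded.  Bins with zero occupancy carry NaN rate.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    position = np.asarray(position, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if velocity is None:
        velocity = np.gradient(position, timestamps)
    mask = run_mask(speed, velocity, direction, run_speed)
    if not mask.any():
        raise ValueError(f"no run samples in direction {direction!r}")
    edges = np.arange(0.0, track_length + bin / 2, bin)
    occupancy, counts, _ = _accumulate(event_times, timestamps, position,
                                       mask, edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, np.nan)
    return TuningCurve(direction=direction, bin_edges=edges,
                       occupancy=occupancy, event_counts=counts, rate=rate)


def _si_from_arrays(occupancy: np.ndarray, counts: np.ndarray) -> float:
    total_occ = occupancy.sum()
    p = occupancy / total_occ
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(occupancy > 0, counts / occupancy, 0.0)
    lam_bar = float((p * lam).sum())
    if lam_bar <= 0:
        raise ValueError("zero mean rate; spatial information undefined")
    rel = lam / lam_bar
    terms = np.where(lam > 0, p * rel * np.log2(np.where(rel > 0, rel, 1.0)),
                     0.0)
    return float(terms.sum())


def spatial_information(curve: TuningCurve) -> float:
    """Spatial information (bits/event) of a tuning curve."""
    if curve.occupancy.sum() <= 0:
        raise ValueError("zero total occupancy")
    si = _si_from_arrays(curve.occupancy, curve.event_counts)
    curve.spatial_info = si
    return si


def place_cell_test(
    event_times: np.ndarray,
    timestamps: np.ndarray,
    position: np.ndarray,
    speed: np.ndarray,
    direction: str,
    track_length: float = 200.0,
    bin: float = 3.0,
    run_speed: float = 3.0,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    shuffle_domain: str = "run",
    velocity: np.ndarray | None = None,
) -> dict | None:
    """Monte Carlo place-field significance for one cell and direction.

    Shuffles redraw the cell's run-period event times uniformly from the
    run samples (``shuffle_domain='run'``, preserving occupancy) or from
    the whole session (``'session'``), then recompute spatial information.
    Returns {'si', 'p_value', 'significant', 'n_events', 'curve'} or None
    when the cell has no run events in that direction.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    timestamps = np.asarray(timestamps, dtype=float)
    position = np.asarray(position, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if velocity is None:
        velocity = np.gradient(position, timestamps)
    mask = run_mask(speed, velocity, direction, run_speed)
    if not mask.any():
        raise ValueError(f"no run samples in direction {direction!r}")
    edges = np.arange(0.0, track_length + bin / 2, bin)
    nbins = len(edges) - 1
    occupancy, counts, _ = _accumulate(event_times, timestamps, position,
                                       mask, edges)
    n_events = int(counts.sum())
    if n_events == 0:
        return None
    observed = _si_from_arrays(occupancy, counts)

    if shuffle_domain == "run":
        domain = np.flatnonzero(mask)
    elif shuffle_domain == "session":
        domain = np.arange(len(timestamps))
    else:
        raise ValueError(f"unknown shuffle_domain {shuffle_domain!r}")
    bin_of = np.clip(np.digitize(position, edges) - 1, 0, nbins - 1)

    draws = domain[rng.integers(0, len(domain), size=(n_shuffles, n_events))]
    shuf_bins = bin_of[draws]
    shuf_counts = np.zeros((n_shuffles, nbins))
    np.add.at(shuf_counts, (np.repeat(np.arange(n_shuffles), n_events),
                            shuf_bins.ravel()), 1.0)
    if shuffle_domain == "session":
        # events drawn outside run samples drop out of the curve
        in_run = mask[draws]
        shuf_counts = np.zeros((n_shuffles, nbins))
        rows = np.repeat(np.arange(n_shuffles), n_events)[in_run.ravel()]
        np.add.at(shuf_counts, (rows, shuf_bins.ravel()[in_run.ravel()]), 1.0)

    p_occ = occupancy / occupancy.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(occupancy > 0, shuf_counts / occupancy, 0.0)
    lam_bar = (lam * p_occ).sum(axis=1)
    ok = lam_bar > 0
    si_shuffled = np.zeros(n_shuffles)
    rel = np.zeros_like(lam)
    rel[ok] = lam[ok] / lam_bar[ok, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        logrel = np.where(rel > 0, np.log2(np.where(rel > 0, rel, 1.0)), 0.0)
    si_shuffled[ok] = (p_occ * rel[ok] * logrel[ok]).sum(axis=1)

    p_value = (1 + int(np.sum(si_shuffled >= observed))) / (1 + n_shuffles)
    curve = TuningCurve(direction=direction, bin_edges=edges,
                        occupancy=occupancy, event_counts=counts,
                        rate=np.where(occupancy > 0, counts / occupancy,
                                      np.nan),
                        spatial_info=observed, p_value=p_value)
    return {"si": observed, "p_value": p_value,
            "significant": p_value < alpha, "n_events": n_events,
            "curve": curve}
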