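"""Calibration experiments measuring detector performance on ground truth.

Each function builds a synthetic fixture with known ground truth, runs the
corresponding detector through its public interface, and returns summary
metrics (recall, precision, false-positive rates, timing error, agreement).
They are used by the validation suite and by ``scripts/acceptance.py``;
problem sizes are chosen so the full battery runs in a few minutes on one
CPU.
"""

from __future__ import annotations

import numpy as np

from hippostate import coupling, place_fields
from hippostate.calcium_events import EventDetectionConfig, detect_events
from hippostate.lfp import (DELTA_BAND, RIPPLE_BAND, THETA_BAND,
                            bandpass_filter, power_envelope,
                            sliding_band_power)
from hippostate.states import (compute_speed, intervals_to_labels,
                               score_sleepbox_states, score_track)
from hippostate.swr import detect_swr
from hippostate.synthetic_data import (SimConfig, make_session,
                                       simulate_behavior, simulate_lfp,
                                       simulate_place_cell_events,
                                       simulate_spikes_and_fluorescence)

__all__ = [
    "swr_detection_benchmark",
    "calcium_event_benchmark",
    "sce_calibration_benchmark",
    "sce_ripple_coupling_benchmark",
    "place_cell_benchmark",
    "state_scoring_benchmark",
]


def _subseed(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))


def swr_detection_benchmark(seed: int = 0, match_window: float = 0.1) -> dict:
    """Recall/precision/onset accuracy of the SWR detector.

    ~120 isolated ripples (150 Hz, 60 ms, generator-default SNR) are
    injected into QW/SWS background LFP; detections within
    ``match_window`` s of a true start count as hits.  Onset error is the
    median |detected start − true start| of the hits, in ms.
    """
    cfg = SimConfig(n_cells=5, seed=seed, ripple_rate=0.2, train_prob=0.0,
                    state_schedule=[("QW", 200.0), ("SWS", 400.0)])
    _, _, states = simulate_behavior(cfg)
    lfp, true_ripples = simulate_lfp(states, cfg)
    power = power_envelope(bandpass_filter(lfp, RIPPLE_BAND), lfp.rate)
    detected = detect_swr(power, lfp.rate)

    true_starts = np.array([r["start"] for r in true_ripples])
    det_starts = np.array([d.start for d in detected])
    errors = []
    hits = 0
    for ts in true_starts:
        if len(det_starts):
            d = np.abs(det_starts - ts)
            if d.min() < match_window:
                hits += 1
                errors.append(d.min())
    false = sum(1 for ds in det_starts
                if np.abs(true_starts - ds).min() >= match_window)
    return {
        "recall": hits / len(true_starts),
        "precision": 1.0 - false / len(det_starts) if len(det_starts) else 0.0,
        "onset_error_ms": float(np.median(errors) * 1000) if errors else np.nan,
        "n_true": len(true_starts),
        "n_detected": len(detected),
    }


def calcium_event_benchmark(seed: int = 0, n_cells: int = 100,
                            match_window: float = 0.3) -> dict:
    """Recall and false-positive rate of the calcium transient detector.

    ``n_cells`` cells emit 0.05 Hz transients (peak 5 Z) on noise of SD 1
    for 600 s; each detection is greedily matched to the nearest unmatched
    true event within ``match_window`` s of its onset.
    """
    cfg = SimConfig(n_cells=n_cells, seed=seed,
                    state_schedule=[("QW", 300.0), ("SWS", 300.0)],
                    event_rate_by_state={"QW": 0.05, "SWS": 0.05})
    _, _, states = simulate_behavior(cfg)
    spikes, fluor = simulate_spikes_and_fluorescence(states, cfg)
    det_cfg = EventDetectionConfig()
    n_true = n_det = n_match = 0
    for c in range(n_cells):
        events = detect_events(fluor.traces[c], cfg.frame_rate, det_cfg,
                               cell_id=c)
        onsets = np.array([ev.onset_time for ev in events])
        used = np.zeros(len(onsets), bool)
        for s in spikes[c]:
            cand = np.flatnonzero((np.abs(onsets - s) < match_window) & ~used)
            if len(cand):
                used[cand[np.argmin(np.abs(onsets[cand] - s))]] = True
                n_match += 1
        n_true += len(spikes[c])
        n_det += len(onsets)
    return {
        "recall": n_match / n_true,
        "false_positive_rate": 1.0 - n_match / n_det if n_det else 0.0,
        "n_true": n_true,
        "n_detected": n_det,
    }


def sce_calibration_benchmark(seed: int = 0, n_seeds: int = 100,
                              n_cells: int = 20, duration: float = 600.0,
                              rate: float = 0.02) -> dict:
    """False-SCE rate on independent Poisson cells and planted-synchrony
    sensitivity, across ``n_seeds`` simulated sessions each."""
    false_sessions = 0
    for k in range(n_seeds):
        rng = _subseed(seed, k)
        ev = {c: np.sort(rng.uniform(0, duration,
                                     rng.poisson(rate * duration)))
              for c in range(n_cells)}
        sces = coupling.detect_sce(ev, duration, seed=_subseed(seed, 10000 + k))
        false_sessions += bool(sces)

    detected_planted = 0
    for k in range(n_seeds):
        rng = _subseed(seed, 20000 + k)
        ev = {c: np.sort(rng.uniform(0, duration,
                                     rng.poisson(rate * duration)))
              for c in range(n_cells)}
        t0 = rng.uniform(50, duration - 50)
        for c in range(8):  # 8 cells fire within 100 ms
            ev[c] = np.sort(np.append(ev[c], t0 + rng.uniform(0, 0.1)))
        sces = coupling.detect_sce(ev, duration, seed=_subseed(seed, 30000 + k))
        detected_planted += any(abs(s.onset - t0) < 0.3 for s in sces)
    return {
        "false_sce_session_rate": false_sessions / n_seeds,
        "planted_detection_rate": detected_planted / n_seeds,
        "n_seeds": n_seeds,
    }


def sce_ripple_coupling_benchmark(seed: int = 0, n_null_seeds: int = 100) -> dict:
    """Sensitivity and specificity of the median + 2·IQR ripple-power test.

    Planted case: SCE onsets placed at true ripple peaks of a synthetic
    sleep LFP.  Null case: onsets drawn uniformly, repeated over
    ``n_null_seeds`` draws; the null fraction is the mean across draws.
    """
    cfg = SimConfig(n_cells=5, seed=seed, ripple_rate=0.2, train_prob=0.0,
                    state_schedule=[("QW", 200.0), ("SWS", 400.0)])
    _, _, states = simulate_behavior(cfg)
    lfp, true_ripples = simulate_lfp(states, cfg)
    power = power_envelope(bandpass_filter(lfp, RIPPLE_BAND), lfp.rate)

    peaks = [0.5 * (r["start"] + r["end"]) for r in true_ripples]
    planted = [coupling.SceEvent(onset=t, cell_ids=list(range(5)),
                                 z_vs_shuffle=4.0) for t in peaks]
    out = coupling.sce_ripple_significance(planted, power, lfp.rate,
                                           seed=_subseed(seed, 1))
    planted_fraction = out["fraction_significant"]

    null_fractions = []
    duration = lfp.duration
    for k in range(n_null_seeds):
        rng = _subseed(seed, 100 + k)
        sces = [coupling.SceEvent(onset=float(t), cell_ids=list(range(5)),
                                  z_vs_shuffle=4.0)
                for t in rng.uniform(0, duration, 10)]
        res = coupling.sce_ripple_significance(sces, power, lfp.rate,
                                               seed=_subseed(seed, 5000 + k))
        null_fractions.append(res["fraction_significant"])
    return {
        "planted_significant_fraction": planted_fraction,
        "null_significant_fraction": float(np.mean(null_fractions)),
        "n_planted": len(planted),
    }


def place_cell_benchmark(seed: int = 0, n_null: int = 200,
                         n_place: int = 100, n_events: int = 30,
                         n_shuffles: int = 1000) -> dict:
    """Type-I error on null cells and power on synthetic place cells.

    Null cells redistribute their events uniformly over run samples; place
    cells carry a 9 cm Gaussian field with the high in/out-of-field
    contrast typical of CA1.  Both use the Monte Carlo shuffle test at
    α = 0.05.
    """
    cfg = SimConfig(seed=seed, state_schedule=[("RUN", 600.0)])
    t, pos, _ = simulate_behavior(cfg)
    speed = compute_speed(pos, t)
    velocity = np.gradient(pos, t)
    run_idx = np.flatnonzero((speed > 3.0) & (velocity > 0))

    false_pos = 0
    for k in range(n_null):
        rng = _subseed(seed, k)
        ev = np.sort(t[rng.choice(run_idx, size=n_events)])
        res = place_fields.place_cell_test(
            ev, t, pos, speed, "rightward", n_shuffles=n_shuffles,
            seed=_subseed(seed, 40000 + k))
        false_pos += res["significant"]

    detected = 0
    for k in range(n_place):
        rng = _subseed(seed, 50000 + k)
        ev = simulate_place_cell_events(t, pos, run_idx, n_events, rng)
        res = place_fields.place_cell_test(
            ev, t, pos, speed, "rightward", n_shuffles=n_shuffles,
            seed=_subseed(seed, 60000 + k))
        detected += res["significant"]
    return {
        "type_i_error": false_pos / n_null,
        "power": detected / n_place,
        "n_null": n_null,
        "n_place": n_place,
    }


def _random_schedule(rng: np.random.Generator) -> list[tuple[str, float]]:
    return [
        ("RUN", float(rng.uniform(120, 240))),
        ("QW", float(rng.uniform(120, 300))),
        ("SWS", float(rng.uniform(240, 420))),
        ("REM", float(rng.uniform(20, 60))),
        ("SWS", float(rng.uniform(180, 300))),
        ("QW", float(rng.uniform(40, 80))),
    ]


def state_scoring_benchmark(seed: int = 0, n_sessions: int = 20) -> dict:
    """Per-sample agreement between scored and ground-truth states.

    Sessions draw random epoch durations (RUN, then a sleep-box sequence
    with two SWS bouts and one REM bout).  Agreement is computed per
    session over all ground-truth-labeled samples and averaged.
    """
    agreements = []
    scored_all = []
    for k in range(n_sessions):
        rng = _subseed(seed, k)
        cfg = SimConfig(n_cells=3, seed=int(rng.integers(2**31)),
                        state_schedule=_random_schedule(rng))
        ses = make_session(cfg)
        t = ses.timestamps
        speed = compute_speed(ses.position, t)
        theta = sliding_band_power(ses.lfp, THETA_BAND, t)
        delta = sliding_band_power(ses.lfp, DELTA_BAND, t)
        track_end = cfg.state_schedule[0][1]
        track = t < track_end
        scored = score_track(t[track], speed[track]) + score_sleepbox_states(
            t[~track], speed[~track], theta[~track], delta[~track])
        pred = intervals_to_labels(scored, t)
        truth = intervals_to_labels(ses.true_states, t)
        agreements.append(float(np.mean(pred == truth)))
        scored_all.extend(scored)
    return {
        "mean_agreement": float(np.mean(agreements)),
        "min_agreement": float(np.min(agreements)),
        "n_sessions": n_sessions,
        "scored_intervals": scored_all,
    }
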