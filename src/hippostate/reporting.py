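"""Statistical contrast tables and the end-to-end pipeline driver.

Contrasts follow the experimental design this pipeline models: per-animal
state means compared with one-way repeated-measures ANOVA followed by
pairwise paired t-tests (Holm-corrected), and paired t-tests for
two-condition (e.g. vehicle vs drug) contrasts.  The statistical engines
are standard library routines; this module owns the table structure and
design validation.  ``run_pipeline`` drives synthesis → imaging → event
detection → LFP/SWR → state scoring → peri-SWR coupling → place fields and
writes all artifacts with full provenance.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from hippostate import calcium_events, coupling, place_fields, swr
from hippostate.lfp import (DELTA_BAND, RIPPLE_BAND, THETA_BAND,
                            bandpass_filter, power_envelope,
                            sliding_band_power)
from hippostate.states import (StateConfig, compute_speed, intervals_to_labels,
                               score_sleepbox_states, score_track)

__all__ = ["ContrastTable", "state_contrasts", "paired_contrast",
           "run_pipeline"]

log = logging.getLogger("hippostate")


@dataclass
class ContrastTable:
    """Per-animal per-state means with ANOVA and post-hoc results."""

    data: pd.DataFrame  # one row per animal x state
    anova: pd.DataFrame  # metric, F, df1, df2, p
    posthoc: pd.DataFrame  # metric, state_a, state_b, t, p_raw, p_holm


def _validate_design(data: pd.DataFrame, metric: str) -> None:
    pivot = data.pivot_table(index="animal", columns="state", values=metric,
                             aggfunc="count")
    missing = [(a, s) for a in pivot.index for s in pivot.columns
               if not pivot.loc[a, s] == 1]
    if missing:
        raise ValueError(
            f"unbalanced design for {metric!r}; missing/duplicated cells: "
            f"{missing}")


def state_contrasts(
    per_animal_metrics: pd.DataFrame,
    metrics: list[str] | None = None,
    exclude: dict[str, list[str]] | None = None,
) -> ContrastTable:
    """Within-subject state contrasts of per-animal metrics.

    ``per_animal_metrics`` has columns 'animal', 'state' and one column per
    metric.  ``exclude`` maps a metric to states dropped from its contrast
    (e.g. REM is excluded from theta-power contrasts).  Requires >= 3
    animals, each observed in every (retained) state.
    """
    df = per_animal_metrics.copy()
    if df["animal"].nunique() < 3:
        raise ValueError("need at least 3 animals")
    if metrics is None:
        metrics = [c for c in df.columns if c not in ("animal", "state")]
    exclude = exclude or {}

    anova_rows = []
    posthoc_rows = []
    for metric in metrics:
        sub = df[~df["state"].isin(exclude.get(metric, []))]
        sub = sub.dropna(subset=[metric])
        _validate_design(sub, metric)
        res = AnovaRM(sub, depvar=metric, subject="animal",
                      within=["state"]).fit()
        row = res.anova_table.iloc[0]
        anova_rows.append({"metric": metric, "F": row["F Value"],
                           "df1": row["Num DF"], "df2": row["Den DF"],
                           "p": row["Pr > F"]})
        states_present = sorted(sub["state"].unique())
        pairs = list(itertools.combinations(states_present, 2))
        raw = []
        for a, b in pairs:
            va = sub[sub["state"] == a].sort_values("animal")[metric].to_numpy()
            vb = sub[sub["state"] == b].sort_values("animal")[metric].to_numpy()
            t, p = stats.ttest_rel(va, vb)
            raw.append((a, b, float(t), float(p)))
        if raw:
            p_holm = multipletests([r[3] for r in raw], method="holm")[1]
            for (a, b, t, p), ph in zip(raw, p_holm):
                posthoc_rows.append({"metric": metric, "state_a": a,
                                     "state_b": b, "t": t, "p_raw": p,
                                     "p_holm": float(ph)})
    return ContrastTable(
        data=df,
        anova=pd.DataFrame(anova_rows,
                           columns=["metric", "F", "df1", "df2", "p"]),
        posthoc=pd.DataFrame(posthoc_rows,
                             columns=["metric", "state_a", "state_b", "t",
                                      "p_raw", "p_holm"]),
    )


def paired_contrast(
    condition_a: np.ndarray, condition_b: np.ndarray, sided: str = "two"
) -> dict:
    """Paired t-test between two conditions.

    ``sided='one'`` tests the hypothesis mean(a) > mean(b).
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have the same length")
    if len(a) < 3:
        raise ValueError("need n >= 3 pairs")
    alternative = {"two": "two-sided", "one": "greater"}[sided]
    t, p = stats.ttest_rel(a, b, alternative=alternative)
    return {"t": float(t), "p": float(p), "n": len(a), "sided": sided}


DEFAULT_ANALYSIS = {
    "event_threshold_z": 3.0,
    "swr_threshold_z": 3.0,
    "swr_min_duration_s": 0.020,
    "sce_window_s": 0.25,
    "sce_min_cells": 5,
    "n_shuffles": 1000,
    "place_bin_cm": 3.0,
}


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    return config


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Run the full analysis and write artifacts to ``out_dir``.

    The config maps 'session' to either SimConfig fields (synthetic
    session) or {'path': directory} (existing session), and optionally
    'analysis' to detection parameters.  ``seed`` overrides the session
    seed and seeds every shuffle procedure.  Outputs are byte-reproducible
    from config + seed.
    """
    from hippostate.session_io import config_from_dict, load_session
    from hippostate.synthetic_data import make_session

    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and h.stream is sys.stderr for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    log.setLevel(logging.INFO)

    try:
        session_cfg = dict(cfg.get("session", {}))
        analysis = {**DEFAULT_ANALYSIS, **cfg.get("analysis", {})}
        n_shuffles = int(analysis["n_shuffles"])

        if "path" in session_cfg:
            path = Path(session_cfg["path"])
            if not path.exists():
                raise FileNotFoundError(f"session directory not found: {path}")
            log.info("loading session from %s", path)
            session = load_session(path)
        else:
            if seed is not None:
                session_cfg["seed"] = int(seed)
            sim = config_from_dict(session_cfg)
            log.info("synthesizing session (seed=%d, %.0f s, %d cells)",
                     sim.seed, sim.duration, sim.n_cells)
            session = make_session(sim)
        master_seed = seed if seed is not None else session.config.seed

        # --- behavior and state scoring -------------------------------
        log.info("stage: states")
        t = session.timestamps
        speed = compute_speed(session.position, t)
        theta = sliding_band_power(session.lfp, THETA_BAND, t)
        delta = sliding_band_power(session.lfp, DELTA_BAND, t)
        contexts: list[tuple[str, float, float]] = []
        for iv in session.true_states:
            if contexts and contexts[-1][0] == iv.context:
                contexts[-1] = (iv.context, contexts[-1][1], iv.end)
            else:
                contexts.append((iv.context, iv.start, iv.end))
        scored = []
        for context, s, e in contexts:
            sel = (t >= s) & (t < e)
            if context == "track":
                scored.extend(score_track(t[sel], speed[sel]))
            else:
                scored.extend(score_sleepbox_states(
                    t[sel], speed[sel], theta[sel], delta[sel]))
        scored.sort(key=lambda iv: iv.start)
        pd.DataFrame([{"label": iv.label, "start_s": iv.start,
                       "end_s": iv.end, "context": iv.context}
                      for iv in scored]
                     ).to_csv(out / "states_scored.csv", index=False)

        # --- calcium events -------------------------------------------
        log.info("stage: calcium events")
        det_cfg = calcium_events.EventDetectionConfig(
            threshold_z=float(analysis["event_threshold_z"]))
        events = calcium_events.detect_events_matrix(session.fluorescence,
                                                     det_cfg)
        calcium_events.events_to_frame(events).to_csv(out / "events.csv",
                                                      index=False)
        rates = calcium_events.event_rates(events, scored)
        rates.to_csv(out / "event_rates.csv", index=False)

        # --- LFP / SWR ------------------------------------------------
        log.info("stage: SWR detection")
        filtered = bandpass_filter(session.lfp, RIPPLE_BAND)
        power = power_envelope(filtered, session.lfp.rate)
        swrs = swr.detect_swr(power, session.lfp.rate,
                              threshold=float(analysis["swr_threshold_z"]),
                              min_duration=float(
                                  analysis["swr_min_duration_s"]),
                              start_time=session.lfp.start_time)
        singlets, trains = swr.group_trains(swrs)
        swr.swr_to_frame(swrs).to_csv(out / "ripples_detected.csv",
                                      index=False)
        swr.swr_rate(swrs, scored).to_csv(out / "swr_rates.csv", index=False)

        # --- peri-SWR coupling ----------------------------------------
        log.info("stage: peri-SWR statistics")
        onsets = np.sort(np.array([ev.onset_time for ev in events]))
        n_cells = session.fluorescence.n_cells
        window_stats: dict[str, dict] = {}
        peth_frames = []
        if swrs:
            for mode in ("all", "singlets", "trains"):
                ws = coupling.swr_window_stats(onsets, swrs, trains,
                                               mode=mode, n_sources=n_cells)
                if ws is not None:
                    window_stats[mode] = {
                        "pre_hz": ws.pre, "at_hz": ws.at, "post_hz": ws.post,
                        "windows": ws.windows, "n_triggers": ws.n_triggers}
            p = coupling.peth(onsets, np.array([ev.start for ev in swrs]),
                              n_sources=n_cells)
            peth_frames.append(pd.DataFrame(
                {"lag_s": p.bin_centers, "count": p.counts,
                 "rate_hz": p.rate, "rate_smoothed_hz": p.rate_smoothed}))
            if session.neuropil is not None:
                lags, mean_trace, np_ws = coupling.neuropil_peth(
                    session.neuropil, session.fluorescence.frame_rate,
                    np.array([ev.start for ev in swrs]))
                window_stats["neuropil"] = {
                    "pre": np_ws.pre, "at": np_ws.at, "post": np_ws.post,
                    "n_triggers": np_ws.n_triggers}
        if peth_frames:
            peth_frames[0].to_csv(out / "peths.csv", index=False)
        (out / "window_stats.json").write_text(
            json.dumps(window_stats, indent=2, default=float))

        # --- SCEs -----------------------------------------------------
        log.info("stage: SCE detection")
        by_cell = {cid: np.array([ev.onset_time for ev in events
                                  if ev.cell_id == cid])
                   for cid in session.fluorescence.cell_ids}
        by_cell = {c: v for c, v in by_cell.items() if len(v)}
        duration = session.timestamps[-1] + 1.0 / session.fluorescence.frame_rate
        sces = []
        if len(by_cell) >= int(analysis["sce_min_cells"]):
            sces = coupling.detect_sce(
                by_cell, duration,
                frame_rate=session.fluorescence.frame_rate,
                window=float(analysis["sce_window_s"]),
                min_cells=int(analysis["sce_min_cells"]),
                n_shuffles=n_shuffles,
                seed=np.random.default_rng(
                    np.random.SeedSequence(master_seed, spawn_key=(101,))))
            coupling.sce_ripple_significance(
                sces, power, session.lfp.rate, n_shuffles=n_shuffles,
                seed=np.random.default_rng(
                    np.random.SeedSequence(master_seed, spawn_key=(102,))),
                start_time=session.lfp.start_time)
        co = coupling.sce_swr_cooccurrence(sces, swrs)
        pd.DataFrame(
            [{"onset_s": s.onset, "n_cells": s.n_cells,
              "z": s.z_vs_shuffle, "ripple_z": s.ripple_power_at_onset,
              "significant": s.ripple_significant} for s in sces],
            columns=["onset_s", "n_cells", "z", "ripple_z", "significant"],
        ).to_csv(out / "sces.csv", index=False)
        (out / "sce_summary.json").write_text(json.dumps(co, indent=2,
                                                         default=float))

        # --- place fields ---------------------------------------------
        log.info("stage: place fields")
        place_rows = []
        has_run = any(iv.label == "RUN" for iv in scored)
        if has_run:
            for cid, ev_times in by_cell.items():
                for k, direction in enumerate(place_fields.DIRECTIONS):
                    try:
                        res = place_fields.place_cell_test(
                            ev_times, t, session.position, speed, direction,
                            track_length=session.config.track_length,
                            bin=float(analysis["place_bin_cm"]),
                            n_shuffles=n_shuffles,
                            seed=np.random.default_rng(np.random.SeedSequence(
                                master_seed, spawn_key=(200 + cid, k))))
                    except ValueError:
                        continue
                    if res is None:
                        continue
                    place_rows.append(
                        {"cell_id": cid, "direction": direction,
                         "si_bits": res["si"], "p_value": res["p_value"],
                         "significant": res["significant"],
                         "n_events": res["n_events"]})
        pd.DataFrame(place_rows,
                     columns=["cell_id", "direction", "si_bits", "p_value",
                              "significant", "n_events"]
                     ).to_csv(out / "place_cells.csv", index=False)

        # --- provenance -----------------------------------------------
        import hippostate

        provenance = {
            "package_version": hippostate.__version__,
            "seed": master_seed,
            "session": session_cfg,
            "analysis": analysis,
            "n_events": len(events),
            "n_swrs": len(swrs),
            "n_trains": len(trains),
            "n_sces": len(sces),
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str))
        log.info("pipeline complete: %s", out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
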