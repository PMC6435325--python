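"""Session directory serialization.

A session directory holds: traces.csv (time × cells), lfp.bin
(little-endian int16 µV) + lfp_meta.json, position.csv, states.csv
(label,start,end,context), ripples.csv, masks.tiff / movie.tiff
(multi-page), and config.yaml.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from hippostate.imaging import FluorescenceMatrix, IcMaskSet, PixelStack
from hippostate.lfp import LfpChannel
from hippostate.states import StateInterval
from hippostate.synthetic_data import SimConfig, SyntheticSession

__all__ = ["save_session", "load_session"]

LFP_SCALE = 1.0  # int16 counts per µV


def save_session(session: SyntheticSession, path: str | Path) -> Path:
    """Write a session (and its ground truth) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    fluor = session.fluorescence
    df = pd.DataFrame(fluor.traces.T,
                      columns=[f"cell_{c}" for c in fluor.cell_ids])
    df.insert(0, "time_s", fluor.times)
    df.to_csv(path / "traces.csv", index=False)

    pd.DataFrame({"time_s": session.timestamps,
                  "position_cm": session.position}
                 ).to_csv(path / "position.csv", index=False)

    pd.DataFrame(
        [{"label": iv.label, "start_s": iv.start, "end_s": iv.end,
          "context": iv.context} for iv in session.true_states]
    ).to_csv(path / "states.csv", index=False)

    pd.DataFrame(
        session.true_ripples or [],
        columns=["start", "end", "train_id"],
    ).rename(columns={"start": "start_s", "end": "end_s"}
             ).to_csv(path / "ripples.csv", index=False)

    lfp = session.lfp
    counts = np.clip(np.round(lfp.samples * LFP_SCALE), -32768, 32767)
    counts.astype("<i2").tofile(path / "lfp.bin")
    (path / "lfp_meta.json").write_text(json.dumps(
        {"rate_hz": lfp.rate, "start_time_s": lfp.start_time,
         "scale_counts_per_uv": LFP_SCALE, "dtype": "<i2",
         "layer_tag": lfp.layer_tag}, indent=2))

    if session.neuropil is not None:
        pd.DataFrame({"time_s": fluor.times,
                      "neuropil": session.neuropil}
                     ).to_csv(path / "neuropil.csv", index=False)
    if session.masks is not None:
        tifffile.imwrite(path / "masks.tiff",
                         session.masks.masks.astype(np.float32),
                         photometric="minisblack")
    if session.movie is not None:
        tifffile.imwrite(path / "movie.tiff",
                         session.movie.frames.astype(np.float32),
                         photometric="minisblack")

    cfg = session.config
    cfg_dict = {
        "n_cells": cfg.n_cells,
        "frame_rate": cfg.frame_rate,
        "lfp_rate": cfg.lfp_rate,
        "track_length": cfg.track_length,
        "state_schedule": [[label, float(d)] for label, d in cfg.state_schedule],
        "event_rate_by_state": dict(cfg.event_rate_by_state),
        "run_speed": cfg.run_speed,
        "rest_speed_jitter": cfg.rest_speed_jitter,
        "event_amplitude_z": cfg.event_amplitude_z,
        "gcamp_rise_tau": cfg.gcamp_rise_tau,
        "gcamp_decay_tau": cfg.gcamp_decay_tau,
        "trace_noise_sd": cfg.trace_noise_sd,
        "ripple_rate": cfg.ripple_rate,
        "ripple_center_freq": cfg.ripple_center_freq,
        "ripple_duration": cfg.ripple_duration,
        "ripple_snr": cfg.ripple_snr,
        "train_prob": cfg.train_prob,
        "theta_freq": cfg.theta_freq,
        "theta_amp_by_state": dict(cfg.theta_amp_by_state),
        "lfp_noise_sd": cfg.lfp_noise_sd,
        "image_size": list(cfg.image_size),
        "seed": cfg.seed,
    }
    (path / "config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    return path


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "state_schedule" in d:
        d["state_schedule"] = [(str(label), float(dur))
                               for label, dur in d["state_schedule"]]
    if "image_size" in d:
        d["image_size"] = tuple(int(v) for v in d["image_size"])
    return SimConfig(**d)


def load_session(path: str | Path) -> SyntheticSession:
    """Read a session directory back into memory."""
    path = Path(path)
    for required in ("traces.csv", "position.csv", "states.csv",
                     "lfp.bin", "lfp_meta.json", "config.yaml"):
        if not (path / required).exists():
            raise FileNotFoundError(f"missing session file: {path / required}")
    cfg = config_from_dict(yaml.safe_load((path / "config.yaml").read_text()))

    tr = pd.read_csv(path / "traces.csv")
    times = tr.pop("time_s").to_numpy()
    cell_ids = [int(c.split("_", 1)[1]) for c in tr.columns]
    fluor = FluorescenceMatrix(traces=tr.to_numpy().T,
                               frame_rate=cfg.frame_rate,
                               cell_ids=cell_ids,
                               start_time=float(times[0]))

    posdf = pd.read_csv(path / "position.csv")
    stdf = pd.read_csv(path / "states.csv")
    states = [StateInterval(r.label, r.start_s, r.end_s, r.context)
              for r in stdf.itertuples()]

    meta = json.loads((path / "lfp_meta.json").read_text())
    samples = np.fromfile(path / "lfp.bin", dtype="<i2").astype(float)
    samples /= meta["scale_counts_per_uv"]
    lfp = LfpChannel(samples=samples, rate=meta["rate_hz"],
                     start_time=meta["start_time_s"],
                     layer_tag=meta.get("layer_tag", "unknown"))

    ripples: list[dict] = []
    rip_path = path / "ripples.csv"
    if rip_path.exists():
        rdf = pd.read_csv(rip_path)
        ripples = [{"start": r.start_s, "end": r.end_s,
                    "train_id": int(r.train_id)} for r in rdf.itertuples()]

    neuropil = None
    if (path / "neuropil.csv").exists():
        neuropil = pd.read_csv(path / "neuropil.csv")["neuropil"].to_numpy()
    masks = None
    if (path / "masks.tiff").exists():
        masks = IcMaskSet(masks=tifffile.imread(path / "masks.tiff"))
    movie = None
    if (path / "movie.tiff").exists():
        movie = PixelStack(frames=tifffile.imread(path / "movie.tiff"),
                           frame_rate=cfg.frame_rate)

    return SyntheticSession(
        config=cfg,
        timestamps=posdf["time_s"].to_numpy(),
        position=posdf["position_cm"].to_numpy(),
        true_states=states,
        true_spike_times={},
        true_ripples=ripples,
        fluorescence=fluor,
        lfp=lfp,
        masks=masks,
        neuropil=neuropil,
        movie=movie,
    )
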