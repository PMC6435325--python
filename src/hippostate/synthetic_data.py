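"""Ground-truth-annotated synthetic sessions for the CA1 analysis pipeline.

A synthetic session emulates a miniscope + silicon-probe recording: a mouse
runs back and forth on a 200 cm linear track, then rests and sleeps in a
sleep box.  Per-cell calcium events follow state-dependent Poisson rates
and are convolved with GCaMP6f double-exponential kinetics (rise 50 ms,
decay 400 ms, peak-normalized); the LFP (2 kHz) carries 1/f background
noise, state-dependent theta (8 Hz) during RUN and REM, and
Hanning-enveloped 150 Hz ripple bursts — grouped into trains with < 1 s
gaps — restricted to QW/SWS.  Small pixel movies compose Gaussian soma
masks with a diffuse neuropil signal.  All randomness flows from one
master seed through independent named substreams, so each component is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hippostate.imaging import FluorescenceMatrix, IcMaskSet, PixelStack
from hippostate.lfp import RIPPLE_BAND, LfpChannel, bandpass_filter
from hippostate.states import StateInterval

__all__ = [
    "SimConfig",
    "SyntheticSession",
    "simulate_behavior",
    "simulate_spikes_and_fluorescence",
    "simulate_lfp",
    "make_masks",
    "render_movie",
    "simulate_place_cell_events",
    "make_session",
]

_STREAMS = {"behavior": 0, "spikes": 1, "lfp": 2, "noise": 3, "movie": 4,
            "masks": 5, "neuropil": 6}

DEFAULT_SCHEDULE = [
    ("RUN", 300.0),
    ("QW", 240.0),
    ("SWS", 420.0),
    ("REM", 40.0),
    ("SWS", 240.0),
    ("QW", 60.0),
]

# Order-of-magnitude defaults: rates highest in RUN, elevated again in REM,
# lowest in SWS (vehicle-control sessions show ~0.02 Hz during running).
DEFAULT_EVENT_RATES = {"RUN": 0.025, "QW": 0.015, "SWS": 0.008, "REM": 0.02}
DEFAULT_THETA_AMP = {"RUN": 60.0, "QW": 5.0, "SWS": 5.0, "REM": 60.0}


@dataclass
class SimConfig:
    """Parameters of a synthetic session (units in field comments)."""

    n_cells: int = 50
    frame_rate: float = 20.0  # Hz (50 ms exposure)
    lfp_rate: float = 2000.0  # Hz
    track_length: float = 200.0  # cm
    state_schedule: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_SCHEDULE))
    event_rate_by_state: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATES))  # Hz
    run_speed: float = 10.0  # cm/s during RUN
    rest_speed_jitter: float = 0.1  # cm/s residual motion when immobile
    arousal_speed: float = 2.0  # cm/s postural shift on waking from sleep
    arousal_duration: float = 3.0  # s of movement at sleep-to-wake transitions
    event_amplitude_z: float = 5.0  # transient peak, units of noise SD
    gcamp_rise_tau: float = 0.05  # s
    gcamp_decay_tau: float = 0.4  # s
    trace_noise_sd: float = 1.0  # Z units
    ripple_rate: float = 0.25  # Hz within QW/SWS
    ripple_center_freq: float = 150.0  # Hz
    ripple_duration: float = 0.06  # s
    ripple_snr: float = 5.0  # ripple amplitude / in-band noise SD
    train_prob: float = 0.3  # P(another ripple follows within < 1 s)
    theta_freq: float = 8.0  # Hz
    theta_amp_by_state: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THETA_AMP))  # µV
    lfp_noise_sd: float = 50.0  # µV broadband background
    image_size: tuple[int, int] = (48, 48)  # pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.state_schedule:
            raise ValueError("state_schedule must be nonempty")
        for label, dur in self.state_schedule:
            if label not in ("RUN", "QW", "SWS", "REM"):
                raise ValueError(f"unknown state label {label!r}")
            if dur <= 0:
                raise ValueError("state durations must be positive")
        if any(r < 0 for r in self.event_rate_by_state.values()):
            raise ValueError("event rates must be nonnegative")
        if self.gcamp_rise_tau <= 0 or self.gcamp_decay_tau <= 0:
            raise ValueError("kinetic time constants must be positive")
        if self.track_length <= 0:
            raise ValueError("track_length must be positive")
        if self.ripple_rate < 0:
            raise ValueError("ripple_rate must be nonnegative")
        bandwidth = RIPPLE_BAND.high - RIPPLE_BAND.low
        if self.lfp_rate < 2 * (self.ripple_center_freq + bandwidth / 2):
            raise ValueError("lfp_rate too low for the ripple band")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.state_schedule))

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream of the master seed."""
        key = _STREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class SyntheticSession:
    """A generated session with its ground-truth annotations."""

    config: SimConfig
    timestamps: np.ndarray  # frame clock, s
    position: np.ndarray  # cm
    true_states: list[StateInterval]
    true_spike_times: dict[int, np.ndarray]
    true_ripples: list[dict]  # {'start','end','train_id'}
    fluorescence: FluorescenceMatrix
    lfp: LfpChannel
    masks: IcMaskSet | None = None
    neuropil: np.ndarray | None = None  # diffuse signal on the frame clock
    movie: PixelStack | None = None


def _kernel_peak_time(rise: float, decay: float) -> float:
    """Argmax of exp(-t/decay) - exp(-t/rise)."""
    return rise * decay / (decay - rise) * np.log(decay / rise)


def gcamp_kernel(
    frame_rate: float, rise: float = 0.05, decay: float = 0.4,
    duration: float = 3.0,
) -> np.ndarray:
    """Peak-normalized double-exponential calcium impulse response."""
    t = np.arange(0.0, duration, 1.0 / frame_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    tp = _kernel_peak_time(rise, decay)
    peak = np.exp(-tp / decay) - np.exp(-tp / rise)
    return k / peak


def simulate_behavior(
    config: SimConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, list[StateInterval]]:
    """Simulate position and the ground-truth state schedule.

    Returns (timestamps, position, states).  During RUN the animal sweeps
    back and forth at ``run_speed``; in QW/SWS/REM it is immobile up to a
    small jitter, except that waking from sleep (SWS/REM -> QW) starts
    with a brief postural movement (``arousal_speed`` for
    ``arousal_duration`` s), as arousals do in vivo.  RUN epochs carry
    context 'track', the rest 'sleepbox'.
    """
    rng = (config.rng("behavior") if seed is None
           else np.random.default_rng(seed))
    fr = config.frame_rate
    n = int(round(config.duration * fr))
    t = np.arange(n) / fr
    position = np.zeros(n)
    states: list[StateInterval] = []

    cursor = 0.0
    pos = 0.0
    direction = 1.0
    prev_label: str | None = None
    for label, dur in config.state_schedule:
        i0 = int(round(cursor * fr))
        i1 = int(round((cursor + dur) * fr))
        context = "track" if label == "RUN" else "sleepbox"
        states.append(StateInterval(label, cursor, cursor + dur, context))
        if (label == "QW" and prev_label in ("SWS", "REM")
                and config.arousal_duration > 0):
            # arousal: the animal shifts away and settles back
            n_ar = min(int(round(config.arousal_duration * fr)), i1 - i0)
            half = n_ar // 2
            step = config.arousal_speed / fr
            for k in range(n_ar):
                pos = pos + step if k < half else max(pos - step, 0.0)
                position[i0 + k] = pos
            i0 += n_ar
        if label == "RUN":
            for i in range(i0, i1):
                pos += direction * config.run_speed / fr
                if pos >= config.track_length:
                    pos = 2 * config.track_length - pos
                    direction = -1.0
                elif pos <= 0.0:
                    pos = -pos
                    direction = 1.0
                position[i] = pos
        else:
            steps = rng.choice([-1.0, 1.0], size=i1 - i0)
            jitter = np.cumsum(steps * config.rest_speed_jitter / fr)
            position[i0:i1] = np.clip(pos + jitter, 0, config.track_length)
            if i1 > i0:
                pos = position[i1 - 1]
        cursor += dur
        prev_label = label
    return t, position, states


def simulate_spikes_and_fluorescence(
    states: list[StateInterval],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[dict[int, np.ndarray], FluorescenceMatrix]:
    """State-dependent Poisson events convolved with GCaMP6f kinetics.

    Each cell emits events as an inhomogeneous Poisson process whose rate
    is constant within a state; every event adds a peak-normalized
    double-exponential transient of amplitude ``event_amplitude_z``;
    Gaussian noise of ``trace_noise_sd`` is added per frame.
    """
    for iv in states:
        if iv.label not in config.event_rate_by_state:
            raise ValueError(f"no event rate configured for {iv.label!r}")
        if config.event_rate_by_state[iv.label] < 0:
            raise ValueError("negative event rate")
    rng = (config.rng("spikes") if seed is None
           else np.random.default_rng(seed))
    fr = config.frame_rate
    duration = max(iv.end for iv in states)
    n = int(round(duration * fr))
    kernel = gcamp_kernel(fr, config.gcamp_rise_tau, config.gcamp_decay_tau)
    klen = len(kernel)

    spikes: dict[int, np.ndarray] = {}
    traces = np.zeros((config.n_cells, n))
    for c in range(config.n_cells):
        times: list[float] = []
        for iv in states:
            rate = config.event_rate_by_state[iv.label]
            if rate <= 0:
                continue
            count = rng.poisson(rate * iv.duration)
            times.extend(rng.uniform(iv.start, iv.end, size=count))
        st = np.sort(np.array(times))
        spikes[c] = st
        for s in st:
            i0 = int(np.ceil(s * fr))
            if i0 >= n:
                continue
            # kernel sampled at frame times relative to the event
            offset = i0 / fr - s
            tk = offset + np.arange(min(klen, n - i0)) / fr
            k = (np.exp(-tk / config.gcamp_decay_tau)
                 - np.exp(-tk / config.gcamp_rise_tau))
            tp = _kernel_peak_time(config.gcamp_rise_tau,
                                   config.gcamp_decay_tau)
            peak = (np.exp(-tp / config.gcamp_decay_tau)
                    - np.exp(-tp / config.gcamp_rise_tau))
            traces[c, i0: i0 + len(tk)] += config.event_amplitude_z * k / peak
    if config.trace_noise_sd > 0:
        noise_rng = (config.rng("noise") if seed is None
                     else np.random.default_rng(seed + 1))
        traces += noise_rng.normal(0.0, config.trace_noise_sd, size=traces.shape)
    fluor = FluorescenceMatrix(traces=traces, frame_rate=fr)
    return spikes, fluor


def _pink_noise(n: int, rng: np.random.Generator, sd: float) -> np.ndarray:
    """1/f-amplitude background noise with the requested SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    return x * (sd / x.std())


def simulate_lfp(
    states: list[StateInterval],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[LfpChannel, list[dict]]:
    """Synthesize LFP with theta, ripples and 1/f background.

    Ripples (Hanning-enveloped sinusoids at ``ripple_center_freq``) occur
    only inside QW/SWS epochs at ``ripple_rate``; with probability
    ``train_prob`` a ripple is followed by another at an end-to-start gap
    < 1 s.  The amplitude is ``ripple_snr`` times the ripple-band SD of the
    background.  Returns the channel and the ground-truth ripple list with
    train annotations (recomputed from the < 1 s gap rule).
    """
    rng = config.rng("lfp") if seed is None else np.random.default_rng(seed)
    fs = config.lfp_rate
    duration = max(iv.end for iv in states)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    lfp = _pink_noise(n, rng, config.lfp_noise_sd)

    # state-dependent theta
    theta = np.sin(2 * np.pi * config.theta_freq * t)
    amp = np.zeros(n)
    for iv in states:
        a = config.theta_amp_by_state.get(iv.label, 0.0)
        i0, i1 = int(round(iv.start * fs)), int(round(iv.end * fs))
        amp[i0:i1] = a
    lfp += amp * theta

    # ripple amplitude calibrated against the in-band background SD
    band_sd = float(bandpass_filter(lfp, RIPPLE_BAND, rate=fs).std())
    amp_rip = config.ripple_snr * band_sd
    ndur = int(round(config.ripple_duration * fs))
    envelope = np.hanning(ndur)

    ripple_starts: list[float] = []
    for iv in states:
        if iv.label not in ("QW", "SWS") or config.ripple_rate <= 0:
            continue
        margin = config.ripple_duration
        count = rng.poisson(config.ripple_rate * iv.duration)
        seeds = np.sort(rng.uniform(iv.start, iv.end - margin, size=count))
        for s in seeds:
            chain = [s]
            while rng.uniform() < config.train_prob:
                gap = rng.uniform(0.08, 0.8)
                nxt = chain[-1] + config.ripple_duration + gap
                if nxt + margin > iv.end:
                    break
                chain.append(nxt)
            ripple_starts.extend(chain)
    ripple_starts = sorted(ripple_starts)

    # drop overlaps (keep the earlier ripple)
    kept: list[float] = []
    for s in ripple_starts:
        if kept and s < kept[-1] + config.ripple_duration + 0.01:
            continue
        kept.append(s)

    true_ripples: list[dict] = []
    for s in kept:
        i0 = int(round(s * fs))
        if i0 + ndur > n:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * config.ripple_center_freq
                     * np.arange(ndur) / fs + phase)
        lfp[i0: i0 + ndur] += amp_rip * envelope * osc
        true_ripples.append({"start": s, "end": s + config.ripple_duration,
                             "train_id": -1})

    # annotate ground-truth trains with the < 1 s end-to-start gap rule
    tid = 0
    i = 0
    while i < len(true_ripples):
        j = i
        while (j + 1 < len(true_ripples)
               and true_ripples[j + 1]["start"] - true_ripples[j]["end"] < 1.0):
            j += 1
        if j > i:
            for k in range(i, j + 1):
                true_ripples[k]["train_id"] = tid
            tid += 1
        i = j + 1

    # internal consistency: no ripple may intersect a RUN or REM epoch
    for rip in true_ripples:
        for iv in states:
            if iv.label in ("RUN", "REM") and (rip["start"] < iv.end
                                               and rip["end"] > iv.start):
                raise RuntimeError("generated ripple intersects RUN/REM")
    return LfpChannel(samples=lfp, rate=fs, layer_tag="pyramidale"), true_ripples


def make_masks(
    config: SimConfig, seed: int | None = None, sigma: float = 1.5,
    background_noise: float = 0.02,
) -> IcMaskSet:
    """Gaussian soma footprints at random, well-separated centers.

    Each mask carries a low-amplitude nonnegative speckle background
    (``background_noise``), emulating the residual full-field weights of
    real ICA spatial filters; set to 0 for clean truncated blobs.
    """
    rng = config.rng("masks") if seed is None else np.random.default_rng(seed)
    h, w = config.image_size
    margin = int(np.ceil(3 * sigma)) + 1
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < config.n_cells and attempts < 200 * config.n_cells:
        attempts += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 > (3 * sigma) ** 2
               for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < config.n_cells:
        raise ValueError(
            f"cannot place {config.n_cells} separated somas in a "
            f"{h}x{w} field; reduce n_cells or enlarge image_size")
    rows, cols = np.mgrid[0:h, 0:w]
    masks = np.zeros((config.n_cells, h, w))
    for i, (r0, c0) in enumerate(centers):
        g = np.exp(-(((rows - r0) ** 2 + (cols - c0) ** 2)
                     / (2 * sigma**2)))
        g[g < np.exp(-4.5)] = 0.0  # truncate support at 3 sigma
        if background_noise > 0:
            g = g + np.abs(rng.normal(0.0, background_noise, size=g.shape))
        masks[i] = g
    return IcMaskSet(masks=masks)


def render_movie(
    masks: IcMaskSet,
    traces: FluorescenceMatrix,
    neuropil_signal: np.ndarray,
    seed: int | np.random.Generator = 0,
    neuropil_weight: float = 0.3,
    pixel_noise_sd: float = 0.0,
) -> PixelStack:
    """Compose a pixel movie from soma masks, traces and a diffuse signal.

    frame(t) = Σ_c mask_c · trace_c(t) + neuropil_weight · neuropil(t)
    everywhere, plus optional iid pixel noise.
    """
    if masks.n_cells != traces.n_cells:
        raise ValueError("mask and trace cell counts differ")
    neuropil_signal = np.asarray(neuropil_signal, dtype=float)
    if len(neuropil_signal) != traces.n_frames:
        raise ValueError("neuropil signal length must match the trace frames")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    flat_masks = masks.masks.reshape(masks.n_cells, -1)
    frames = traces.traces.T @ flat_masks  # (time, pixels)
    frames += neuropil_weight * neuropil_signal[:, None]
    if pixel_noise_sd > 0:
        frames = frames + rng.normal(0.0, pixel_noise_sd, size=frames.shape)
    return PixelStack(
        frames=frames.reshape(traces.n_frames, *masks.shape),
        frame_rate=traces.frame_rate,
        start_time=traces.start_time,
    )


def simulate_neuropil(
    config: SimConfig, n_frames: int, seed: int | None = None
) -> np.ndarray:
    """Slow diffuse fluorescence: low-pass-filtered Gaussian noise."""
    rng = (config.rng("neuropil") if seed is None
           else np.random.default_rng(seed))
    white = rng.standard_normal(n_frames)
    from scipy.ndimage import gaussian_filter1d

    slow = gaussian_filter1d(white, sigma=0.5 * config.frame_rate,
                             mode="reflect")
    sd = slow.std()
    return slow / sd if sd > 0 else slow


def simulate_place_cell_events(
    timestamps: np.ndarray,
    position: np.ndarray,
    run_sample_idx: np.ndarray,
    n_events: int,
    rng: np.random.Generator,
    field_center: float | None = None,
    field_sigma: float = 9.0,
    baseline: float = 0.05,
    track_length: float = 200.0,
) -> np.ndarray:
    """Event onsets of a synthetic place cell during running.

    Events are drawn from the run samples with probability proportional to
    a Gaussian spatial field (σ = ``field_sigma`` cm) on a uniform
    ``baseline``; the default contrast (peak/baseline = 21) reflects the
    high in-field/out-of-field rate ratio of CA1 place cells.  With
    ``baseline`` large the cell degrades toward a non-place cell; pass
    ``field_center=None`` to draw the field location uniformly in the
    central track.
    """
    position = np.asarray(position, dtype=float)
    if field_center is None:
        field_center = rng.uniform(0.15 * track_length, 0.85 * track_length)
    pos_run = position[run_sample_idx]
    w = np.exp(-((pos_run - field_center) ** 2) / (2 * field_sigma**2))
    w = w + baseline
    idx = rng.choice(run_sample_idx, size=n_events, p=w / w.sum())
    return np.sort(np.asarray(timestamps, dtype=float)[idx])


def make_session(config: SimConfig, include_movie: bool = False) -> SyntheticSession:
    """Generate a full session from a config (deterministic in the seed)."""
    t, position, states = simulate_behavior(config)
    spikes, fluor = simulate_spikes_and_fluorescence(states, config)
    lfp, ripples = simulate_lfp(states, config)
    neuropil = simulate_neuropil(config, fluor.n_frames)
    masks = None
    movie = None
    if include_movie:
        masks = make_masks(config)
        movie = render_movie(masks, fluor, neuropil,
                             seed=config.rng("movie"), pixel_noise_sd=0.0)
    return SyntheticSession(
        config=config,
        timestamps=t,
        position=position,
        true_states=states,
        true_spike_times=spikes,
        true_ripples=ripples,
        fluorescence=fluor,
        lfp=lfp,
        masks=masks,
        neuropil=neuropil,
        movie=movie,
    )
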