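"""LFP band filtering, power envelopes, multitaper spectrograms, MUA screening.

Filtering uses zero-phase Blackman-windowed FIR band-passes (applied by
linear convolution with a symmetric odd-length kernel, so there is no group
delay).  Ripple power is estimated as the magnitude of the analytic signal
of the 80–400 Hz filtered trace, Gaussian-smoothed (σ = 10 ms) and z-scored
over the full recording; a squared-signal + boxcar alternative is available.
Spectrograms are multitaper (DPSS) estimates with the low preset (0–20 Hz,
4 s window, 100 ms step) and high preset (80–300 Hz, 100 ms window, 10 ms
step).  Multiunit snippets are screened for 1.3 kHz camera noise by
least-squares projection onto a quadrature pair at the noise frequency;
snippets carrying >= 40 µV of that component are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal.windows import dpss

__all__ = [
    "LfpChannel",
    "BandDefinition",
    "RIPPLE_BAND",
    "THETA_BAND",
    "DELTA_BAND",
    "bandpass_filter",
    "power_envelope",
    "band_power",
    "sliding_band_power",
    "spectrogram",
    "filter_mua",
]


@dataclass
class LfpChannel:
    """A local field potential channel (µV), uniformly sampled."""

    samples: np.ndarray
    rate: float = 2000.0
    start_time: float = 0.0
    layer_tag: str = "unknown"  # pyramidale | radiatum | unknown

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("LFP samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")


RIPPLE_BAND = BandDefinition("ripple", 80.0, 400.0)
THETA_BAND = BandDefinition("theta", 5.0, 12.0)
DELTA_BAND = BandDefinition("delta", 0.5, 4.0)


def _fir_taps(band: BandDefinition, rate: float, n_samples: int) -> np.ndarray:
    """Blackman-window FIR band-pass; order 3.3/(transition/rate) with
    transition width 25% of the low band edge, capped by the data length."""
    if band.high >= rate / 2:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) exceeds Nyquist "
            f"({rate / 2} Hz)"
        )
    transition = 0.25 * band.low
    ntaps = int(np.ceil(3.3 * rate / transition))
    ntaps = min(ntaps, max(3, (n_samples // 3) * 2 - 1))
    if ntaps % 2 == 0:
        ntaps += 1
    return signal.firwin(
        ntaps, [band.low, band.high], window="blackman", pass_zero=False, fs=rate
    )


def bandpass_filter(lfp: LfpChannel | np.ndarray, band: BandDefinition,
                    rate: float | None = None) -> np.ndarray:
    """Zero-phase Blackman FIR band-pass of an LFP channel or raw array."""
    if isinstance(lfp, LfpChannel):
        x, fs = lfp.samples, lfp.rate
    else:
        if rate is None:
            raise ValueError("rate required when passing a raw array")
        x, fs = np.asarray(lfp, dtype=float), float(rate)
    taps = _fir_taps(band, fs, len(x))
    # symmetric odd-length kernel + 'same' convolution => exactly zero phase
    return signal.fftconvolve(x, taps, mode="same")


def power_envelope(
    filtered: np.ndarray,
    rate: float,
    smooth_sigma: float = 0.010,
    method: str = "hilbert",
    zscore: bool = True,
) -> np.ndarray:
    """Instantaneous band power: analytic-signal magnitude (default) or
    squared signal with a boxcar, smoothed and z-scored over the recording."""
    filtered = np.asarray(filtered, dtype=float)
    if filtered.size == 0:
        raise ValueError("empty input")
    if method == "hilbert":
        env = np.abs(signal.hilbert(filtered))
        if smooth_sigma > 0:
            env = gaussian_filter1d(env, sigma=smooth_sigma * rate, mode="reflect")
    elif method == "squared":
        env = filtered**2
        if smooth_sigma > 0:
            win = max(1, int(round(2 * smooth_sigma * rate)))
            env = uniform_filter1d(env, size=win, mode="reflect")
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    if not zscore:
        return env
    sd = env.std()
    if sd == 0:
        raise ValueError("zero-variance envelope cannot be z-scored")
    return (env - env.mean()) / sd


def band_power(
    lfp: LfpChannel,
    band: BandDefinition,
    intervals: list[tuple[float, float]],
) -> list[float]:
    """Mean squared band-filtered signal over each (start, end) interval."""
    filtered = bandpass_filter(lfp, band)
    t0, fs = lfp.start_time, lfp.rate
    out: list[float] = []
    for start, end in intervals:
        i0 = max(0, int(np.ceil((start - t0) * fs)))
        i1 = min(len(filtered), int(np.floor((end - t0) * fs)))
        if i1 <= i0:
            warnings.warn(f"interval ({start}, {end}) is empty; excluded",
                          stacklevel=2)
            continue
        out.append(float(np.mean(filtered[i0:i1] ** 2)))
    return out


def sliding_band_power(
    lfp: LfpChannel,
    band: BandDefinition,
    out_times: np.ndarray,
    window: float = 10.0,
) -> np.ndarray:
    """Band power in a sliding window, sampled at ``out_times``.

    Used by the state scorer to get theta and delta power series on the
    behavior clock.
    """
    filtered = bandpass_filter(lfp, band)
    win = max(1, int(round(window * lfp.rate)))
    power = uniform_filter1d(filtered**2, size=win, mode="nearest")
    return np.interp(np.asarray(out_times, float), lfp.times, power)


SPECTROGRAM_PRESETS = {
    "low": dict(freq_range=(0.0, 20.0), window=4.0, step=0.1),
    "high": dict(freq_range=(80.0, 300.0), window=0.1, step=0.01),
}


def spectrogram(
    lfp: LfpChannel,
    freq_range: tuple[float, float] | None = None,
    window: float | None = None,
    step: float | None = None,
    preset: str | None = None,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multitaper sliding-window spectrogram.

    Returns (times, freqs, power) with power of shape (n_windows, n_freqs).
    ``preset`` selects 'low' (0–20 Hz, 4 s / 100 ms) or 'high'
    (80–300 Hz, 100 ms / 10 ms); explicit arguments override.
    """
    if preset is not None:
        p = SPECTROGRAM_PRESETS[preset]
        freq_range = freq_range or p["freq_range"]
        window = window or p["window"]
        step = step or p["step"]
    if freq_range is None or window is None or step is None:
        raise ValueError("give freq_range, window and step, or a preset")
    if window <= step:
        raise ValueError("window must exceed step")
    x, fs = lfp.samples, lfp.rate
    nwin = int(round(window * fs))
    nstep = int(round(step * fs))
    if nwin > len(x):
        raise ValueError("window longer than the recording")
    tapers = dpss(nwin, nw, n_tapers)  # (n_tapers, nwin)
    freqs = np.fft.rfftfreq(nwin, 1 / fs)
    fsel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    starts = np.arange(0, len(x) - nwin + 1, nstep)
    power = np.empty((len(starts), int(fsel.sum())))
    for i, s in enumerate(starts):
        seg = x[s: s + nwin]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        power[i] = (np.abs(spec[:, fsel]) ** 2).mean(axis=0) / fs
    times = lfp.start_time + (starts + nwin / 2) / fs
    return times, freqs[fsel], power


def fit_noise_amplitude(
    waveform: np.ndarray, rate: float = 32000.0, noise_freq: float = 1300.0
) -> float:
    """Amplitude (µV) of a sinusoidal component at ``noise_freq`` estimated
    by least squares (quadrature pair + DC) over the snippet."""
    w = np.asarray(waveform, dtype=float)
    t = np.arange(len(w)) / rate
    design = np.column_stack(
        [np.sin(2 * np.pi * noise_freq * t), np.cos(2 * np.pi * noise_freq * t),
         np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(design, w, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


def filter_mua(
    waveforms: np.ndarray,
    rate: float = 32000.0,
    noise_freq: float = 1300.0,
    amp_threshold: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Screen spike snippets for camera-associated 1.3 kHz electrical noise.

    Snippets whose fitted noise-component amplitude is at least
    ``amp_threshold`` µV are excluded.  Returns (accepted_idx, excluded_idx).
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    amps = np.array([fit_noise_amplitude(w, rate, noise_freq) for w in waveforms])
    excluded = amps >= amp_threshold
    return np.flatnonzero(~excluded), np.flatnonzero(excluded)
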