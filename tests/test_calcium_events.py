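"""Calcium transient detection, onsets, rates and bursts."""

import numpy as np
import pytest

from hippostate.calcium_events import (CalciumEvent, EventDetectionConfig,
                                       burst_fraction, detect_events,
                                       detection_delay, event_rates,
                                       zscore_trace)
from hippostate.states import StateInterval
from hippostate.synthetic_data import gcamp_kernel

RATE = 20.0
RAW = EventDetectionConfig(smooth_sigma_s=0.0)  # bare threshold crossings


def bump_trace(peak=6.0, n=600, at=300, width=8, noise=0.0, rng=None):
    """A noiseless baseline with one smooth bump of a given raw height."""
    x = np.zeros(n)
    x[at - width: at + width] = peak * np.hanning(2 * width)
    if noise and rng is not None:
        x = x + rng.normal(0, noise, n)
    return x


def scan_onset_oracle(z, peak_idx, frac):
    """Brute-force per-sample scan for the fractional-amplitude crossing."""
    level = frac * z[peak_idx]
    j = peak_idx
    while j > 0 and z[j - 1] > level:
        j -= 1
    lo, hi = z[j - 1], z[j]
    return (j - 1) + (level - lo) / (hi - lo)


class TestDetectEvents:
    def test_constant_trace_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            detect_events(np.ones(100), RATE, RAW)

    def test_isolated_bump_yields_one_event_with_scanned_onset(self):
        x = bump_trace()
        events = detect_events(x, RATE, RAW)
        assert len(events) == 1
        ev = events[0]
        z = zscore_trace(x)
        peak_idx = int(round(ev.peak_time * RATE))
        oracle = scan_onset_oracle(z, peak_idx, RAW.onset_fraction)
        assert ev.onset_time == pytest.approx(oracle / RATE, abs=1e-12)
        assert ev.amplitude == pytest.approx(z.max())

    def test_onset_precedes_peak_and_sits_at_fraction(self, rng):
        x = bump_trace(noise=0.3, rng=rng)
        for ev in detect_events(x, RATE, RAW):
            assert ev.onset_time <= ev.peak_time
            z = zscore_trace(x)
            # interpolated z at the onset is the 20%-of-peak level
            idx = ev.onset_time * RATE
            i = int(np.floor(idx))
            zi = z[i] + (idx - i) * (z[min(i + 1, len(z) - 1)] - z[i])
            assert zi == pytest.approx(RAW.onset_fraction * ev.amplitude,
                                       abs=0.15)

    def test_threshold_monotonicity(self, rng):
        x = rng.normal(size=2000) + bump_trace(n=2000, at=700)
        counts = [len(detect_events(
            x, RATE, EventDetectionConfig(threshold_z=thr,
                                          smooth_sigma_s=0.0,
                                          min_samples=1)))
            for thr in (1.5, 2.0, 3.0, 4.0)]
        assert counts == sorted(counts, reverse=True)

    def test_two_separated_excursions_are_two_events(self):
        x = bump_trace(n=1200, at=300) + bump_trace(n=1200, at=900)
        assert len(detect_events(x, RATE, RAW)) == 2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EventDetectionConfig(threshold_z=0.0)
        with pytest.raises(ValueError):
            EventDetectionConfig(onset_fraction=1.5)


class TestDetectionDelay:
    def test_step_rise_delay_is_below_one_frame(self):
        # start and 20% crossing fall within the same inter-sample step
        x = np.zeros(400)
        x[200:210] = 8.0  # instantaneous rise
        events = detect_events(x, RATE, RAW)
        out = detection_delay(x, RATE, events)
        assert 0.0 <= out["mean"] < 1.0 / RATE

    def test_kernel_delay_matches_closed_form(self):
        # double-exponential transient: delay from the 0.5 Z start sample
        # to the 20%-of-peak crossing follows the kernel shape
        kern = 6.0 * gcamp_kernel(200.0)  # dense sampling, peak 6 raw units
        x = np.concatenate([np.zeros(2000), kern, np.zeros(2000)])
        events = detect_events(x, 200.0, RAW)
        assert len(events) == 1
        out = detection_delay(x, 200.0, events)
        # oracle on the z-scored kernel: time from the last sample at or
        # below 0.5 z to the 20%-of-peak crossing
        z = zscore_trace(x)
        t = np.arange(len(kern)) / 200.0
        k = z.max() * gcamp_kernel(200.0)
        t_half = t[np.argmax(k > 0.5)]
        t_frac = t[np.argmax(k > 0.2 * k.max())]
        expected = t_frac - t_half
        assert out["mean"] == pytest.approx(expected, abs=1.5 / 200.0)

    def test_empty_event_list_raises(self):
        with pytest.raises(ValueError, match="no events"):
            detection_delay(np.zeros(10), RATE, [])


class TestEventRates:
    def _ev(self, cell, t):
        return CalciumEvent(cell_id=cell, onset_time=t, peak_time=t + 0.1,
                            amplitude=4.0, threshold_used=3.0)

    def test_rate_arithmetic(self):
        events = [self._ev(0, t) for t in np.linspace(5, 115, 6)]
        ivs = [StateInterval("RUN", 0.0, 120.0, "track")]
        out = event_rates(events, ivs)
        assert out.loc[0, "rate_hz"] == pytest.approx(6 / 120.0)

    def test_absent_label_not_reported(self):
        out = event_rates([self._ev(0, 1.0)],
                          [StateInterval("QW", 0.0, 10.0)])
        assert set(out["state"]) == {"QW"}

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            event_rates([], [StateInterval("QW", 0.0, 10.0),
                             StateInterval("SWS", 5.0, 15.0)])

    def test_matches_membership_count_oracle(self, rng):
        events = [self._ev(int(c), float(t))
                  for c, t in zip(rng.integers(0, 3, 50),
                                  rng.uniform(0, 300, 50))]
        ivs = [StateInterval("QW", 0.0, 100.0),
               StateInterval("SWS", 100.0, 250.0),
               StateInterval("QW", 250.0, 300.0)]
        out = event_rates(events, ivs)
        for _, row in out.iterrows():
            n = 0
            for ev in events:
                if ev.cell_id != row["cell_id"]:
                    continue
                for iv in ivs:
                    if iv.label == row["state"] and \
                            iv.start <= ev.onset_time < iv.end:
                        n += 1
            assert row["n_events"] == n


class TestBurstFraction:
    def _events(self, times, cell=0):
        return [CalciumEvent(cell, t, t + 0.1, 4.0, 3.0) for t in times]

    def test_single_event_has_no_instantaneous_rate(self):
        out = burst_fraction(self._events([10.0]), np.arange(100.0),
                             np.zeros(100))
        assert out["n_bursts"] == 0

    def test_one_second_pair_is_burst(self):
        speed = np.full(100, 2.0)
        out = burst_fraction(self._events([10.0, 11.0]), np.arange(100.0),
                             speed)
        assert out["n_bursts"] == 1
        assert out["fraction_moving"] == 1.0

    def test_three_second_pair_is_not_burst(self):
        out = burst_fraction(self._events([10.0, 13.0]), np.arange(100.0),
                             np.zeros(100))
        assert out["n_bursts"] == 0
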