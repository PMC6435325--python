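"""Peri-SWR statistics and synchronous-calcium-event detection."""

import numpy as np
import pytest

from hippostate.coupling import (detect_sce, neuropil_peth, peth,
                                 sce_null_moments, sce_ripple_significance,
                                 sce_swr_cooccurrence, swr_window_stats,
                                 _window_occupancy)
from hippostate.swr import SwrEvent, group_trains


def _swr(start, dur=0.05):
    return SwrEvent(start=start, end=start + dur, peak_power=4.0)


class TestPeth:
    def test_no_events_gives_zero_histogram(self):
        p = peth(np.array([]), np.array([10.0, 20.0]))
        assert np.all(p.counts == 0)

    def test_events_at_triggers_peak_at_zero_lag(self, rng):
        triggers = np.sort(rng.uniform(20, 580, 40))
        p = peth(triggers.copy(), triggers)
        assert abs(p.bin_centers[np.argmax(p.rate_smoothed)]) <= 0.05

    def test_poisson_background_is_flat(self, rng):
        # homogeneous events at rate r: mean PETH bin within 3 SE of r
        r = 2.0
        events = np.sort(rng.uniform(0, 3000, int(3000 * r)))
        triggers = np.sort(rng.uniform(100, 2900, 60))
        p = peth(events, triggers)
        per_bin_mean = p.rate.mean()
        se = p.rate.std() / np.sqrt(len(p.rate))
        assert abs(per_bin_mean - r) < 3 * se + 0.05 * r

    def test_smoothing_conserves_mass(self, rng):
        events = np.sort(rng.uniform(0, 600, 500))
        triggers = np.sort(rng.uniform(50, 550, 30))
        p = peth(events, triggers)
        assert p.rate_smoothed.sum() == pytest.approx(p.rate.sum(),
                                                      rel=1e-9)

    def test_requires_triggers(self):
        with pytest.raises(ValueError, match="trigger"):
            peth(np.array([1.0]), np.array([]))


class TestSwrWindowStats:
    def test_homogeneous_events_have_equal_windows(self, rng):
        events = np.sort(rng.uniform(0, 2000, 8000))
        swrs = [_swr(s) for s in np.linspace(100, 1900, 80)]
        ws = swr_window_stats(events, swrs, mode="all")
        assert ws.at == pytest.approx(ws.pre, rel=0.25)
        assert ws.post == pytest.approx(ws.pre, rel=0.25)
        assert ws.windows["pre"] == [-5.0, -2.0]
        assert ws.windows["post"] == [1.0, 2.0]

    def test_pre_trigger_dip_detected(self, rng):
        # remove events in the 300 ms before each trigger
        triggers = np.linspace(100, 1900, 90)
        events = np.sort(rng.uniform(0, 2000, 8000))
        keep = np.ones(len(events), bool)
        for trig in triggers:
            keep &= ~((events > trig - 0.3) & (events <= trig + 0.02))
        ws = swr_window_stats(events[keep], [_swr(s) for s in triggers],
                              mode="all")
        assert ws.pre > ws.at

    def test_train_mode_triggers_on_last_member_offset(self, rng):
        events = np.sort(rng.uniform(0, 600, 2000))
        swrs = [_swr(10.0), _swr(10.3), _swr(10.9), _swr(50.0)]
        singlets, trains = group_trains(swrs)
        ws = swr_window_stats(events, swrs, trains, mode="trains")
        assert ws.n_triggers == 1
        assert ws.windows["at"] == "offset"

    def test_trains_mode_without_trains_warns(self):
        with pytest.warns(UserWarning, match="no SWR trains"):
            out = swr_window_stats(np.array([1.0]), [_swr(10.0)], [],
                                   mode="trains")
        assert out is None


class TestNeuropilPeth:
    def test_constant_trace_gives_flat_average(self):
        trace = np.full(4000, 2.5)
        lags, avg, ws = neuropil_peth(trace, 20.0, np.array([60.0, 100.0]))
        np.testing.assert_allclose(avg, 2.5)
        assert ws.pre == pytest.approx(2.5)

    def test_recovers_injected_deflection(self, rng):
        fr = 20.0
        trace = rng.normal(0, 0.05, 40000)
        deflection = np.exp(-np.arange(40) / 10.0)
        triggers = np.linspace(100, 1900, 60)
        for trig in triggers:
            i = int(trig * fr)
            trace[i: i + 40] += deflection
        lags, avg, _ = neuropil_peth(trace, fr, triggers)
        sel = (lags >= 0) & (lags < 2.0)
        r = np.corrcoef(avg[sel], deflection)[0, 1]
        assert r > 0.95

    def test_noise_averaging_scales_as_sqrt_n(self, rng):
        fr = 20.0
        trace = rng.normal(size=200000)
        for n in (10, 90):
            triggers = np.linspace(200, 9800, n)
            _, avg, _ = neuropil_peth(trace, fr, triggers)
            if n == 10:
                sd10 = avg.std()
            else:
                sd90 = avg.std()
        assert sd10 / sd90 == pytest.approx(3.0, rel=0.35)

    def test_edge_triggers_dropped(self):
        trace = np.zeros(200)
        with pytest.raises(ValueError, match="fits"):
            neuropil_peth(trace, 20.0, np.array([0.5]))


class TestDetectSce:
    def test_no_events_yields_no_sces(self):
        assert detect_sce({0: np.array([]), 1: np.array([])}, 600.0) == []

    def test_planted_synchrony_is_detected_with_first_onset(self, rng):
        ev = {c: np.sort(rng.uniform(0, 600, 10)) for c in range(20)}
        planted = 60.0 + 0.01 * np.arange(8)
        for c in range(8):
            ev[c] = np.sort(np.append(ev[c], planted[c]))
        sces = detect_sce(ev, 600.0, seed=1)
        assert len(sces) >= 1
        hit = min(sces, key=lambda s: abs(s.onset - 60.0))
        assert hit.onset == pytest.approx(60.0, abs=0.01)
        assert hit.n_cells >= 8
        assert hit.z_vs_shuffle > 3

    def test_null_paths_agree(self, rng):
        occ = np.vstack([
            _window_occupancy(np.sort(rng.choice(300, 12, replace=False)),
                              300, 5) for _ in range(8)])
        m1, s1 = sce_null_moments(occ, 40, np.random.default_rng(9),
                                  method="explicit")
        m2, s2 = sce_null_moments(occ, 40, np.random.default_rng(9),
                                  method="fft")
        assert m1 == pytest.approx(m2, abs=1e-9)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_invariant_to_cell_relabeling_and_time_shift(self, rng):
        ev = {c: np.sort(rng.uniform(0, 300, 12)) for c in range(10)}
        for c in range(6):
            ev[c] = np.sort(np.append(ev[c], 100.0 + 0.02 * c))
        a = detect_sce(ev, 300.0, min_cells=5, seed=3)
        relabeled = {100 + c: v for c, v in ev.items()}
        b = detect_sce(relabeled, 300.0, min_cells=5, seed=3)
        shifted = {c: v + 50.0 for c, v in ev.items()}
        c_out = detect_sce(shifted, 350.0, min_cells=5, seed=3,
                           start_time=50.0)
        assert [s.onset for s in a] == [s.onset for s in b]
        assert [round(s.onset + 50.0, 6) for s in a] == \
            [round(s.onset, 6) for s in c_out]

    def test_seed_reproducibility(self, rng):
        ev = {c: np.sort(rng.uniform(0, 300, 15)) for c in range(10)}
        a = detect_sce(ev, 300.0, seed=5)
        b = detect_sce(ev, 300.0, seed=5)
        assert [(s.onset, s.z_vs_shuffle) for s in a] == \
            [(s.onset, s.z_vs_shuffle) for s in b]

    def test_session_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_sce({0: np.array([0.1])}, 0.1, window=0.25)


class TestSceSwrCoupling:
    def test_no_ripples_no_cooccurrence(self):
        from hippostate.coupling import SceEvent

        sces = [SceEvent(onset=10.0, cell_ids=[1, 2, 3, 4, 5],
                         z_vs_shuffle=4.0)]
        assert sce_swr_cooccurrence(sces, [])["fraction"] == 0.0

    def test_window_membership(self):
        from hippostate.coupling import SceEvent

        swrs = [_swr(100.0)]
        near = SceEvent(onset=99.95, cell_ids=[1] * 5, z_vs_shuffle=4.0)
        late = SceEvent(onset=100.3, cell_ids=[1] * 5, z_vs_shuffle=4.0)
        out = sce_swr_cooccurrence([near, late], swrs)
        assert out["n_cooccurring"] == 1  # -50 ms in; +300 ms out

    def test_constant_power_has_no_significant_sces(self):
        from hippostate.coupling import SceEvent

        sces = [SceEvent(onset=5.0, cell_ids=[1] * 5, z_vs_shuffle=4.0)]
        out = sce_ripple_significance(sces, np.zeros(20000), 2000.0, seed=0)
        assert out["n_significant"] == 0

    def test_planted_coupling_is_significant(self, rng):
        from hippostate.coupling import SceEvent

        power = rng.normal(0, 0.3, 1200000)
        peaks = np.linspace(20, 580, 25)
        fs = 2000.0
        for pk in peaks:
            i = int(pk * fs)
            power[i - 100: i + 100] += 5.0 * np.hanning(200)
        sces = [SceEvent(onset=float(pk), cell_ids=[1] * 5,
                         z_vs_shuffle=4.0) for pk in peaks]
        out = sce_ripple_significance(sces, power, fs, seed=0)
        assert out["fraction_significant"] >= 0.8
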