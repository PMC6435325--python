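"""Ground-truth structure of the synthetic session generator."""

import numpy as np
import pytest

from hippostate.imaging import FluorescenceMatrix
from hippostate.synthetic_data import (SimConfig, gcamp_kernel, make_masks,
                                       make_session, render_movie,
                                       simulate_behavior, simulate_lfp,
                                       simulate_spikes_and_fluorescence)


class TestBehavior:
    def test_run_traversal_kinematics(self):
        # 10 cm/s on a 200 cm track: one full traversal per 20 s
        cfg = SimConfig(state_schedule=[("RUN", 600.0)], seed=0)
        t, pos, states = simulate_behavior(cfg)
        assert cfg.track_length == 200.0
        # count arrivals at the far end as traversal markers
        at_end = (pos > 199.0).astype(int)
        n_traversals = int(np.sum(np.diff(at_end) == 1))
        assert n_traversals == 15  # 600 s / (2 * 200 cm / 10 cm/s) * 2 ends
        speed = np.abs(np.gradient(pos, t))
        assert np.median(speed) == pytest.approx(10.0, rel=0.05)

    def test_zero_jitter_rest_is_stationary(self):
        cfg = SimConfig(state_schedule=[("QW", 60.0)], rest_speed_jitter=0.0,
                        seed=0)
        _, pos, _ = simulate_behavior(cfg)
        assert np.ptp(pos) == 0.0

    def test_states_tile_session_without_overlap(self):
        cfg = SimConfig(seed=0)
        _, _, states = simulate_behavior(cfg)
        for a, b in zip(states[:-1], states[1:]):
            assert b.start == pytest.approx(a.end)
        assert states[0].start == 0.0
        assert states[-1].end == pytest.approx(cfg.duration)

    def test_unknown_state_label_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            SimConfig(state_schedule=[("NAP", 60.0)])


class TestSpikesAndFluorescence:
    def test_null_process_is_silent(self):
        cfg = SimConfig(n_cells=3, trace_noise_sd=0.0, seed=0,
                        state_schedule=[("QW", 60.0)],
                        event_rate_by_state={"QW": 0.0})
        _, _, states = simulate_behavior(cfg)
        spikes, fluor = simulate_spikes_and_fluorescence(states, cfg)
        assert all(len(s) == 0 for s in spikes.values())
        assert np.all(fluor.traces == 0)

    def test_poisson_event_count(self):
        # 100 cells x 600 s x 0.05 Hz -> mean 3000, SD sqrt(3000)
        cfg = SimConfig(n_cells=100, seed=5, state_schedule=[("QW", 600.0)],
                        event_rate_by_state={"QW": 0.05})
        _, _, states = simulate_behavior(cfg)
        spikes, _ = simulate_spikes_and_fluorescence(states, cfg)
        total = sum(len(s) for s in spikes.values())
        assert abs(total - 3000) < 3 * np.sqrt(3000)

    def test_kernel_peak_matches_closed_form(self):
        cfg = SimConfig(n_cells=1, trace_noise_sd=0.0, seed=0,
                        state_schedule=[("QW", 30.0)],
                        event_rate_by_state={"QW": 0.0})
        _, _, states = simulate_behavior(cfg)
        _, fluor = simulate_spikes_and_fluorescence(states, cfg)
        # inject one spike by hand through the kernel path
        rise, decay = cfg.gcamp_rise_tau, cfg.gcamp_decay_tau
        t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
        kern = gcamp_kernel(cfg.frame_rate, rise, decay)
        assert np.argmax(kern) == pytest.approx(t_peak * cfg.frame_rate, abs=1)
        # discrete sampling cannot exceed the continuous-time peak of 1
        assert kern.max() <= 1.0
        assert kern.max() == pytest.approx(1.0, abs=0.02)

    def test_single_spike_trace_peaks_after_spike(self):
        cfg = SimConfig(n_cells=1, trace_noise_sd=0.0, seed=0,
                        state_schedule=[("QW", 30.0)],
                        event_rate_by_state={"QW": 0.0})
        _, _, states = simulate_behavior(cfg)
        spikes, fluor = simulate_spikes_and_fluorescence(states, cfg)
        traces = fluor.traces.copy()
        # emulate a spike at exactly t = 10 s via the generator's kernel
        kern = cfg.event_amplitude_z * gcamp_kernel(cfg.frame_rate)
        i0 = int(10.0 * cfg.frame_rate)
        traces[0, i0: i0 + len(kern)] += kern
        peak_t = np.argmax(traces[0]) / cfg.frame_rate
        rise, decay = cfg.gcamp_rise_tau, cfg.gcamp_decay_tau
        t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
        assert peak_t > 10.0
        assert peak_t == pytest.approx(10.0 + t_peak, abs=1.0 / cfg.frame_rate)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="nonneg|negative"):
            SimConfig(event_rate_by_state={"QW": -0.1})

    def test_state_dependent_counts_track_configured_rates(self):
        cfg = SimConfig(n_cells=60, seed=9,
                        state_schedule=[("QW", 300.0), ("SWS", 300.0)],
                        event_rate_by_state={"QW": 0.05, "SWS": 0.01})
        _, _, states = simulate_behavior(cfg)
        spikes, _ = simulate_spikes_and_fluorescence(states, cfg)
        qw = sum(int(np.sum(s < 300.0)) for s in spikes.values())
        sws = sum(int(np.sum(s >= 300.0)) for s in spikes.values())
        assert abs(qw - 900) < 4 * np.sqrt(900)
        assert abs(sws - 180) < 4 * np.sqrt(180)


class TestLfp:
    def test_null_oscillations_leave_pure_noise(self):
        cfg = SimConfig(seed=0, ripple_rate=0.0,
                        theta_amp_by_state={"QW": 0.0, "SWS": 0.0},
                        state_schedule=[("QW", 60.0), ("SWS", 60.0)])
        _, _, states = simulate_behavior(cfg)
        lfp, ripples = simulate_lfp(states, cfg)
        assert ripples == []
        assert lfp.samples.std() == pytest.approx(cfg.lfp_noise_sd, rel=0.05)

    def test_ripple_count_and_containment(self):
        cfg = SimConfig(seed=2, ripple_rate=0.5, train_prob=0.0,
                        state_schedule=[("RUN", 60.0), ("SWS", 300.0)])
        _, _, states = simulate_behavior(cfg)
        _, ripples = simulate_lfp(states, cfg)
        # ~150 primary ripples expected (Poisson)
        assert abs(len(ripples) - 150) < 4 * np.sqrt(150)
        sws = states[1]
        for rip in ripples:
            assert sws.start <= rip["start"] and rip["end"] <= sws.end

    def test_train_prob_one_forces_trains(self):
        cfg = SimConfig(seed=3, ripple_rate=0.05, train_prob=1.0,
                        state_schedule=[("SWS", 400.0)])
        _, _, states = simulate_behavior(cfg)
        _, ripples = simulate_lfp(states, cfg)
        assert len(ripples) > 2
        # brute-force gap check: every ripple has a neighbor closer than 1 s
        for i, rip in enumerate(ripples):
            gaps = []
            if i > 0:
                gaps.append(rip["start"] - ripples[i - 1]["end"])
            if i + 1 < len(ripples):
                gaps.append(ripples[i + 1]["start"] - rip["end"])
            assert rip["train_id"] >= 0
            assert min(gaps) < 1.0

    def test_ripples_avoid_run_and_rem(self):
        cfg = SimConfig(seed=4, ripple_rate=0.4,
                        state_schedule=[("QW", 200.0), ("SWS", 200.0),
                                        ("REM", 60.0), ("SWS", 100.0)])
        _, _, states = simulate_behavior(cfg)
        _, ripples = simulate_lfp(states, cfg)
        rem = [iv for iv in states if iv.label == "REM"][0]
        for rip in ripples:
            assert not (rip["start"] < rem.end and rip["end"] > rem.start)


class TestRenderMovie:
    def test_zero_inputs_render_zero_stack(self):
        masks = make_masks(SimConfig(n_cells=2, image_size=(20, 20), seed=0))
        traces = FluorescenceMatrix(traces=np.zeros((2, 10)), frame_rate=20.0)
        movie = render_movie(masks, traces, np.zeros(10), seed=0)
        assert np.all(movie.frames == 0)

    def test_one_pixel_mask_identity(self, rng):
        from hippostate.imaging import IcMaskSet

        m = np.zeros((1, 8, 8))
        m[0, 3, 3] = 1.0
        tr = rng.normal(size=(1, 40))
        movie = render_movie(IcMaskSet(masks=m),
                             FluorescenceMatrix(traces=tr, frame_rate=20.0),
                             np.zeros(40), seed=0, neuropil_weight=0.0)
        np.testing.assert_allclose(movie.frames[:, 3, 3], tr[0])

    def test_round_trip_through_extract_traces(self, rng):
        from hippostate.imaging import extract_traces

        masks = make_masks(SimConfig(n_cells=5, image_size=(30, 30), seed=1),
                           background_noise=0.0)
        tr = rng.normal(size=(5, 100))
        movie = render_movie(masks,
                             FluorescenceMatrix(traces=tr, frame_rate=20.0),
                             np.zeros(100), seed=0, neuropil_weight=0.0)
        out = extract_traces(movie, masks)
        for c in range(5):
            assert np.corrcoef(out.traces[c], tr[c])[0, 1] > 0.99


class TestReproducibility:
    def test_same_seed_is_bit_identical(self):
        a = make_session(SimConfig(n_cells=4, seed=11, state_schedule=[
            ("QW", 60.0), ("SWS", 200.0)]))
        b = make_session(SimConfig(n_cells=4, seed=11, state_schedule=[
            ("QW", 60.0), ("SWS", 200.0)]))
        np.testing.assert_array_equal(a.position, b.position)
        np.testing.assert_array_equal(a.fluorescence.traces,
                                      b.fluorescence.traces)
        np.testing.assert_array_equal(a.lfp.samples, b.lfp.samples)
        assert a.true_ripples == b.true_ripples

    def test_different_seed_differs(self):
        a = make_session(SimConfig(n_cells=2, seed=1,
                                   state_schedule=[("QW", 60.0)]))
        b = make_session(SimConfig(n_cells=2, seed=2,
                                   state_schedule=[("QW", 60.0)]))
        assert not np.array_equal(a.fluorescence.traces, b.fluorescence.traces)
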