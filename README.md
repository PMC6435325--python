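# hippostate

Analysis pipeline for joint one-photon calcium imaging and LFP recordings of
hippocampal CA1 across the sleep–wake cycle, with a ground-truth synthetic
session generator.

Miniscope experiments in freely behaving mice record somatic GCaMP6f ΔF/F
traces (20 fps) together with pyramidal-layer LFP (2 kHz) while the animal
runs on a 200 cm linear track and then rests and sleeps. `hippostate`
implements the downstream analysis such a dataset needs:

- **imaging** — apply IC spatial masks to ΔF/F movies to get per-soma traces;
  select neuropil pixels (pixels strictly below the median of per-pixel maxima
  over unit-normalized ICs within the soma-containing ROI) and integrate them
  into a neuropil trace.
- **calcium_events** — detect transients as threshold crossings of the
  z-scored trace (3 Z for state analyses, 2 Z for pharmacology contrasts),
  with event onset at the 20%-of-maximum crossing; state-resolved event rates
  and burst statistics.
- **lfp** — zero-phase Blackman FIR band filters (ripple 80–400 Hz, theta
  5–12 Hz, delta 0.5–4 Hz), analytic-signal power envelopes, multitaper
  spectrograms, and screening of multiunit snippets for 1.3 kHz camera noise
  (≥ 40 µV excluded).
- **swr** — sharp-wave-ripple detection at 3 Z of ripple power with
  boundaries at the return to the mean and a 20 ms minimum duration; grouping
  into singlets and trains (inter-event gap < 1 s).
- **states** — RUN (> 3 cm/s on the track), QW, SWS (≥ 3 min immobility) and
  REM (sustained theta/delta elevation arising out of SWS, ≥ 10 s) scoring.
- **coupling** — peri-SWR event time histograms (50 ms bins, σ = 50 ms
  Gaussian smoothing) with pre (−5…−2 s), at-SWR and post windows;
  synchronous calcium events (SCEs: ≥ 5 cells within 250 ms, > 3 SD above a
  1000-fold circular-shuffle null), SCE–SWR co-occurrence (−100/+150 ms) and
  ripple-power significance (median + 2·IQR of a shuffled-onset null).
- **place_fields** — directional 3 cm tuning curves from run-period events,
  spatial information `SI = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄)` in bits/event, and a
  1000-shuffle Monte Carlo place-cell test (p < 0.05).
- **reporting** — repeated-measures ANOVA state contrasts with Holm-corrected
  paired post hocs, paired condition contrasts, and an end-to-end pipeline
  driver with full provenance.
- **synthetic_data** — generates sessions with known ground truth: behavior
  with state schedules, state-dependent Poisson events convolved with GCaMP6f
  kinetics (rise 50 ms, decay 400 ms), LFP with 1/f background, theta, and
  ripple trains confined to QW/SWS, and pixel movies composed of soma masks
  plus diffuse neuropil signal.

## Worked example

Run the demo pipeline on a synthetic session (30 cells; 4 min of track
running followed by ~14 min in the sleep box including two SWS bouts and a
REM epoch), then summarize:

```sh
hippostate run --config demo.yaml --seed 7 --out demo_out
hippostate report --out demo_out
```

with `demo.yaml`:

```yaml
session:
  n_cells: 30
  state_schedule: [[RUN, 240], [QW, 200], [SWS, 360], [REM, 30], [SWS, 180], [QW, 60]]
```

prints (abridged):

```
== event_rates.csv ==
           mean       sem
state
QW     0.017592  0.001731
REM    0.017932  0.003923
RUN    0.022222  0.002108
SWS    0.008065  0.000675
== swr_rates.csv ==
state  n_events  duration_s  rate_hz
   QW        93      236.85 0.392654
  REM         0       31.60 0.000000
  RUN         0      240.00 0.000000
  SWS       184      558.00 0.329749
```

Calcium event rates are highest during running, drop in slow-wave sleep and
recover in REM, mirroring the state dependence the generator was configured
with; SWRs are detected only in quiet wakefulness and SWS, where the
generator placed them. `demo_out/` additionally contains the detected events
(`events.csv`), SWR intervals with train annotations
(`ripples_detected.csv`), scored state intervals (`states_scored.csv`),
peri-SWR histograms and window statistics (`peths.csv`,
`window_stats.json`), SCEs (`sces.csv`) and per-cell place-field statistics
(`place_cells.csv`). In this demo the cells carry no spatial tuning, and
accordingly no cell passes the place-field test.

The same stages are available as library functions; `hippostate simulate`
writes a raw synthetic session directory (traces.csv, lfp.bin + metadata,
position.csv, ground-truth states.csv and ripples.csv) that `hippostate run`
can consume via `session: {path: ...}`.

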