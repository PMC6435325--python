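# Methods

This note documents the models and estimators implemented in `hippostate`,
the defaults and why they were chosen, and the limits of what the synthetic
validation establishes.

## Signal model

**Calcium.** Each cell emits point events (somatic calcium transients) as an
inhomogeneous Poisson process whose rate is piecewise-constant within
behavioral states. The fluorescence impulse response is a peak-normalized
difference of exponentials, `k(t) = exp(−t/τ_d) − exp(−t/τ_r)`, with
τ_r = 50 ms (GCaMP6f rise at body temperature) and τ_d = 400 ms (typical
GCaMP6f decay); both are configurable. Transient peak amplitude defaults to
5 in units of the trace noise SD ("Z units"), with additive white Gaussian
noise of SD 1 per frame at 20 fps. Default state rates (RUN 0.025, QW 0.015,
SWS 0.008, REM 0.02 Hz) are order-of-magnitude choices consistent with
vehicle-control event rates of ~0.02 Hz during running reported for this
kind of preparation; no quantitative within-state rates are asserted as
ground truth.

**LFP.** The synthetic LFP is 1/f-amplitude background noise (default SD
50 µV at 2 kHz) plus a state-gated 8 Hz theta sinusoid (strong in RUN and
REM) and ripple events confined to QW/SWS: Hanning-enveloped 150 Hz bursts
of 60 ms, placed as a Poisson process (0.25 Hz default) with geometric
chaining into trains (gap < 1 s) at probability `train_prob`. Ripple
amplitude is expressed as an SNR relative to the ripple-band SD of the
background; the default of 5 reflects the contrast of pyramidal-layer
ripples in vivo, where 3 SD power thresholds detect events reliably.

**Behavior.** RUN is back-and-forth traversal of a 200 cm track at 10 cm/s;
rest states are immobile up to a 0.1 cm/s jitter. Waking from sleep starts
with a 3 s, 2 cm/s postural movement, the observable correlate of an
arousal; without it, the end of a sleep bout would be undetectable from
position alone.

All randomness derives from one master seed through named `SeedSequence`
substreams (behavior, spikes, lfp, noise, masks, neuropil, movie), so each
component is reproducible in isolation and sessions are bit-identical for a
fixed seed.

## Estimator choices

**Event detection.** Traces are z-scored against their full-recording mean
and SD (a robust median/MAD alternative is available). Each maximal
excursion above threshold (3 Z default) is one event; the onset is found by
walking backward from the excursion peak to the 20%-of-peak level, linearly
interpolated between samples. Two noise guards are on by default and can be
disabled: Gaussian pre-smoothing with σ = 100 ms — two frames, matched to
the indicator's ~130 ms rise-to-peak, a matched-filter argument — and a
minimum excursion duration of 2 frames. With white frame noise of SD 1 and
5 Z transients, bare single-sample threshold crossings produce on the order
of one spurious event per 20 s of trace (mostly re-crossings during the
decay phase); the two guards bring the false-positive fraction below 5%
while keeping recall above 90%.

**Ripple power and SWR boundaries.** Ripple power is the magnitude of the
analytic signal of the 80–400 Hz Blackman-FIR-filtered LFP, Gaussian
smoothed with σ = 10 ms and z-scored over the recording (a squared-signal +
boxcar estimator is available). Filters are applied by linear convolution
with symmetric odd-length kernels, hence exactly zero-phase; FIR order is
`ceil(3.3 / (transition/rate))` with transition width 25% of the low band
edge, capped by the data length. SWR events are excursions ≥ 3 Z whose
suprathreshold core lasts ≥ 20 ms; boundaries extend outward to the nearest
return of power to the recording mean, and events whose extended boundaries
touch are merged. Applying the minimum duration to the core (not the
extended extent) keeps short noise excursions out; the extent reading would
re-admit them after boundary extension. Typical start-time accuracy on
synthetic ripples is 7–10 ms (median); the error distribution has a small
tail where the mean-crossing extension walks through pre-ripple noise, so
the median is the meaningful summary.

**State scoring.** Speed is the absolute centered difference of position,
smoothed 0.5 s. On the track, RUN is speed > 3 cm/s and the rest is QW. In
the sleep box, immobility is speed < 0.5 cm/s; a continuous immobility run
of at least 3 min contains sleep, with sleep onset placed at the 3-min mark
and the lead-in labeled QW — posture, which experimenters use to separate
pre-sleep quiet wakefulness from sleep, is unobservable from position, and
the immobility-duration criterion is the natural proxy.
Within sleep, windows where the theta/delta band-power ratio (10 s sliding
windows) is ≥ 2 and that arise after established SWS become REM if they
last ≥ 10 s; the numeric ratio threshold is a package choice (the defining
feature is "high theta"), configurable and echoed into output metadata.
Scored boundaries at the QW→SWS transition carry an irreducible error equal
to the difference between the true (unobservable) sleep latency and 3 min;
per-sample agreement with ground truth on random synthetic sessions
averages ~0.93–0.96.

**Peri-SWR statistics.** PETHs use 50 ms bins (one frame) and Gaussian
smoothing σ = 50 ms applied with reflecting boundaries, which conserves
total mass exactly for a symmetric kernel. Rates are per cell:
counts / (n_triggers × n_cells × bin). "At-SWR" activity is the smoothed
PETH value at lag 0 (trigger = SWR start for all-SWR analyses, SWR offset
for singlet/train analyses, the last member's offset for trains); baseline
is the mean rate in −5…−2 s; delayed activity is the mean in +1…+2 s
(all-SWR) or a 500 ms window centered on the smoothed-PETH maximum within
0–3 s (singlets/trains).

**SCE detection.** A 250 ms window slides in one-frame steps; the statistic
is the number of distinct cells with ≥ 1 event onset in the window. The
null preserves each cell's inter-event structure by circularly shifting its
onset train by an independent uniform offset, 1000 times; window counts are
pooled over positions and shuffles, and a window is an SCE when its count
exceeds the pooled mean by > 3 SD with ≥ 5 cells. The pooled mean and SD
are computed exactly from per-cell window-occupancy cross-correlations
(an FFT identity over the same shuffle draws) rather than materializing
every shuffled count series; the explicit path is retained and the two
agree to 1e-9. Overlapping or adjacent SCE windows merge; the SCE onset is
the earliest participating transient. Ripple coupling reads ripple power at
the SCE onset and compares against the median + 2·IQR of power at 1000
uniformly re-drawn onset sets.

**Place fields.** Directional tuning curves accumulate occupancy and event
counts over 3 cm bins using only samples with speed > 3 cm/s and velocity
sign matching the direction. Spatial information is the standard
bits-per-event form `Σ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄)`; zero-rate bins contribute 0.
The Monte Carlo test redraws the cell's run-period events uniformly from
run samples (preserving occupancy; a whole-session shuffle domain is
available) and uses the add-one estimator
`p = (1 + #{SI_shuffle ≥ SI_obs}) / (1 + 1000)`, so the smallest attainable
p is 1/1001. At 30 events the raw SI estimator is upward-biased for both
observed and shuffled data; detection power therefore depends on field
contrast, reaching ~0.99 for 9 cm Gaussian fields with the ≥ 10:1
in/out-of-field contrast typical of CA1 and falling to ~0.4 at a 5:1
contrast.

**Contrast tables.** Per-animal state means are compared with one-way
repeated-measures ANOVA (statsmodels `AnovaRM`) and pairwise paired t-tests
with Holm correction; REM rows can be excluded per metric (as done for
theta-power contrasts). The module validates design balance and owns the
table structure; the test mathematics are delegated to statsmodels/scipy.

## Validation scope

`scripts/acceptance.py` and the acceptance tests measure every detector
against the generator's ground truth at desk scale: ~120 ripples for SWR
detection, 100 cells × 600 s for event detection, 100 sessions each for the
SCE false-positive and planted-synchrony calibrations, 200 null and 100
place cells for the Monte Carlo test, and 20 random sessions for state
scoring. These sizes keep the full battery to a few minutes on one CPU
while holding binomial uncertainty on the reported rates to a few percent.

The generator deliberately omits several features of real data: no
photobleaching or motion artifacts, white (not shot-limited or correlated)
trace noise, sinusoidal theta rather than asymmetric sawtooth theta, no
sharp-wave (radiatum) component under the ripple, no EMG, and IC masks that
are Gaussian blobs with speckle rather than learned spatial filters.
Passing the battery therefore establishes that the implementations are
correct and calibrated under the stated statistical model — not that the
thresholds are optimal for any particular in vivo dataset. Statistics from
the original experiments (ANOVA F/p values, the −0.189 s pre-SWR
suppression latency, the 12.6% SCE–SWR coincidence) derive from in vivo
recordings and are out of scope here.
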