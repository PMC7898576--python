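# Methods

This note records the models implemented in `pupilbeat`, the parameter
choices that matter, what the synthetic data do and do not emulate, and
the numerical decisions taken where the design was genuinely open.

## Stimuli

Rhythms live on a 16-position grid spanning 4 beats at 107 BPM, so one
grid slot lasts 60/(107·4) ≈ 140.2 ms and one loop 2.243 s. Five shipped
presets span sparse-to-dense onset profiles and, deliberately, distinct
*metric periods*: `sparse` repeats every 4 grid slots (its periodicity
energy collapses onto the 1.78 Hz beat level), `halftime` every 8 slots
(even loop harmonics only), and `complex1-like`, `syncopated` and
`dense` span the full loop (all harmonics of the 0.446 Hz loop rate).
Because every stimulus shares the loop tempo, periodicity peaks can only
fall on loop harmonics; what distinguishes stimuli is *which* harmonics
carry energy. Stimuli whose peak sets nest inside another's (e.g.
`dense` inside `complex1-like`) are genuinely hard to separate with
peak-band coherence — a limitation of the method, not of the
implementation — which is why the default analysis trio takes one
pattern from each metric class.

Three synthetic timbres are rendered as exponentially decaying
band-limited noise bursts with distinct spectral centroids (conga-like
200 Hz / 80 ms decay, snap-like 2 kHz / 30 ms, shaker-like 6 kHz /
15 ms) so that they drive different regions of the 40-band front end, as
distinct sampled instruments would. Bursts wrap circularly past the loop
end; as a result concatenating k rendered loops is sample-identical to
rendering the k-tiled pattern — continuous looping is exactly seamless.
At a 42 800 Hz sample rate (divisible by the grid) every onset falls on
an integer sample; at arbitrary rates onsets are rounded to the nearest
sample.

Deviants are 200 ms windows scaled by `10^(ΔdB/20)`, never wrapping
across the loop boundary; all samples outside the window are
bit-identical to the input. Scheduling: after every standard loop the
next loop carries a deviant with probability 0.8 (after every deviant,
never), at one of four probed positions drawn without replacement in
shuffled blocks over the positions still below their 20-observation
quota.

## Temporal salience model

The front end replaces an auditory-nerve simulation with a 40-channel
band-pass filterbank: 2nd-order Butterworth bands with edges midway (in
ERB number) between centers equally spaced on the ERB scale from 141 to
8877 Hz, followed by 10 ms frame RMS, giving 100 Hz envelopes. The
downstream contract is only the 40-band envelope matrix, so any
reasonable cochlear front end slots in here. Bands lying above Nyquist
at low sample rates contribute zero envelopes.

Onsets are the half-wave rectified first difference per band; groups of
8 adjacent bands are averaged to 5. Each band drives 99 two-pole reson
filters,

    y[t] = g·x[t] + 2r·cos(2πf/r_s)·y[t−1] − r²·y[t−2],
    r = exp(−π·f/(Q·r_s)),   Q = 10,   r_s = 100 Hz,

with g set for unit gain at resonance and center frequencies log-spaced
over 0.25–10 Hz. Constant-Q log spacing matches musical periodicity
resolution; the damping is a configurable default, not an empirically
fitted value. Periodicity surfaces are sliding-window RMS (2 s window,
10 ms hop — wide enough to cover a cycle of the slowest peak
periodicities while still tracking change); the mean periodicity profile
averages the five surfaces and then time. Peaks are strict local maxima
above `min + 0.05·range`; plateaus contribute their lowest-frequency
sample. Salience is the mean rectified filter output over the selected
(band, filter) pairs; "amplitude" here is the rectified absolute value
(the analytic envelope is a defensible alternative and the choice is
isolated in one function).

A caution on oracles: a periodic onset train excites *all* its
harmonics with equal line amplitude, so unit-gain resonators at 4, 6, 8
and 10 Hz ring as hard as the 2 Hz one. "The model detects a 2 Hz
rhythm" means the 2 Hz filter is a local peak and the maximum below the
second harmonic, not the global argmax of the bank.

The amplitude-envelope predictor (50 ms sliding RMS, zero-phase
3rd-order Butterworth low-pass at 50 Hz, resampled to 100 Hz) correlates
only moderately with the oscillator salience as a *time series*
(r ≈ 0.2–0.45 across presets): the envelope is spiky and near zero
between onsets while the masked oscillator sum is smooth and
band-limited, so the test suite asserts positive association rather than
a high r. Strong agreement between the two predictors is a statement
about their values at probed event positions, which depends on how
probes are chosen.

## Pupil forward model

The pupillary response function h(t) = t^n·exp(−n·t/t_max) with
n = 10.1 and t_max = 512 ms (non-motor response) peaks analytically at
t_max and is evaluated in log space (t^10.1 overflows float64 within the
3 s window when t is in milliseconds). The kernel is peak-normalized —
no output units are fixed and predictions are z-scored before
comparison — and truncated where the tail falls below 0.1% of peak
(≈ 1.38 s at defaults). The empirical 1300 ms return-to-baseline delay
is carried as metadata only. Prediction tiles one-loop salience,
convolves, discards one full kernel length of transient (continuous
listening is in steady state), and mean-centers.

## Synthetic pupil data

A raw 500 Hz log is the z-scored prediction scaled to 30 arbitrary
units around a 2000 a.u. baseline, plus: (a) 1/f^1.5-shaped noise with
SD 60 a.u. — spontaneous pupil fluctuation (hippus and slower waves)
concentrates at low frequencies and typically exceeds stimulus-entrained
modulation, and representing it as such is what makes weakly driven
harmonics incoherent, as in real recordings; (b) a slow sinusoidal
drift (0.005–0.02 Hz, below the high-pass cutoff); (c) blinks as
100–300 ms missing runs flanked by ±60 a.u. eyelid-sweep spikes and
saccade flags, at 0.05 blinks/s by default. The generator does **not**
emulate luminance responses, gaze-position artifacts, session-scale
fatigue, or trial-to-trial variability of the evoked response itself;
passing tests therefore show that the analysis recovers entrainment
under realistic noise and artifact structure, not that the oscillator
model explains real listeners.

## Preprocessing and evoked responses

Blink/saccade-flagged samples and any sample more than 20 a.u. above its
predecessor are set missing; a ±25-sample (50 ms) pad absorbs edge
artifacts; gaps are linearly interpolated (leading/trailing gaps take
the nearest valid value and are flagged); a trace needing ≥ 30%
interpolation is rejected. The trace is high-passed at 0.05 Hz
(3rd-order Butterworth, applied forward–backward so event-locked
latencies are not delayed) and z-scored. The 20 a.u. jump threshold
refers to the generator's unit scale and is configurable.

Evoked epochs span deviant onset through 3000 ms minus the mean of the
200 ms pre-onset baseline; features are mean and max evoked size,
latency to maximum, and velocity as the deterministic two-point slope
from the onset sample to the maximum (zero when the maximum is at
onset). Features are computed on the z-scored signal. Outlier screening
removes values beyond 3 scaled MADs (1.4826·median |x−median|); if the
MAD is zero while values differ, only exact-median values are kept, with
a warning.

## Entrainment statistics

The pupil is resampled 500→100 Hz (anti-aliased) so Welch bins align
with the model predictions. Coherence uses 4.4 s Hann windows with 75%
overlap (bin spacing ≈ 0.227 Hz); the summary averages coherence at the
nearest bins to the stimulus's MPP peaks below 3 Hz. The null averages
the same quantity against every other stimulus's prediction, each
evaluated at that stimulus's own peaks (a switch selects the
own-stimulus-peaks reading instead, since either reading of the
shuffled null is defensible). Paired t-tests on (true − null) return
t = 0 for exactly identical pairs and raise on a nonzero constant
difference. Δ-AIC is `AIC_i − min(AIC)`, so the best model maps to
exactly 0.

Problem sizes: the test suite and acceptance checks simulate 28-loop
(~63 s) pupil runs, 10 simulated participants for the recovery test, and
200 replicate ZEST runs — sizes at which the binomial scheduling check,
threshold recovery (±1.5 dB) and true-vs-null separation (one-sided
paired t, p < .01) are all stable across seeds.

## Known limitations

- Reson damping, filter spacing and the RMS window are configurable
  defaults; no empirical fit to listeners is claimed.
- The shuffled-stimulus null is weak when stimuli share periodicity
  content; the method cannot distinguish stimuli whose peak sets
  coincide.
- Velocity and latency features are argmax-based and hence sensitive to
  noise at low SNR; no smoothing is applied before feature extraction.
- Mixed-effects / GLMM / ROC model fitting on the exported trial tables
  is out of scope; the per-trial feature CSV is written for external
  statistics packages.
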