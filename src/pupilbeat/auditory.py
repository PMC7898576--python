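"""Linear oscillator (reson filter bank) model of dynamic temporal salience.

The processing chain, applied to a looping rhythmic stimulus:

1. A 40-channel band-pass front end (center frequencies 141-8877 Hz on an
   ERB-like auditory scale) with per-band RMS envelopes at the 100 Hz
   model rate.
2. Onset detection per band: half-wave rectified first-order difference
   of the RMS envelope.
3. Reduction of the 40 onset bands to 5 by averaging adjacent groups of 8.
4. A bank of 99 damped linear oscillators (two-pole reson filters) tuned
   to periodicities between 0.25 and 10 Hz, driven by each of the 5
   bands. Oscillators driven most strongly ring with the largest
   amplitude.
5. Windowed RMS of the reson outputs -> per-band periodicity surfaces ->
   Average Periodicity Surface -> time-averaged Mean Periodicity Profile
   (MPP), whose peaks (local maxima exceeding 5% of the profile's
   amplitude range) are the stimulus's prominent metric periodicities.
6. Temporal salience: the point-wise mean resonator amplitude over the
   peak-frequency filters in all five bands (``peak_masked``), or over
   every filter (``full_reson``); a model-free RMS amplitude envelope of
   the audio is the third predictor variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from pupilbeat.synth import MODEL_RATE_HZ, AudioSignal

N_COCHLEAR_BANDS = 40
N_REDUCED_BANDS = 5
N_RESON_FILTERS = 99
RESON_F_MIN_HZ = 0.25
RESON_F_MAX_HZ = 10.0
FRONT_END_F_MIN_HZ = 141.0
FRONT_END_F_MAX_HZ = 8877.0


@dataclass(frozen=True)
class BandOnsetMatrix:
    """Bands x time matrix at the 100 Hz model rate (nonnegative)."""

    values: np.ndarray
    band_centers_hz: np.ndarray
    rate_hz: float = MODEL_RATE_HZ

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a bands x time matrix")
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "band_centers_hz", np.asarray(self.band_centers_hz, dtype=float)
        )

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ResonBank:
    """99 constant-Q two-pole resonators log-spaced in [0.25, 10] Hz."""

    frequencies_hz: np.ndarray
    q: float = 10.0
    model_rate_hz: float = MODEL_RATE_HZ

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("filter frequencies must be strictly increasing")
        if f[0] < RESON_F_MIN_HZ - 1e-9 or f[-1] > RESON_F_MAX_HZ + 1e-9:
            raise ValueError("filter frequencies must lie within [0.25, 10] Hz")
        object.__setattr__(self, "frequencies_hz", f)

    @classmethod
    def default(cls, model_rate_hz: float = MODEL_RATE_HZ) -> "ResonBank":
        freqs = np.geomspace(RESON_F_MIN_HZ, RESON_F_MAX_HZ, N_RESON_FILTERS)
        return cls(freqs, q=10.0, model_rate_hz=model_rate_hz)


@dataclass(frozen=True)
class PeriodicitySurface:
    """Windowed-RMS energy per (periodicity frequency, time)."""

    energy: np.ndarray  # frequencies x time
    frequencies_hz: np.ndarray
    window_s: float
    hop_s: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.energy) < -1e-12):
            raise ValueError("periodicity energy must be nonnegative")


@dataclass(frozen=True)
class MeanPeriodicityProfile:
    """Time-averaged periodicity energy and its peak set.

    Peaks are strict local maxima of the profile whose value exceeds
    ``min(profile) + 0.05 * (max - min)``; on a plateau the
    lowest-frequency sample is taken.
    """

    profile: np.ndarray
    frequencies_hz: np.ndarray
    peak_mask: np.ndarray
    peak_frequencies_hz: np.ndarray


@dataclass(frozen=True)
class SalienceSeries:
    """Predicted attentional salience over one loop at 100 Hz."""

    values: np.ndarray
    variant: str  # peak_masked | full_reson | amplitude_envelope
    rate_hz: float = MODEL_RATE_HZ
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-12):
            raise ValueError("salience must be nonnegative")
        object.__setattr__(self, "values", np.maximum(v, 0.0))


# ---------------------------------------------------------------------------
# Front end
# ---------------------------------------------------------------------------

def _hz_to_erb_number(f: np.ndarray) -> np.ndarray:
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f, dtype=float))


def _erb_number_to_hz(e: np.ndarray) -> np.ndarray:
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 0.00437


def erb_band_centers(
    f_min: float = FRONT_END_F_MIN_HZ,
    f_max: float = FRONT_END_F_MAX_HZ,
    n_bands: int = N_COCHLEAR_BANDS,
) -> np.ndarray:
    """Band center frequencies equally spaced on the ERB-number scale."""
    return _erb_number_to_hz(
        np.linspace(_hz_to_erb_number(f_min), _hz_to_erb_number(f_max), n_bands)
    )


def cochlear_bands(
    audio: AudioSignal, model_rate_hz: float = MODEL_RATE_HZ
) -> BandOnsetMatrix:
    """40-band RMS envelopes of the audio at the model rate.

    Each channel is a 2nd-order Butterworth band-pass with edges midway
    (in ERB number) between adjacent centers; envelopes are frame RMS
    values over non-overlapping 10 ms frames.
    """
    x = audio.samples
    if x.size == 0:
        raise ValueError("empty audio")
    if audio.sample_rate < 8000:
        raise ValueError("audio sample rate must be >= 8 kHz")
    sr = audio.sample_rate
    centers = erb_band_centers()
    erb = _hz_to_erb_number(centers)
    half = np.diff(erb) / 2.0
    lo_erb = erb - np.concatenate([[half[0]], half])
    hi_erb = erb + np.concatenate([half, [half[-1]]])
    lo = _erb_number_to_hz(lo_erb)
    hi = np.minimum(_erb_number_to_hz(hi_erb), 0.95 * sr / 2.0)

    frame = int(round(sr / model_rate_hz))
    n_frames = x.size // frame
    if n_frames == 0:
        raise ValueError("audio shorter than one model frame")
    env = np.empty((centers.size, n_frames))
    for b in range(centers.size):
        if lo[b] >= hi[b]:
            # band lies above Nyquist at this sample rate: no content
            env[b] = 0.0
            continue
        sos = signal.butter(2, [lo[b], hi[b]], btype="bandpass", fs=sr, output="sos")
        y = signal.sosfilt(sos, x)
        frames = y[: n_frames * frame].reshape(n_frames, frame)
        env[b] = np.sqrt(np.mean(frames**2, axis=1))
    return BandOnsetMatrix(env, centers, model_rate_hz)


def detect_onsets(envelopes: BandOnsetMatrix) -> BandOnsetMatrix:
    """Half-wave rectified first-order difference of each band envelope."""
    d = np.diff(envelopes.values, axis=1, prepend=envelopes.values[:, :1])
    return BandOnsetMatrix(
        np.maximum(d, 0.0), envelopes.band_centers_hz, envelopes.rate_hz
    )


def reduce_bands(
    onsets: BandOnsetMatrix, group_size: int = 8
) -> BandOnsetMatrix:
    """Average adjacent groups of bands (40 -> 5 by default)."""
    n = onsets.n_bands
    if n % group_size != 0:
        raise ValueError(f"{n} bands not divisible by group size {group_size}")
    n_out = n // group_size
    vals = onsets.values.reshape(n_out, group_size, -1).mean(axis=1)
    centers = onsets.band_centers_hz.reshape(n_out, group_size).mean(axis=1)
    return BandOnsetMatrix(vals, centers, onsets.rate_hz)


# ---------------------------------------------------------------------------
# Reson filters
# ---------------------------------------------------------------------------

def _reson_coefficients(
    f_hz: float, q: float, rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """(b, a) of the two-pole resonator with unit gain at resonance.

    y[t] = g*x[t] + 2r*cos(w0)*y[t-1] - r^2*y[t-2], r = exp(-pi*f/(Q*rate)).
    """
    if f_hz >= rate_hz / 2.0:
        raise ValueError("resonance frequency must be below Nyquist")
    if f_hz <= 0 or q <= 0:
        raise ValueError("frequency and Q must be positive")
    w0 = 2.0 * np.pi * f_hz / rate_hz
    r = np.exp(-np.pi * f_hz / (q * rate_hz))
    a = np.array([1.0, -2.0 * r * np.cos(w0), r * r])
    # normalize |H| to 1 at the resonance frequency
    z = np.exp(1j * w0)
    h0 = 1.0 / (a[0] + a[1] / z + a[2] / z**2)
    b = np.array([1.0 / np.abs(h0)])
    return b, a


def reson_filter(
    x: np.ndarray, f_hz: float, q: float = 10.0, model_rate_hz: float = MODEL_RATE_HZ
) -> np.ndarray:
    """Drive a single damped linear oscillator with input ``x``."""
    b, a = _reson_coefficients(f_hz, q, model_rate_hz)
    return signal.lfilter(b, a, np.asarray(x, dtype=float))


def reson_bank_apply(
    onsets: BandOnsetMatrix, bank: Optional[ResonBank] = None
) -> np.ndarray:
    """Apply the 99-filter bank to every band: (bands, filters, time)."""
    if bank is None:
        bank = ResonBank.default(onsets.rate_hz)
    n_bands, n_t = onsets.values.shape
    out = np.empty((n_bands, bank.frequencies_hz.size, n_t))
    for k, f in enumerate(bank.frequencies_hz):
        b, a = _reson_coefficients(f, bank.q, bank.model_rate_hz)
        out[:, k, :] = signal.lfilter(b, a, onsets.values, axis=1)
    return out


# ---------------------------------------------------------------------------
# Periodicity surfaces and the MPP
# ---------------------------------------------------------------------------

def _sliding_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding-window RMS along the last axis (edges reflected)."""
    # clamp: uniform_filter1d can go fractionally negative on tiny values
    return np.sqrt(np.maximum(uniform_filter1d(x**2, size=window, axis=-1, mode="reflect"), 0.0))


def periodicity_surface(
    reson_band: np.ndarray,
    frequencies_hz: np.ndarray,
    window_s: float = 2.0,
    hop_s: float = 0.01,
    rate_hz: float = MODEL_RATE_HZ,
) -> PeriodicitySurface:
    """Windowed RMS of one band's reson outputs (filters x time)."""
    if window_s < hop_s:
        raise ValueError("window must be at least one hop long")
    window = max(int(round(window_s * rate_hz)), 1)
    hop = max(int(round(hop_s * rate_hz)), 1)
    rms = _sliding_rms(np.asarray(reson_band, dtype=float), window)[..., ::hop]
    return PeriodicitySurface(rms, np.asarray(frequencies_hz), window_s, hop_s)


def average_surface(surfaces: Sequence[PeriodicitySurface]) -> PeriodicitySurface:
    """Point-wise mean of per-band periodicity surfaces."""
    if not surfaces:
        raise ValueError("no surfaces to average")
    ref = surfaces[0]
    stack = np.stack([s.energy for s in surfaces])
    return PeriodicitySurface(
        stack.mean(axis=0), ref.frequencies_hz, ref.window_s, ref.hop_s
    )


def mean_periodicity_profile(
    aps: PeriodicitySurface, peak_threshold_fraction: float = 0.05
) -> MeanPeriodicityProfile:
    """Time-average the Average Periodicity Surface and pick its peaks.

    Peaks: strict local maxima whose value exceeds the profile minimum
    plus ``peak_threshold_fraction`` of the profile's amplitude range.
    Plateaus contribute their lowest-frequency sample.
    """
    profile = aps.energy.mean(axis=-1)
    rng = profile.max() - profile.min()
    mask = np.zeros(profile.size, dtype=bool)
    if rng > 0:
        idx, props = signal.find_peaks(profile, plateau_size=1)
        left = props["left_edges"]
        thr = profile.min() + peak_threshold_fraction * rng
        keep = profile[idx] > thr
        mask[left[keep]] = True
    return MeanPeriodicityProfile(
        profile, aps.frequencies_hz, mask, aps.frequencies_hz[mask]
    )


# ---------------------------------------------------------------------------
# Salience predictors
# ---------------------------------------------------------------------------

def temporal_salience(
    reson_out: np.ndarray,
    bank: ResonBank,
    mpp: Optional[MeanPeriodicityProfile] = None,
    variant: str = "peak_masked",
    source: str = "",
) -> SalienceSeries:
    """Mean rectified resonator amplitude over selected (band, filter) pairs.

    ``peak_masked`` averages only the filters at the MPP's peak
    frequencies (across all bands); ``full_reson`` averages every filter.
    """
    if variant not in {"peak_masked", "full_reson"}:
        raise ValueError("variant must be 'peak_masked' or 'full_reson'")
    amp = np.abs(np.asarray(reson_out, dtype=float))
    if variant == "peak_masked":
        if mpp is None or not mpp.peak_mask.any():
            raise ValueError("peak_masked salience requires a nonempty peak set")
        amp = amp[:, mpp.peak_mask, :]
    values = amp.mean(axis=(0, 1))
    return SalienceSeries(values, variant, bank.model_rate_hz, source)


def amplitude_envelope(
    audio: AudioSignal,
    rms_window_ms: float = 50.0,
    lp_cutoff_hz: float = 50.0,
    lp_order: int = 3,
    out_rate_hz: float = MODEL_RATE_HZ,
) -> SalienceSeries:
    """RMS amplitude envelope of the audio, the model-free predictor.

    Sliding 50 ms RMS (the upper envelope), zero-phase 3rd-order
    Butterworth low-pass at 50 Hz, then resampling to the 100 Hz model
    rate.
    """
    sr = audio.sample_rate
    window = int(round(rms_window_ms / 1000.0 * sr))
    if window > audio.samples.size:
        raise ValueError("RMS window longer than the signal")
    env = _sliding_rms(audio.samples, max(window, 1))
    if lp_cutoff_hz < sr / 2.0:
        sos = signal.butter(lp_order, lp_cutoff_hz, btype="lowpass", fs=sr, output="sos")
        env = signal.sosfiltfilt(sos, env)
    up = int(round(out_rate_hz))
    down = int(round(sr))
    from math import gcd

    g = gcd(up, down)
    env = signal.resample_poly(env, up // g, down // g)
    return SalienceSeries(np.maximum(env, 0.0), "amplitude_envelope", out_rate_hz)


# ---------------------------------------------------------------------------
# Convenience: full chain
# ---------------------------------------------------------------------------

def model_salience(
    audio: AudioSignal,
    variant: str = "peak_masked",
    bank: Optional[ResonBank] = None,
    n_warmup_loops: int = 2,
    loop_samples: Optional[int] = None,
    source: str = "",
) -> tuple[SalienceSeries, MeanPeriodicityProfile]:
    """Run the full oscillator chain on (possibly tiled) loop audio.

    ``audio`` should contain at least ``n_warmup_loops + 1`` identical
    loops so the resonators reach steady state; the returned salience
    covers the final loop. ``loop_samples`` is the loop length at the
    model rate (defaults to the full signal, i.e. no trimming).
    """
    if variant == "amplitude_envelope":
        env = amplitude_envelope(audio)
        vals = env.values
        if loop_samples is not None:
            vals = vals[-loop_samples:]
        dummy = mean_periodicity_profile(
            PeriodicitySurface(
                np.zeros((N_RESON_FILTERS, 1)),
                ResonBank.default().frequencies_hz,
                2.0,
                0.01,
            )
        )
        return SalienceSeries(vals, "amplitude_envelope", source=source), dummy
    if bank is None:
        bank = ResonBank.default()
    env40 = cochlear_bands(audio)
    onsets40 = detect_onsets(env40)
    onsets5 = reduce_bands(onsets40)
    reson_out = reson_bank_apply(onsets5, bank)
    surfaces = [
        periodicity_surface(reson_out[b], bank.frequencies_hz)
        for b in range(reson_out.shape[0])
    ]
    mpp = mean_periodicity_profile(average_surface(surfaces))
    sal = temporal_salience(reson_out, bank, mpp, variant, source=source)
    vals = sal.values
    if loop_samples is not None:
        vals = vals[-loop_samples:]
    return SalienceSeries(vals, variant, bank.model_rate_hz, source), mpp
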