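"""Entrainment of the pupil to model predictions: coherence statistics.

Magnitude-squared coherence between the cleaned pupil trace and the
model-predicted pupil signal,

    C(f) = |Pxy(f)|^2 / (Pxx(f) * Pyy(f)),

with all spectra estimated by Welch's method (4.4 s Hann windows, 75%
overlap). The entrainment summary is the coherence averaged over the
stimulus's model-predicted peak periodicities below 3 Hz; the null is
the same quantity computed against the predictions for the *other*
stimuli (each at its own peak frequencies). True-vs-null separation is
assessed with a paired t-test across participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal, stats

from pupilbeat.auditory import MeanPeriodicityProfile
from pupilbeat.synth import MODEL_RATE_HZ

WELCH_WINDOW_S = 4.4
WELCH_OVERLAP = 0.75
PEAK_FREQ_CEILING_HZ = 3.0


@dataclass(frozen=True)
class CoherenceResult:
    """Frequency-resolved coherence between a pupil trace and a prediction."""

    frequencies_hz: np.ndarray
    coherence: np.ndarray
    window_s: float = WELCH_WINDOW_S
    overlap: float = WELCH_OVERLAP
    peak_frequencies_used: tuple[float, ...] = ()
    true_mean_coherence: Optional[float] = None
    null_mean_coherence: Optional[float] = None


def _welch_params(rate_hz: float, window_s: float, overlap: float, n: int):
    nperseg = int(round(window_s * rate_hz))
    if n < nperseg:
        raise ValueError("signal shorter than one Welch window")
    return nperseg, int(round(overlap * nperseg))


def resample_to_model_rate(
    x: np.ndarray, rate_hz: float, target_hz: float = MODEL_RATE_HZ
) -> np.ndarray:
    """Anti-aliased resampling (500 Hz pupil -> 100 Hz model rate).

    Cross-spectral comparison needs both signals on one grid; the model
    runs at 100 Hz, so the pupil is decimated with resample_poly's
    built-in low-pass.
    """
    from math import gcd

    up, down = int(round(target_hz)), int(round(rate_hz))
    g = gcd(up, down)
    return signal.resample_poly(np.asarray(x, dtype=float), up // g, down // g)


def welch_psd(
    x: np.ndarray,
    rate_hz: float = MODEL_RATE_HZ,
    window_s: float = WELCH_WINDOW_S,
    overlap: float = WELCH_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (Hann window). Returns (f, Pxx)."""
    x = np.asarray(x, dtype=float)
    nperseg, noverlap = _welch_params(rate_hz, window_s, overlap, x.size)
    return signal.welch(x, fs=rate_hz, window="hann", nperseg=nperseg, noverlap=noverlap)


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate_hz: float = MODEL_RATE_HZ,
    window_s: float = WELCH_WINDOW_S,
    overlap: float = WELCH_OVERLAP,
) -> CoherenceResult:
    """Magnitude-squared coherence |Pxy|^2 / (Pxx * Pyy) on a Welch grid.

    Bins where either auto-spectrum is zero are undefined and returned as
    NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    nperseg, noverlap = _welch_params(rate_hz, window_s, overlap, x.size)
    f, pxy = signal.csd(x, y, fs=rate_hz, window="hann", nperseg=nperseg, noverlap=noverlap)
    _, pxx = signal.welch(x, fs=rate_hz, window="hann", nperseg=nperseg, noverlap=noverlap)
    _, pyy = signal.welch(y, fs=rate_hz, window="hann", nperseg=nperseg, noverlap=noverlap)
    denom = pxx * pyy
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(pxy) ** 2 / denom
    c = np.where(denom > 0, c, np.nan)
    return CoherenceResult(f, np.clip(c, 0.0, 1.0), window_s, overlap)


def peak_band_coherence(
    coh: CoherenceResult,
    mpp: MeanPeriodicityProfile,
    freq_ceiling_hz: float = PEAK_FREQ_CEILING_HZ,
) -> float:
    """Mean coherence at the model-predicted peak frequencies below 3 Hz.

    Each peak frequency is matched to the nearest Welch bin.
    """
    peaks = np.asarray(mpp.peak_frequencies_hz, dtype=float)
    peaks = peaks[peaks < freq_ceiling_hz]
    if peaks.size == 0:
        raise ValueError("no model-predicted peak frequencies below the ceiling")
    idx = np.array([int(np.argmin(np.abs(coh.frequencies_hz - p))) for p in peaks])
    return float(np.nanmean(coh.coherence[idx]))


def null_coherence(
    pupil: np.ndarray,
    predictions: Mapping[str, np.ndarray],
    mpps: Mapping[str, MeanPeriodicityProfile],
    own_stimulus_id: str,
    rate_hz: float = MODEL_RATE_HZ,
    window_s: float = WELCH_WINDOW_S,
    overlap: float = WELCH_OVERLAP,
    use_other_peaks: bool = True,
) -> float:
    """Mean peak-band coherence of the pupil against every *other* stimulus.

    The null distribution of coherence estimates: the pupil trace is
    compared with the model prediction for each stimulus other than its
    own. By default each comparison is evaluated at the other stimulus's
    own peak frequencies; ``use_other_peaks=False`` evaluates every
    comparison at the pupil's own stimulus's peaks instead.
    """
    others = [s for s in predictions if s != own_stimulus_id]
    if not others:
        raise ValueError("need at least one other stimulus for the null")
    vals = []
    for s in others:
        pred = np.asarray(predictions[s], dtype=float)
        n = min(pupil.size, pred.size)
        coh = coherence(pupil[:n], pred[:n], rate_hz, window_s, overlap)
        mpp = mpps[s] if use_other_peaks else mpps[own_stimulus_id]
        vals.append(peak_band_coherence(coh, mpp))
    return float(np.mean(vals))


def true_and_null_coherence(
    pupil: np.ndarray,
    predictions: Mapping[str, np.ndarray],
    mpps: Mapping[str, MeanPeriodicityProfile],
    own_stimulus_id: str,
    rate_hz: float = MODEL_RATE_HZ,
    **kwargs,
) -> CoherenceResult:
    """Per-run true and null coherence summaries for one pupil trace."""
    pred = np.asarray(predictions[own_stimulus_id], dtype=float)
    n = min(pupil.size, pred.size)
    coh = coherence(pupil[:n], pred[:n], rate_hz)
    mpp = mpps[own_stimulus_id]
    true_val = peak_band_coherence(coh, mpp)
    null_val = null_coherence(
        pupil, predictions, mpps, own_stimulus_id, rate_hz, **kwargs
    )
    peaks = tuple(
        float(p) for p in mpp.peak_frequencies_hz if p < PEAK_FREQ_CEILING_HZ
    )
    return CoherenceResult(
        coh.frequencies_hz, coh.coherence, coh.window_s, coh.overlap,
        peaks, true_val, null_val,
    )


def paired_true_null_test(
    true_values: Sequence[float],
    null_values: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, int, float]:
    """Paired t-test on (true - null). Returns (t, df, p)."""
    t_arr = np.asarray(true_values, dtype=float)
    n_arr = np.asarray(null_values, dtype=float)
    if t_arr.size != n_arr.size:
        raise ValueError("paired samples must have equal length")
    if t_arr.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = t_arr - n_arr
    if np.var(diffs) == 0:
        if np.all(diffs == 0):  # identical pairs: no effect, t is exactly 0
            return 0.0, int(t_arr.size - 1), 1.0
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(t_arr, n_arr, alternative=alternative)
    return float(res.statistic), int(t_arr.size - 1), float(res.pvalue)


def delta_aic(aic_values: Sequence[float]) -> np.ndarray:
    """Rescale AIC values to information lost relative to the best model.

    delta_i = AIC_i - AIC_min; the best model maps to exactly 0.
    """
    a = np.asarray(aic_values, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 AIC values")
    if not np.all(np.isfinite(a)):
        raise ValueError("AIC values must be finite")
    return a - a.min()


def loop_epoch_average(
    pupil: np.ndarray,
    loop_onsets_s: Sequence[float],
    rate_hz: float,
    loops_per_epoch: int = 8,
    psd_window_s: Optional[float] = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Average the pupil over consecutive 8-loop epochs; PSD of the average.

    The trace is segmented at every ``loops_per_epoch``-th loop onset;
    complete epochs are averaged point-wise. The PSD of the averaged
    epoch uses one window spanning the epoch unless ``psd_window_s``
    overrides it.
    """
    x = np.asarray(pupil, dtype=float)
    onsets = np.asarray(loop_onsets_s, dtype=float)
    if onsets.size < loops_per_epoch + 1:
        raise ValueError("need at least one complete epoch of loop onsets")
    loop_len = int(round((onsets[1] - onsets[0]) * rate_hz))
    epoch_len = loop_len * loops_per_epoch
    starts = [int(round(t * rate_hz)) for t in onsets[::loops_per_epoch]]
    segs = [x[s : s + epoch_len] for s in starts if s + epoch_len <= x.size]
    if len(segs) < 1:
        raise ValueError("fewer than one complete epoch in the trace")
    avg = np.mean(np.stack(segs), axis=0)
    win = psd_window_s if psd_window_s is not None else epoch_len / rate_hz
    f, p = welch_psd(avg, rate_hz, window_s=win, overlap=0.0)
    return avg, (f, p)
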