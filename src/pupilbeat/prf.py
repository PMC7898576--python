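"""Forward prediction of the continuous pupil signal.

Attentional salience is convolved with a canonical pupillary response
function (PRF), the Erlang gamma kernel

    h(t) = t**n * exp(-n * t / t_max)

with n = 10.1 neural signalling steps and, for the non-motor response to
suprathreshold auditory events, a peak latency t_max = 512 ms. The kernel
attains its unique maximum exactly at t_max (dh/dt = 0 there) and is
peak-normalized, since predictions are z-scored before any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from pupilbeat.auditory import SalienceSeries
from pupilbeat.synth import MODEL_RATE_HZ

DEFAULT_N = 10.1
DEFAULT_T_MAX_MS = 512.0
#: empirically reported pupil return-to-baseline delay; metadata only —
#: the kernel is truncated where it decays below 0.1% of peak instead.
RETURN_TO_BASELINE_MS = 1300.0


@dataclass(frozen=True)
class PRFKernel:
    """Sampled Erlang-gamma pupillary response function, peak = 1."""

    samples: np.ndarray
    rate_hz: float
    n: float
    t_max_ms: float
    truncation_ms: float
    return_to_baseline_ms: float = RETURN_TO_BASELINE_MS

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * 1000.0 / self.rate_hz

    @property
    def peak_time_ms(self) -> float:
        """Time of the sampled maximum (t_max on any grid containing it)."""
        return float(np.argmax(self.samples) * 1000.0 / self.rate_hz)


def erlang_gamma(t_ms: np.ndarray, n: float = DEFAULT_N, t_max_ms: float = DEFAULT_T_MAX_MS) -> np.ndarray:
    """Evaluate the unnormalized kernel h(t) = t^n exp(-n t / t_max).

    Computed in log space: t^10.1 overflows float64 well before 3 s when t
    is in milliseconds.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    log_h = n * np.log(t[pos]) - n * t[pos] / t_max_ms
    log_peak = n * np.log(t_max_ms) - n
    out[pos] = np.exp(log_h - log_peak)  # peak value 1 at t = t_max
    return out


def prf_kernel(
    n: float = DEFAULT_N,
    t_max_ms: float = DEFAULT_T_MAX_MS,
    rate_hz: float = MODEL_RATE_HZ,
    truncation_ms: float | None = None,
    tail_fraction: float = 1e-3,
) -> PRFKernel:
    """Build the sampled PRF at ``rate_hz``.

    The kernel is truncated where the tail falls below ``tail_fraction``
    of the peak (about 3.5 s at defaults) unless ``truncation_ms`` is
    given explicitly; truncating earlier than the peak is an error.
    """
    if n <= 0 or t_max_ms <= 0:
        raise ValueError("n and t_max must be positive")
    if truncation_ms is None:
        # march past the peak until the tail is negligible
        t_ms = t_max_ms
        step = 1000.0 / rate_hz
        while erlang_gamma(np.array([t_ms]), n, t_max_ms)[0] > tail_fraction:
            t_ms += step
        truncation_ms = t_ms
    if truncation_ms < t_max_ms:
        raise ValueError("truncation must not precede the kernel peak")
    t = np.arange(0.0, truncation_ms + 1e-9, 1000.0 / rate_hz)
    h = erlang_gamma(t, n, t_max_ms)
    h /= h.max()
    return PRFKernel(h, rate_hz, n, t_max_ms, float(truncation_ms))


@dataclass(frozen=True)
class PredictedPupil:
    """Predicted continuous pupil signal at the model rate, mean-centered."""

    values: np.ndarray
    rate_hz: float
    n_loops: int
    variant: str
    transient_discard_s: float


def predict_pupil(
    salience: SalienceSeries, prf: PRFKernel, n_loops: int = 8
) -> PredictedPupil:
    """Tile one-loop salience, convolve with the PRF, discard the transient.

    The first kernel-length of the convolution output is discarded (the
    oscillating listener has been hearing the loop continuously), then the
    final ``n_loops`` loops are kept and mean-centered.
    """
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    if abs(salience.rate_hz - prf.rate_hz) > 1e-9:
        raise ValueError("salience and PRF must share a sample rate")
    loop_n = salience.values.size
    discard = prf.samples.size
    n_warm = int(np.ceil(discard / loop_n)) + 1
    tiled = np.tile(salience.values, n_loops + n_warm)
    conv = signal.fftconvolve(tiled, prf.samples, mode="full")[: tiled.size]
    out = conv[-n_loops * loop_n :]
    out = out - out.mean()
    return PredictedPupil(
        out, salience.rate_hz, n_loops, salience.variant, discard / salience.rate_hz
    )


def prediction_spectrum(
    pred: PredictedPupil, window_s: float = 4.4, overlap: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of the predicted pupil signal."""
    from pupilbeat.entrainment import welch_psd

    return welch_psd(pred.values, rate_hz=pred.rate_hz, window_s=window_s, overlap=overlap)
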