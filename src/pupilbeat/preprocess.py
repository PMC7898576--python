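"""Pupil preprocessing and evoked pupil-dilation-response extraction.

Cleaning rules, applied to a raw 500 Hz log:

1. Samples flagged as blink or saccade are set missing, as is any sample
   more than 20 arbitrary units above the preceding sample; a 25-sample
   (50 ms) pad around every missing run removes edge artifacts.
2. Missing data are linearly interpolated; a run needing 30% or more
   interpolation is rejected.
3. The trace is high-pass filtered at 0.05 Hz (3rd-order Butterworth,
   zero phase) to remove slow drift, then z-scored.

The pupil dilation response (PDR) to a deviant is the 0-3000 ms
post-onset trace minus the mean of a 200 ms pre-onset baseline; features
are the mean and max evoked size, the latency to maximum, and the
velocity (two-point slope from onset to maximum). Outlier screening uses
the scaled-MAD rule (remove values beyond 3 scaled median absolute
deviations from the median).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import binary_dilation

from pupilbeat.synth import PUPIL_RATE_HZ, RawPupilLog

JUMP_THRESHOLD_AU = 20.0
PAD_SAMPLES = 25
MAX_INTERP_FRACTION = 0.30
HIGHPASS_CUTOFF_HZ = 0.05
HIGHPASS_ORDER = 3
BASELINE_MS = 200.0
EPOCH_MS = 3000.0
MAD_SCALE = 1.4826  # consistency factor for Gaussian data


@dataclass
class CleanPupilTrace:
    """A cleaned pupil trace with interpolation bookkeeping."""

    values: np.ndarray
    rate_hz: float
    interpolated_mask: np.ndarray
    fraction_interpolated: float
    stage: str  # interpolated | highpassed | zscored
    rejected: bool = False
    edge_filled: bool = False  # leading/trailing gap filled by nearest value


def mark_artifacts(
    raw: RawPupilLog,
    jump_threshold: float = JUMP_THRESHOLD_AU,
    pad_samples: int = PAD_SAMPLES,
) -> np.ndarray:
    """Set artifact samples to NaN and pad around every missing run.

    Marks blink- and saccade-flagged samples and any sample more than
    ``jump_threshold`` arbitrary units above its predecessor, then
    dilates the missing mask by ``pad_samples`` on each side.
    """
    x = np.asarray(raw.pupil, dtype=float).copy()
    bad = np.isnan(x) | np.asarray(raw.blink, bool) | np.asarray(raw.saccade, bool)
    jump = np.zeros_like(bad)
    jump[1:] = np.diff(x) > jump_threshold
    bad |= jump & ~np.isnan(x)
    if pad_samples > 0:
        bad = binary_dilation(bad, np.ones(2 * pad_samples + 1, dtype=bool))
    x[bad] = np.nan
    return x


def interpolate_and_screen(
    masked: np.ndarray,
    rate_hz: float = PUPIL_RATE_HZ,
    max_fraction: float = MAX_INTERP_FRACTION,
) -> CleanPupilTrace:
    """Linearly interpolate missing runs; reject if >= 30% needs filling.

    Leading/trailing gaps cannot be interpolated and are filled with the
    nearest valid value (flagged via ``edge_filled``). The returned trace
    always carries the interpolated fraction; ``rejected`` is True when
    it meets the rejection threshold.
    """
    x = np.asarray(masked, dtype=float)
    missing = np.isnan(x)
    frac = float(np.mean(missing))
    if not missing.any():
        return CleanPupilTrace(x.copy(), rate_hz, missing, 0.0, "interpolated")
    if missing.all():
        raise ValueError("trace contains no valid samples")
    idx = np.arange(x.size)
    valid = ~missing
    filled = np.interp(idx, idx[valid], x[valid])  # np.interp clamps at the edges
    edge_filled = bool(missing[0] or missing[-1])
    return CleanPupilTrace(
        filled, rate_hz, missing, frac, "interpolated",
        rejected=frac >= max_fraction, edge_filled=edge_filled,
    )


def highpass_and_zscore(
    trace: CleanPupilTrace,
    cutoff_hz: float = HIGHPASS_CUTOFF_HZ,
    order: int = HIGHPASS_ORDER,
) -> CleanPupilTrace:
    """Remove slow drift (zero-phase Butterworth high-pass), then z-score."""
    x = trace.values
    if np.std(x) == 0:
        raise ValueError("zero-variance trace cannot be z-scored")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=trace.rate_hz, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = np.std(y)
    if sd == 0:
        raise ValueError("zero-variance trace after high-pass")
    z = (y - np.mean(y)) / sd
    return CleanPupilTrace(
        z, trace.rate_hz, trace.interpolated_mask, trace.fraction_interpolated,
        "zscored", trace.rejected, trace.edge_filled,
    )


def zscore(values: np.ndarray) -> np.ndarray:
    """(x - mean(x)) / std(x)."""
    sd = np.std(values)
    if sd == 0:
        raise ValueError("zero-variance input")
    return (values - np.mean(values)) / sd


@dataclass(frozen=True)
class PDRFeatures:
    """Scalar features of one evoked pupil-dilation-response epoch."""

    baseline_mean: float
    mean_evoked: float
    max_evoked: float
    latency_to_max_ms: float
    velocity_per_s: float  # two-point slope, onset sample -> epoch maximum


@dataclass(frozen=True)
class PDREpoch:
    """Baseline-corrected 0-3000 ms epoch around one deviant onset."""

    trial_id: int
    trial_kind: str  # hit | miss | no_deviant
    samples: np.ndarray
    rate_hz: float
    features: PDRFeatures


def _epoch_features(epoch: np.ndarray, rate_hz: float, baseline_mean: float) -> PDRFeatures:
    i_max = int(np.argmax(epoch))
    latency_ms = i_max * 1000.0 / rate_hz
    if i_max == 0:
        velocity = 0.0  # maximum at onset: zero-length rise
    else:
        velocity = (epoch[i_max] - epoch[0]) / (latency_ms / 1000.0)
    return PDRFeatures(
        baseline_mean=float(baseline_mean),
        mean_evoked=float(np.mean(epoch)),
        max_evoked=float(np.max(epoch)),
        latency_to_max_ms=float(latency_ms),
        velocity_per_s=float(velocity),
    )


def epoch_pdr(
    trace: CleanPupilTrace,
    event_times_s,
    trial_kinds=None,
    baseline_ms: float = BASELINE_MS,
    epoch_ms: float = EPOCH_MS,
) -> list[PDREpoch]:
    """Extract baseline-corrected evoked epochs and their features.

    Each epoch spans onset through ``epoch_ms`` (3000 ms); the mean of the
    ``baseline_ms`` (200 ms) window preceding onset is subtracted.
    """
    x = trace.values
    rate = trace.rate_hz
    n_base = int(round(baseline_ms / 1000.0 * rate))
    n_epoch = int(round(epoch_ms / 1000.0 * rate))
    event_times_s = np.asarray(event_times_s, dtype=float)
    if trial_kinds is None:
        trial_kinds = ["deviant"] * event_times_s.size
    epochs = []
    for i, (t0, kind) in enumerate(zip(event_times_s, trial_kinds)):
        onset = int(round(t0 * rate))
        if onset - n_base < 0 or onset + n_epoch > x.size:
            raise ValueError(f"event at {t0:.3f}s too close to the trace edge")
        baseline = float(np.mean(x[onset - n_base : onset]))
        seg = x[onset : onset + n_epoch] - baseline
        epochs.append(PDREpoch(i, str(kind), seg, rate, _epoch_features(seg, rate, baseline)))
    return epochs


def pdr_feature_table(epochs: list[PDREpoch]) -> pd.DataFrame:
    """Tidy per-trial feature table for external statistics."""
    return pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in epochs],
            "trial_kind": [e.trial_kind for e in epochs],
            "baseline": [e.features.baseline_mean for e in epochs],
            "mean_evoked": [e.features.mean_evoked for e in epochs],
            "max_evoked": [e.features.max_evoked for e in epochs],
            "latency_to_max_ms": [e.features.latency_to_max_ms for e in epochs],
            "velocity_per_s": [e.features.velocity_per_s for e in epochs],
        }
    )


def mad_outlier_filter(values, k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Remove values beyond ``k`` scaled MADs from the median.

    Returns (kept values, removed indices). The scaled MAD is
    ``1.4826 * median(|x - median(x)|)``. If the MAD is zero while the
    values differ, only exact-median values are kept (with a warning).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    if mad == 0:
        if np.all(x == med):
            return x.copy(), np.array([], dtype=int)
        warnings.warn("zero MAD with non-identical values; keeping exact-median only")
        keep = x == med
    else:
        keep = np.abs(x - med) <= k * mad
    return x[keep], np.flatnonzero(~keep)
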