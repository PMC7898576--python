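"""Synthetic stimuli, deviant schedules, and raw pupil logs.

Everything downstream of this module (oscillator model, ZEST simulation,
pupil preprocessing, entrainment statistics) is exercised on data produced
here: short percussion loops on a 16-position onset grid at 107 BPM, loop
schedules with dB-SPL increment deviants, and 500 Hz eye-tracker-style
pupil logs with blinks, drift, and broadband noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

if TYPE_CHECKING:  # pragma: no cover
    from pupilbeat.auditory import SalienceSeries
    from pupilbeat.prf import PRFKernel

MODEL_RATE_HZ = 100.0
PUPIL_RATE_HZ = 500.0

# Burst parameters per synthetic timbre: (center_hz, bandwidth_hz, decay_s).
# Spectral centroids are chosen to drive distinct regions of a 40-band
# cochlear front end: a snap-like mid burst, a shaker-like high hiss, and a
# conga-like low thump.
TIMBRES = {
    "snap": (2000.0, 1500.0, 0.030),
    "shaker": (6000.0, 3000.0, 0.015),
    "conga": (200.0, 150.0, 0.080),
}


@dataclass(frozen=True)
class Track:
    """One instrument line of a rhythm pattern."""

    timbre: str
    mask: np.ndarray  # boolean, length n_positions
    velocity: np.ndarray  # float in (0, 1], length n_positions (0 off-onset)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        vel = np.asarray(self.velocity, dtype=float)
        if mask.shape != vel.shape:
            raise ValueError("mask and velocity must have equal length")
        if np.any(vel[mask] <= 0) or np.any(vel[mask] > 1):
            raise ValueError("onset velocities must lie in (0, 1]")
        if self.timbre not in TIMBRES:
            raise ValueError(f"unknown timbre {self.timbre!r}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "velocity", vel)


@dataclass(frozen=True)
class RhythmPattern:
    """A looping rhythm: onset masks per timbre on a metrical grid.

    The grid divides ``beats_per_loop`` beats into ``n_positions`` equal
    slots; at 107 BPM with 16 positions over 4 beats each slot lasts
    ~140 ms and the loop ~2.2 s.
    """

    tracks: tuple[Track, ...]
    n_positions: int = 16
    tempo_bpm: float = 107.0
    beats_per_loop: int = 4
    name: str = ""

    def __post_init__(self) -> None:
        if self.tempo_bpm <= 0:
            raise ValueError("tempo must be positive")
        if self.n_positions < 1 or self.beats_per_loop < 1:
            raise ValueError("grid must have positive size")
        if not self.tracks:
            raise ValueError("pattern must contain at least one track")
        for tr in self.tracks:
            if tr.mask.size != self.n_positions:
                raise ValueError("track mask length must equal n_positions")
        if not any(tr.mask.any() for tr in self.tracks):
            raise ValueError("pattern must contain at least one onset")

    @property
    def grid_interval_s(self) -> float:
        """Duration of one grid slot in seconds."""
        return 60.0 / (self.tempo_bpm * self.n_positions / self.beats_per_loop)

    @property
    def loop_duration_s(self) -> float:
        return self.grid_interval_s * self.n_positions

    def tiled(self, k: int) -> "RhythmPattern":
        """Pattern repeated k times on a k-fold longer grid."""
        if k < 1:
            raise ValueError("k must be >= 1")
        tracks = tuple(
            Track(tr.timbre, np.tile(tr.mask, k), np.tile(tr.velocity, k))
            for tr in self.tracks
        )
        return RhythmPattern(
            tracks, self.n_positions * k, self.tempo_bpm, self.beats_per_loop * k,
            name=f"{self.name}x{k}" if self.name else "",
        )


@dataclass(frozen=True)
class AudioSignal:
    """Sampled mono waveform."""

    samples: np.ndarray
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("audio samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class LoopRecord:
    loop_index: int
    kind: str  # "standard" | "deviant"
    probe_position: Optional[int] = None
    level_db: Optional[float] = None


@dataclass(frozen=True)
class DeviantSchedule:
    """Ordered loop sequence implementing the deviant-scheduling rule.

    After every standard loop there is a ``p_deviant`` chance the next loop
    carries a deviant at one of four probed grid positions, cycled without
    replacement; after every deviant loop the next loop is standard.
    """

    loop_sequence: tuple[LoopRecord, ...]
    probe_positions: tuple[int, ...]
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loop_index": [r.loop_index for r in self.loop_sequence],
                "kind": [r.kind for r in self.loop_sequence],
                "probe_position": [r.probe_position for r in self.loop_sequence],
                "level_db": [r.level_db for r in self.loop_sequence],
            }
        )

    @property
    def n_deviants(self) -> int:
        return sum(1 for r in self.loop_sequence if r.kind == "deviant")


@dataclass
class RawPupilLog:
    """A raw 500 Hz eye-tracker log: pupil size in arbitrary units.

    ``pupil`` is NaN within blink segments; ``blink``/``saccade`` are
    per-sample flags; ``events`` maps marker labels to onset times (s).
    """

    time_ms: np.ndarray
    pupil: np.ndarray
    blink: np.ndarray
    saccade: np.ndarray
    sample_rate: float = PUPIL_RATE_HZ
    events: dict = field(default_factory=dict)
    seed: Optional[int] = None
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        event_col = np.array([""] * self.time_ms.size, dtype=object)
        for label, times in self.events.items():
            idx = np.round(np.asarray(times) * self.sample_rate).astype(int)
            idx = idx[(idx >= 0) & (idx < event_col.size)]
            for i in idx:
                event_col[i] = label if event_col[i] == "" else event_col[i] + "|" + label
        return pd.DataFrame(
            {
                "time_ms": self.time_ms,
                "pupil": self.pupil,
                "blink": self.blink.astype(int),
                "saccade": self.saccade.astype(int),
                "event": event_col,
            }
        )


# ---------------------------------------------------------------------------
# Pattern presets
# ---------------------------------------------------------------------------

def _preset_specs() -> dict:
    """Five generic 16-grid presets spanning sparse to dense onset profiles.

    Strings mark onsets per grid slot: '.' rest, digits 1-9 velocity/9.
    """
    return {
        # four-on-the-floor low drum + offbeat shaker
        "sparse": {
            "conga": "9...9...9...9...",
            "shaker": "..4...4...4...4.",
        },
        # repeats every half loop: periodicity energy at even loop harmonics
        "halftime": {
            "conga": "9....9..9....9..",
            "snap": "..7.......7.....",
            "shaker": "4.4.4.4.4.4.4.4.",
        },
        # emulates a multi-timbre pattern with moderate syncopation
        "complex1-like": {
            "conga": "9..6..9...9..6..",
            "snap": "....8......8....",
            "shaker": "4.4.4.4.4.4.4.4.",
        },
        # heavily syncopated, off-grid accents
        "syncopated": {
            "conga": ".7..9..7...9..7.",
            "snap": "..6.....6.....6.",
            "shaker": "4..4..4..4..4..4",
        },
        # dense sixteenth-note texture
        "dense": {
            "shaker": "6565656565656565",
            "snap": "....9...8...9..7",
            "conga": "9..7..9..7..9..7",
        },
    }


PRESET_NAMES = tuple(_preset_specs().keys())


def _tracks_from_strings(spec: dict) -> tuple[Track, ...]:
    tracks = []
    for timbre, pat in spec.items():
        mask = np.array([c != "." for c in pat])
        vel = np.array([int(c) / 9.0 if c != "." else 0.0 for c in pat])
        tracks.append(Track(timbre, mask, vel))
    return tuple(tracks)


def make_pattern(
    preset_or_spec,
    seed: int = 0,
    tempo_bpm: float = 107.0,
    n_positions: int = 16,
    beats_per_loop: int = 4,
) -> RhythmPattern:
    """Build a :class:`RhythmPattern` from a named preset or explicit spec.

    Parameters
    ----------
    preset_or_spec
        Either one of ``PRESET_NAMES`` or a dict mapping timbre name to an
        onset string ('.' = rest, '1'-'9' = onset velocity/9).
    seed
        Reserved for randomized pattern generation; presets are
        deterministic and ignore it.
    """
    if isinstance(preset_or_spec, str):
        presets = _preset_specs()
        if preset_or_spec not in presets:
            raise KeyError(
                f"unknown preset {preset_or_spec!r}; available: {sorted(presets)}"
            )
        spec = presets[preset_or_spec]
        name = preset_or_spec
    elif isinstance(preset_or_spec, dict):
        if not preset_or_spec:
            raise ValueError("empty pattern spec")
        spec = preset_or_spec
        name = "custom"
    else:
        raise TypeError("preset_or_spec must be a preset name or a dict")
    tracks = _tracks_from_strings(spec)
    return RhythmPattern(tracks, n_positions, tempo_bpm, beats_per_loop, name=name)


# ---------------------------------------------------------------------------
# Audio rendering
# ---------------------------------------------------------------------------

def _timbre_burst(timbre: str, sample_rate: float, seed: int) -> np.ndarray:
    """Exponentially decaying band-limited noise burst for one timbre.

    The waveform is a fixed function of (timbre, sample_rate, seed) so that
    rendering is deterministic and every onset of a timbre is identical.
    """
    center, bw, decay = TIMBRES[timbre]
    timbre_index = sorted(TIMBRES).index(timbre)  # stable across processes
    rng = np.random.default_rng(np.random.SeedSequence([seed, timbre_index]))
    n = int(round(5 * decay * sample_rate))  # ~5 time constants
    noise = rng.standard_normal(n)
    nyq = sample_rate / 2.0
    hi = min(center + bw / 2.0, 0.95 * nyq) / nyq
    # at low sample rates a high-centered timbre folds down to the widest
    # realizable band below Nyquist
    lo = min(max(center - bw / 2.0, 20.0) / nyq, 0.8 * hi)
    sos = signal.butter(2, [lo, hi], btype="bandpass", output="sos")
    burst = signal.sosfilt(sos, noise)
    t = np.arange(n) / sample_rate
    burst *= np.exp(-t / decay)
    # 1 ms linear fade-in avoids a broadband click at onset
    n_fade = max(int(0.001 * sample_rate), 1)
    burst[:n_fade] *= np.linspace(0.0, 1.0, n_fade)
    peak = np.max(np.abs(burst))
    return burst / peak if peak > 0 else burst


def render_loop(
    pattern: RhythmPattern,
    sample_rate: float = 44100.0,
    seed: int = 0,
    headroom: float = 0.9,
) -> AudioSignal:
    """Render one loop of a pattern as audio.

    Bursts wrap circularly past the loop end, so the loop is seamless:
    concatenating k rendered loops is sample-identical to rendering
    ``pattern.tiled(k)``.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    n_total = int(round(pattern.loop_duration_s * sample_rate))
    out = np.zeros(n_total)
    grid = pattern.grid_interval_s
    for tr in pattern.tracks:
        burst = _timbre_burst(tr.timbre, sample_rate, seed)
        if burst.size > n_total:
            raise ValueError("timbre burst longer than loop")
        for pos in np.flatnonzero(tr.mask):
            start = int(round(pos * grid * sample_rate))
            idx = (start + np.arange(burst.size)) % n_total
            out[idx] += tr.velocity[pos] * burst
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= headroom / peak
    return AudioSignal(out, sample_rate)


def insert_deviant(
    loop_audio: AudioSignal,
    probe_time_s: float,
    duration_ms: float = 200.0,
    delta_db: float = 0.0,
) -> AudioSignal:
    """Apply a dB intensity increment to a 200 ms window of the loop.

    Samples inside [probe_time, probe_time + duration] are scaled by
    ``10**(delta_db/20)``; every other sample is bit-identical to the
    input. The window must not wrap past the loop end.
    """
    if delta_db < 0:
        raise ValueError("delta_db must be >= 0")
    sr = loop_audio.sample_rate
    start = int(round(probe_time_s * sr))
    n_dev = int(round(duration_ms / 1000.0 * sr))
    if start < 0 or start + n_dev > loop_audio.samples.size:
        raise ValueError("deviant window exceeds loop bounds (no wrap-around)")
    out = loop_audio.samples.copy()
    out[start : start + n_dev] *= 10.0 ** (delta_db / 20.0)
    return AudioSignal(out, sr)


# ---------------------------------------------------------------------------
# Deviant scheduling
# ---------------------------------------------------------------------------

def schedule_run(
    n_observations_per_position: int = 20,
    p_deviant: float = 0.8,
    probe_positions: Sequence[int] = (0, 4, 8, 12),
    seed: int = 0,
    max_loops: Optional[int] = None,
) -> DeviantSchedule:
    """Generate a loop schedule until every probed position has its quota.

    The rule: after a standard loop the next loop is a deviant with
    probability ``p_deviant``; after a deviant loop the next loop is always
    standard. Probe positions are drawn without replacement in shuffled
    blocks over the positions still below quota.
    """
    probe_positions = tuple(int(p) for p in probe_positions)
    if len(set(probe_positions)) != len(probe_positions):
        raise ValueError("probe positions must be distinct")
    if not 0.0 <= p_deviant <= 1.0:
        raise ValueError("p_deviant must lie in [0, 1]")
    if n_observations_per_position < 1:
        raise ValueError("n_observations_per_position must be >= 1")
    rng = np.random.default_rng(seed)
    remaining = {p: n_observations_per_position for p in probe_positions}
    bag: list[int] = []
    records: list[LoopRecord] = []
    i = 0
    # first loop is always standard; schedule ends once quotas are filled
    records.append(LoopRecord(i, "standard"))
    while any(v > 0 for v in remaining.values()):
        i += 1
        if max_loops is not None and i >= max_loops:
            break
        prev = records[-1]
        if prev.kind == "standard" and rng.random() < p_deviant:
            bag = [p for p in bag if remaining[p] > 0]
            if not bag:
                bag = [p for p in probe_positions if remaining[p] > 0]
                rng.shuffle(bag)
            pos = bag.pop()
            remaining[pos] -= 1
            records.append(LoopRecord(i, "deviant", probe_position=pos))
        else:
            records.append(LoopRecord(i, "standard"))
    return DeviantSchedule(tuple(records), probe_positions, seed)


def deviant_after_standard_rate(schedule: DeviantSchedule) -> float:
    """Fraction of standard loops immediately followed by a deviant loop.

    The last loop of the sequence has no follower and is excluded.
    """
    kinds = [r.kind for r in schedule.loop_sequence]
    n_std = 0
    n_followed = 0
    for a, b in zip(kinds[:-1], kinds[1:]):
        if a == "standard":
            n_std += 1
            if b == "deviant":
                n_followed += 1
    if n_std == 0:
        raise ValueError("schedule contains no followed standard loop")
    return n_followed / n_std


# ---------------------------------------------------------------------------
# Pupil synthesis
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rate_hz: float, rng: np.random.Generator,
                exponent: float = 1.5, f_floor_hz: float = 0.01) -> np.ndarray:
    """Unit-SD noise with a 1/f**exponent power spectrum (flat below f_floor).

    Spontaneous pupil fluctuation (hippus and slower waves) has most of
    its power at low frequencies; white noise would misrepresent the
    band where entrainment is measured.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_floor_hz) ** (-exponent / 2.0)
    shape[0] = 0.0
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def synth_pupil(
    salience: "SalienceSeries",
    prf: "PRFKernel",
    n_loops: int = 8,
    noise_sd: float = 60.0,
    blink_rate_hz: float = 0.05,
    seed: int = 0,
    baseline_au: float = 2000.0,
    signal_gain_au: float = 30.0,
    drift_amp_au: float = 15.0,
    blink_spike_au: float = 60.0,
    deviant_times_s: Optional[Sequence[float]] = None,
) -> RawPupilLog:
    """Synthesize a raw 500 Hz pupil log from a one-loop salience series.

    The clean signal is the salience tiled ``n_loops`` times, convolved
    with the pupillary response function, z-scored, scaled to arbitrary
    units and offset to a realistic baseline. On top of it: 1/f-shaped
    physiological noise at twice the entrained-signal SD (spontaneous
    pupil fluctuation typically exceeds stimulus-driven modulation), a
    slow sinusoidal drift (below the 0.05 Hz high-pass cutoff
    downstream), and blink artifacts — 100-300 ms missing runs flanked
    by spike samples, as an eye-tracker records them.
    """
    from pupilbeat.prf import predict_pupil  # local import avoids cycle

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    rng = np.random.default_rng(seed)

    pred = predict_pupil(salience, prf, n_loops=n_loops)
    clean100 = pred.values
    sd = np.std(clean100)
    if sd > 0:
        clean100 = (clean100 - np.mean(clean100)) / sd
    # 100 Hz -> 500 Hz
    clean500 = signal.resample_poly(clean100, 5, 1)
    n = clean500.size
    t = np.arange(n) / PUPIL_RATE_HZ

    pupil = baseline_au + signal_gain_au * clean500
    if drift_amp_au > 0:
        f_drift = rng.uniform(0.005, 0.02)
        phase = rng.uniform(0, 2 * np.pi)
        pupil = pupil + drift_amp_au * np.sin(2 * np.pi * f_drift * t + phase)
    if noise_sd > 0:
        pupil = pupil + noise_sd * _pink_noise(n, PUPIL_RATE_HZ, rng)

    blink = np.zeros(n, dtype=bool)
    saccade = np.zeros(n, dtype=bool)
    if blink_rate_hz > 0:
        n_blinks = rng.poisson(blink_rate_hz * n / PUPIL_RATE_HZ)
        for _ in range(n_blinks):
            dur = int(rng.uniform(0.100, 0.300) * PUPIL_RATE_HZ)
            start = rng.integers(5, max(n - dur - 5, 6))
            blink[start : start + dur] = True
            # eyelid-sweep spike artifacts at the blink boundaries
            pupil[max(start - 3, 0) : start] += blink_spike_au
            pupil[start + dur : start + dur + 3] -= blink_spike_au
            saccade[max(start - 2, 0) : start + 1] = True
            saccade[start + dur - 1 : start + dur + 2] = True
    pupil = np.where(blink, np.nan, pupil)

    loop_dur = salience.values.size / MODEL_RATE_HZ
    events = {"loop_onset": [k * loop_dur for k in range(n_loops)]}
    if deviant_times_s is not None:
        events["deviant_onset"] = list(deviant_times_s)
    return RawPupilLog(
        time_ms=t * 1000.0,
        pupil=pupil,
        blink=blink,
        saccade=saccade,
        sample_rate=PUPIL_RATE_HZ,
        events=events,
        seed=seed,
        missing_fraction=float(np.mean(blink)),
    )
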