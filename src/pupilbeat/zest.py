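"""ZEST Bayesian adaptive threshold estimation and experiment simulation.

ZEST maintains a discretized probability density over a listener's
dB-increment detection threshold. Each deviant is presented at the mean
of the current density; the density is updated by Bayes' rule from the
yes/no response via an assumed psychometric likelihood

    P(yes | level L, threshold theta) =
        gamma + (1 - gamma - lapse) * Phi((L - theta) / sigma)

with guess rate gamma, lapse rate lambda and spread sigma (defaults 0.02,
0.02, 2 dB — conventional, configurable; a procedure of this family needs
an assumed psychometric form). The estimate after the fixed 20-observation
stopping rule is the mean of the final density. Four positions within the
loop are tracked by four independent ZEST states, interleaved by the
deviant schedule; responses count only within a 1000 ms window after
probe onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from pupilbeat.synth import DeviantSchedule

DEFAULT_PRIOR_MEAN_DB = 10.0
DEFAULT_PRIOR_SD_DB = 6.0
DEFAULT_STOP_OBSERVATIONS = 20
RESPONSE_WINDOW_MS = 1000.0


@dataclass(frozen=True)
class ZestState:
    """Discretized posterior over threshold (dB) plus trial history."""

    grid_db: np.ndarray
    pdf: np.ndarray
    history: tuple[tuple[float, bool], ...] = ()
    guess_rate: float = 0.02
    lapse_rate: float = 0.02
    slope_db: float = 2.0

    def __post_init__(self) -> None:
        pdf = np.asarray(self.pdf, dtype=float)
        if np.any(pdf < 0):
            raise ValueError("pdf must be nonnegative")
        if abs(pdf.sum() - 1.0) > 1e-9:
            raise ValueError("pdf must sum to 1")
        object.__setattr__(self, "pdf", pdf)
        object.__setattr__(self, "grid_db", np.asarray(self.grid_db, dtype=float))

    @property
    def n_observations(self) -> int:
        return len(self.history)

    @property
    def mean_db(self) -> float:
        return float(np.sum(self.grid_db * self.pdf))

    @property
    def sd_db(self) -> float:
        m = self.mean_db
        return float(np.sqrt(np.sum((self.grid_db - m) ** 2 * self.pdf)))


def init_zest(
    prior_mean_db: float = DEFAULT_PRIOR_MEAN_DB,
    prior_sd_db: float = DEFAULT_PRIOR_SD_DB,
    grid_min_db: float = -10.0,
    grid_max_db: float = 30.0,
    grid_step_db: float = 0.1,
    guess_rate: float = 0.02,
    lapse_rate: float = 0.02,
    slope_db: float = 2.0,
) -> ZestState:
    """Initialize with a truncated-Gaussian prior; its mean sets the start level.

    At defaults the first presented level is the 10 dB starting increment.
    """
    if grid_step_db <= 0:
        raise ValueError("grid step must be positive")
    if not grid_min_db <= prior_mean_db <= grid_max_db:
        raise ValueError("grid must cover the prior mean")
    grid = np.arange(grid_min_db, grid_max_db + grid_step_db / 2, grid_step_db)
    pdf = norm.pdf(grid, loc=prior_mean_db, scale=prior_sd_db)
    pdf /= pdf.sum()
    return ZestState(grid, pdf, (), guess_rate, lapse_rate, slope_db)


def next_level(state: ZestState) -> float:
    """Level of the next deviant: the posterior mean, clipped to the grid."""
    return float(np.clip(state.mean_db, state.grid_db[0], state.grid_db[-1]))


def _p_yes(level_db: float, theta_db: np.ndarray, state: ZestState) -> np.ndarray:
    return state.guess_rate + (1.0 - state.guess_rate - state.lapse_rate) * norm.cdf(
        (level_db - theta_db) / state.slope_db
    )


def zest_update(state: ZestState, level_db: float, response: bool) -> ZestState:
    """Bayes update of the threshold density after one observation."""
    p = _p_yes(level_db, state.grid_db, state)
    likelihood = p if response else 1.0 - p
    post = state.pdf * likelihood
    total = post.sum()
    if total <= 0:
        raise ValueError("posterior has zero mass")
    return replace(
        state, pdf=post / total, history=state.history + ((level_db, bool(response)),)
    )


def final_threshold(
    state: ZestState, stop_observations: int = DEFAULT_STOP_OBSERVATIONS
) -> float:
    """Mean of the final density once the stopping quota is reached."""
    if state.n_observations < stop_observations:
        raise ValueError(
            f"stopping rule not reached: {state.n_observations} < {stop_observations}"
        )
    return state.mean_db


@dataclass
class PsychometricObserver:
    """Simulated listener with a cumulative-Gaussian detection function.

    ``slope_db = 0`` gives a deterministic step observer (detects iff
    level >= threshold, no guesses or lapses). Reaction times are drawn
    lognormal around ~450 ms; occasional slow responses fall outside the
    1000 ms scoring window and are scored as misses.
    """

    true_threshold_db: float = 6.0
    slope_db: float = 2.0
    lapse_rate: float = 0.02
    false_alarm_rate: float = 0.02
    seed: int = 0
    rt_median_ms: float = 450.0
    rt_sigma: float = 0.35
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.lapse_rate < 0.5 and 0 <= self.false_alarm_rate < 0.5):
            raise ValueError("rates must lie in [0, 0.5)")
        if self.slope_db < 0:
            raise ValueError("slope must be nonnegative")
        self._rng = np.random.default_rng(self.seed)

    def respond(self, level_db: float) -> tuple[bool, Optional[float]]:
        """(detected, reaction_time_ms); RT is None for non-responses."""
        if self.slope_db == 0:
            p = 1.0 if level_db >= self.true_threshold_db else 0.0
        else:
            p = self.false_alarm_rate + (
                1.0 - self.false_alarm_rate - self.lapse_rate
            ) * norm.cdf((level_db - self.true_threshold_db) / self.slope_db)
        detected = bool(self._rng.random() < p)
        if not detected:
            return False, None
        rt = float(
            self.rt_median_ms * np.exp(self._rng.normal(0.0, self.rt_sigma))
        )
        return True, rt


def run_experiment(
    schedule: DeviantSchedule,
    observer: PsychometricObserver,
    stop_observations: int = DEFAULT_STOP_OBSERVATIONS,
    response_window_ms: float = RESPONSE_WINDOW_MS,
    **zest_kwargs,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Run the full adaptive deviance-detection experiment.

    One independent ZEST track per probed position, interleaved by the
    schedule. A detection whose reaction time exceeds the response window
    is scored as a miss. Returns the complete trial table (one row per
    loop, standards included) and the final threshold per position.
    """
    states = {p: init_zest(**zest_kwargs) for p in schedule.probe_positions}
    rows = []
    for rec in schedule.loop_sequence:
        if rec.kind == "standard":
            rows.append(
                dict(
                    loop_index=rec.loop_index,
                    trial_kind="no_deviant",
                    probe_position=pd.NA,
                    level_db=np.nan,
                    response=pd.NA,
                    response_time_ms=np.nan,
                )
            )
            continue
        pos = rec.probe_position
        state = states[pos]
        if state.n_observations >= stop_observations:
            raise ValueError(
                f"schedule presents position {pos} beyond the stopping quota"
            )
        level = rec.level_db if rec.level_db is not None else next_level(state)
        detected, rt = observer.respond(level)
        scored_hit = detected and rt is not None and rt <= response_window_ms
        states[pos] = zest_update(state, level, scored_hit)
        rows.append(
            dict(
                loop_index=rec.loop_index,
                trial_kind="deviant",
                probe_position=pos,
                level_db=level,
                response="hit" if scored_hit else "miss",
                response_time_ms=rt if scored_hit else np.nan,
            )
        )
    trials = pd.DataFrame(rows)
    thresholds = {
        p: final_threshold(s, stop_observations) for p, s in states.items()
    }
    return trials, thresholds
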