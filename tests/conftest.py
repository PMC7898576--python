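"""Shared fixtures: stimuli, model outputs and predictions are expensive
relative to the rest of the suite, so the default trio is computed once per
session."""

import numpy as np
import pytest

from pupilbeat.auditory import model_salience
from pupilbeat.prf import predict_pupil, prf_kernel
from pupilbeat.synth import MODEL_RATE_HZ, make_pattern, render_loop

# 42800 Hz is divisible by the 107 BPM grid: each 140.19 ms slot is exactly
# 6000 samples, so loop boundaries and onsets fall on integer samples.
RENDER_RATE = 42800.0
TRIO = ("complex1-like", "sparse", "halftime")


@pytest.fixture(scope="session")
def prf_default():
    return prf_kernel()


@pytest.fixture(scope="session")
def trio_model(prf_default):
    """Salience, MPP and 28-loop predicted pupil for the default stimuli."""
    out = {}
    for name in TRIO:
        pattern = make_pattern(name)
        loop_samples = int(round(pattern.loop_duration_s * MODEL_RATE_HZ))
        audio = render_loop(pattern.tiled(3), RENDER_RATE, seed=0)
        sal, mpp = model_salience(audio, loop_samples=loop_samples, source=name)
        pred = predict_pupil(sal, prf_default, n_loops=28)
        out[name] = dict(pattern=pattern, salience=sal, mpp=mpp, prediction=pred.values)
    return out


@pytest.fixture(scope="session")
def impulse_train_2hz():
    """A 2 Hz isochronous onset series at the model rate (60 s)."""
    x = np.zeros(6000)
    x[:: int(MODEL_RATE_HZ / 2)] = 1.0
    return x
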