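"""Shared fixtures: synthetic recordings, calibrated models, one session.

Everything is generated programmatically and seeded, so the suite is
deterministic and needs no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from affectbci import (
    EffectSpec,
    EEGRecording,
    calibrate,
    gen_background,
    gen_calibration_recording,
    run_session,
)
from affectbci.synth import make_responder_setup


def make_noise_recording(
    duration: float,
    events: list[tuple[float, float, str]],
    seed: int = 0,
    fs: float = 128.0,
) -> EEGRecording:
    """White-noise 14-channel recording with the given event annotations."""
    rec = gen_background(
        n_channels=14, duration=duration, fs=fs, exponent=0.0, seed=seed
    )
    rec.events = events
    return rec


@pytest.fixture(scope="session")
def strong_rec():
    """Calibration recording with a strong planted alpha class effect."""
    return gen_calibration_recording(EffectSpec.strong(), seed=7)


@pytest.fixture(scope="session")
def strong_model(strong_rec):
    return calibrate(strong_rec)


@pytest.fixture(scope="session")
def coupled_session():
    """20-trial closed-loop session with a task-tracking responder."""
    model, responder = make_responder_setup(5)
    return run_session(model, responder, 20, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
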