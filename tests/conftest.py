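from dataclasses import replace

import numpy as np
import pytest

from chewevents import synthetic
from chewevents.cycles import estimate_burst_threshold, baseline_samples
from chewevents.preprocessing import preprocess


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recording():
    """600 s, one 200 s eating event; shared across tests (read-only)."""
    cfg = replace(
        synthetic.SynthConfig(),
        duration=600.0,
        n_events=1,
        event_duration_range=(200.0, 200.0),
        min_event_gap=60.0,
        seed=3,
    )
    rec, gt = synthetic.generate_recording(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def short_preprocessed(short_recording):
    cfg, rec, gt = short_recording
    xp = preprocess(rec)
    theta_c = estimate_burst_threshold(baseline_samples(xp, gt.reference))
    return xp, theta_c, gt
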