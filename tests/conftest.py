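"""Shared fixtures: small synthetic cohorts generated at test time."""

import warnings

import numpy as np
import pytest

from kinemetrics.keypoint_io import KeypointSeries
from kinemetrics.joints import JOINTS
from kinemetrics.pipeline import RunConfig
from kinemetrics.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def fast_config() -> SynthConfig:
    """Scaled-down study design: short recordings, few infants, fast tests."""
    return SynthConfig(n_infants=6, duration_s=40.0, frame_rate=10.0, seed=11)


@pytest.fixture(scope="session")
def fast_run_config() -> RunConfig:
    return RunConfig(frame_rate=10.0, min_duration_s=20.0)


@pytest.fixture(scope="session")
def fast_cohort(fast_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(fast_config)


def make_series(
    n_frames: int = 10,
    frame_rate: float = 30.0,
    confidence: float = 0.9,
    seed: int = 0,
    infant_id: str = "t0",
) -> KeypointSeries:
    """A fully observed keypoint series with reproducible random positions."""
    rng = np.random.default_rng(seed)
    n_j = len(JOINTS)
    return KeypointSeries(
        infant_id=infant_id,
        frame_rate=frame_rate,
        frames=np.arange(n_frames),
        x=rng.uniform(0, 320, (n_frames, n_j)),
        y=rng.uniform(0, 240, (n_frames, n_j)),
        confidence=np.full((n_frames, n_j), confidence),
    )
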