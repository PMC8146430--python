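"""Shared fixtures: small synthetic inputs generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from connentropy import RoiTimeSeries
from connentropy.cohort import CohortConfig, NoCoupling


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210422)


@pytest.fixture(scope="session")
def fs():
    return 200.0


@pytest.fixture(scope="session")
def sine_trial(fs):
    """A 60-s single-channel 10 Hz unit sinusoid."""
    t = np.arange(0, 60, 1 / fs)
    return RoiTimeSeries(np.sin(2 * np.pi * 10 * t)[np.newaxis, :], fs)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Small, fast cohort: 4 ROIs, enough samples for twenty 5-s trials."""
    return CohortConfig(group_sizes=(2, 2, 2), n_rois=4, duration=115.0,
                        coupling_spec=NoCoupling(), leakage_mix=0.0, seed=42)
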