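"""Shared fixtures: scaled-down synthetic sessions for fast tests.

The small configuration keeps the 8-run x 4-task layout but shortens
tasks to 12 s and samples at 250 Hz, which preserves every structural
property the pipeline relies on (1 s epochs, 1 Hz resolution, 1-100 Hz
bandwidth) at a fraction of the cost.  The full-scale default session is
generated once per test run for the structural-count checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitattn import (
    EEGSession,
    Segment,
    SimConfig,
    extract_features,
    generate_session,
    preprocess,
    standard_montage,
)

SMALL = dict(fs=250.0, task_duration_s=12.0, break_duration_s=2.0)


def make_small_config(**overrides) -> SimConfig:
    kwargs = {**SMALL, **overrides}
    return SimConfig(**kwargs)


def wrap_data(data: np.ndarray, fs: float) -> EEGSession:
    """Wrap a (32, n) array as a minimal valid session (one run, four
    equal task segments); n must be divisible by 4."""
    n = data.shape[1]
    assert n % 4 == 0
    q = n // 4
    segments = tuple(
        Segment(code, 1, i * q, (i + 1) * q)
        for i, code in enumerate("ABCD")
    )
    session = EEGSession(
        data=np.asarray(data, dtype=np.float32),
        fs=fs,
        montage=standard_montage(),
        segments=segments,
    )
    session.validate()
    return session


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return make_small_config(seed=1)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_standardized(small_session):
    standardized, _ = preprocess(small_session)
    return standardized


@pytest.fixture(scope="session")
def small_features(small_standardized):
    return extract_features(small_standardized)


@pytest.fixture(scope="session")
def full_session():
    """Full-scale default session (1200 Hz, 60 s tasks, 60 s breaks)."""
    return generate_session(SimConfig(seed=7))
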