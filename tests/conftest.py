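"""Shared fixtures.

Heavy artifacts (trained pipelines) are session-scoped so that the
acceptance tests and the API tests share one training run per seed.
"""
from __future__ import annotations

import numpy as np
import pytest

from semgintent import synthetic
from semgintent.preprocessing import build_dataset


@pytest.fixture(scope="session")
def short_recording():
    """8 s of walking — enough for several complete strides."""
    params = synthetic.GaitParams(duration=8.0, seed=42)
    return synthetic.generate_recording(params)


@pytest.fixture(scope="session")
def short_dataset(short_recording):
    return build_dataset(short_recording)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
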