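"""Shared fixtures.

The demo dataset (8 channels, 5 active, full two-session finger-tapping
paradigm at 9.19 Hz, seed 1) is the packaged study-condition dataset used by
the end-to-end prediction and detection tests. The heavy prediction runs are
session-scoped so the RLS/KRLS sweeps over all horizons execute once.
"""

from __future__ import annotations

import numpy as np
import pytest

from nirsdip import SignalPredictionModel, bandpass, generate_dataset
from nirsdip.pipeline import dhrf_for_record
from nirsdip.simulate import SimulationConfig

DEMO_SEED = 1
DEMO_ACTIVE = (2, 3, 5, 6, 8)
HORIZONS = (1, 5, 10, 15, 20)


@pytest.fixture(scope="session")
def demo_record():
    cfg = SimulationConfig(n_channels=8, active_channels=DEMO_ACTIVE)
    return generate_dataset(cfg, seed=DEMO_SEED)


@pytest.fixture(scope="session")
def filtered_record(demo_record):
    return bandpass(demo_record)


@pytest.fixture(scope="session")
def demo_dhrf(filtered_record):
    return dhrf_for_record(filtered_record)


@pytest.fixture(scope="session")
def rls_results(filtered_record, demo_dhrf):
    model = SignalPredictionModel(filtered_record, demo_dhrf, model="rls", horizons=HORIZONS)
    return model.fit()


@pytest.fixture(scope="session")
def krls_results(filtered_record, demo_dhrf):
    model = SignalPredictionModel(
        filtered_record, demo_dhrf, model="krls", kernel="gaussian", horizons=HORIZONS
    )
    return model.fit()
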