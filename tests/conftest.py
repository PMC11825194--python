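from __future__ import annotations

import pytest

from persistkit.config import SimulationConfig
from persistkit.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(n_patients=300, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_patients=300, seed=42)
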