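import numpy as np
import pytest

from pupilswitch.config import (
    ComponentParams,
    GapProcess,
    LookingParams,
    SimulationConfig,
    null_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Deterministic config: no noise, no drift, no gaps, no exclusions."""
    return SimulationConfig(
        n_participants={"10mo": 2, "15mo": 2},
        noise_sd_mm=0.0,
        drift_sd_mm=0.0,
        amplitude_subject_sd=0.0,
        gap_process=GapProcess(gap_rate_per_s=0.0),
        exclusion_target={"10mo": 0.0, "15mo": 0.0},
        seed=7,
    ).validate()


@pytest.fixture
def small_config():
    """Small but fully stochastic cohort for integration tests."""
    return SimulationConfig(
        n_participants={"10mo": 3, "15mo": 3},
        seed=11,
    ).validate()


@pytest.fixture
def null_cfg():
    return null_config(n_participants={"10mo": 3, "15mo": 3}, seed=5)


def lean_null_config(n: int, seed: int, age: str = "15mo") -> SimulationConfig:
    """Null cohort without a familiarization phase (fast to generate)."""
    return null_config(
        n_participants={age: n},
        n_familiarization_blocks=0,
        looking=LookingParams(familiarization_block_p=()),
        seed=seed,
    )
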