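import numpy as np
import pytest

from motorequiv.simulate import (
    EffectorModulation,
    MotorSignature,
    SimulationConfig,
    generate_cohort,
    synthesize_recording,
)

IDENTITY = EffectorModulation("right_hand", 1.0, 1.0)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, jitter-free settings for closed-form oracles."""
    return SimulationConfig(noise_sd=0.0, cycle_jitter=0.0, rng_seed=0)


@pytest.fixture(scope="session")
def hammer_signature():
    # forth duration = 0.45 * 0.8889 s = 0.4 s exactly at 200 Hz
    return MotorSignature(
        participant_id="P01",
        tool="hammer",
        stroke_amplitude=300.0,
        cycle_duration=0.4 / 0.45,
        forth_fraction=0.45,
        rest_offset=(0.0, 0.0, 400.0),
    )


@pytest.fixture(scope="session")
def clean_hammer_sim(clean_config, hammer_signature):
    """Noise-free 22-cycle hammer recording with analytic ground truth."""
    return synthesize_recording(
        hammer_signature, "hammer", "right_hand", IDENTITY, clean_config
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Preserved-mode cohort small enough for fast end-to-end tests."""
    return generate_cohort(SimulationConfig(n_participants=5, rng_seed=11))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    from motorequiv.reporting import extract_cohort

    table, records = extract_cohort(small_cohort.recordings)
    return table


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
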