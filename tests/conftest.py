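import numpy as np
import pytest

from mvkin import SimulationConfig, simulate_paired_session
from mvkin.pipeline import process_bundle


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The standard study conditions: 40-degree side dip, 5 s at 12 Hz,
    4-camera ring, 1 px keypoint noise, 100 Hz reference with 1 degree
    noise, seed 42, five repetitions."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_session(default_config):
    return simulate_paired_session(default_config)


@pytest.fixture(scope="session")
def default_outcomes(default_session):
    """Processed repetitions of the default session (shared: read-only)."""
    return [process_bundle(b) for b in default_session]


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(
        pixel_sigma_px=0.0, reference_noise_sigma_deg=0.0, repetitions=1
    )


@pytest.fixture(scope="session")
def noiseless_outcome(noiseless_config):
    (bundle,) = simulate_paired_session(noiseless_config)
    return process_bundle(bundle)


def random_ratings_table(rng: np.random.Generator, n: int = 100, k: int = 2) -> np.ndarray:
    """Random two-way table with genuine subject and rater effects."""
    subjects = rng.normal(0.0, 2.0, size=(n, 1))
    raters = rng.normal(0.0, 0.5, size=(1, k))
    noise = rng.normal(0.0, 1.0, size=(n, k))
    return subjects + raters + noise
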