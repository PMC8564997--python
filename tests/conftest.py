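import numpy as np
import pytest

from occlureg import NoiseModel, SimulationConfig, default_layout, run_experiment


def random_rigid(rng):
    """A random proper rigid transform (uniform rotation, ±50 mm translation)."""
    from occlureg.scan_simulator import random_pose

    return random_pose(rng)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def small_config():
    """A reduced design for fast end-to-end tests (not the study conditions)."""
    return SimulationConfig(points_per_concave=80, n_repetitions=4, seed=7)


@pytest.fixture(scope="session")
def small_report(small_config):
    return run_experiment(small_config)


@pytest.fixture(scope="session")
def default_report():
    """One full default-condition experiment (15 reps x 2 operators, 300 pts)."""
    return run_experiment(SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def zero_noise_report():
    cfg = SimulationConfig(
        noise=NoiseModel(sigma_contact=0.0, sigma_scan=0.0),
        points_per_concave=60,
        n_repetitions=3,
        seed=5,
    )
    return run_experiment(cfg, compute_stats=False)
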