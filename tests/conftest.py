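import numpy as np
import pytest

from gsecens.order_params import compute_op_series
from gsecens.synthetic_data import (default_config, ground_truth,
                                    simulate_two_state_trajectory,
                                    synthetic_topology_map)

# Seed used for every deterministic simulation fixture in the suite.
SUITE_SEED = 11


@pytest.fixture(scope="session")
def benchmark_sim():
    """The standard benchmark run: 10,000 frames at the default conditions
    (state-2 stationary occupancy 0.3, dd_Asp 1.0/0.45 nm, noise 0.05 nm).

    Session-scoped because the order-parameter sweep takes a few seconds;
    several recovery tests share it.
    """
    cfg = default_config(seed=SUITE_SEED)
    traj, gt = simulate_two_state_trajectory(cfg)
    series = compute_op_series(traj, synthetic_topology_map(cfg))
    return cfg, traj, gt, series


@pytest.fixture(scope="session")
def noisefree_sim():
    """Small noise-free two-state run: downstream values must be exact."""
    cfg = default_config(seed=3, n_frames=40, noise_sigma_nm=0.0)
    traj, gt = simulate_two_state_trajectory(cfg)
    series = compute_op_series(traj, synthetic_topology_map(cfg))
    return cfg, traj, gt, series


@pytest.fixture()
def small_cfg():
    return default_config(seed=5, n_frames=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation from a seeded generator."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


@pytest.fixture(scope="session")
def truth_defaults():
    return ground_truth(default_config())
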