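"""Shared fixtures: small synthetic cohorts with known ground truth."""

import numpy as np
import pytest

from megadecline.simulate import (ScenarioParams, simulate_climate,
                                  simulate_species, simulate_trajectory)


@pytest.fixture(scope="session")
def climate():
    return simulate_climate(seed=0)


@pytest.fixture(scope="session")
def two_segment_points():
    """Noiseless two-segment data: slopes -0.03 / -0.50, break at 50 kyr."""
    t = np.geomspace(1e3, 1e6, 40)
    u = -np.log10(t)
    ubp = -np.log10(5e4)
    y = np.where(u <= ubp, 4.0 - 0.03 * (u - ubp), 4.0 - 0.50 * (u - ubp))
    return np.column_stack([np.log10(t), y])


def make_linear_cohort(n_species, mass_effect, noise_sd, seed, base_slope=-0.3):
    """Cohort of log-linear trajectories whose slopes depend on mass."""
    traits, truth = simulate_species(n_species, mass_slope_effect=mass_effect,
                                     base_slope=base_slope, seed=seed)
    rng = np.random.default_rng(seed + 99)
    trajs = []
    for i, tr in enumerate(traits):
        s = float(truth.loc[i, "true_post_slope"])
        p = ScenarioParams(scenario="piecewise_decline", pre_slope=s,
                           post_slope=s, noise_sd=noise_sd, seed=seed + i)
        traj, _ = simulate_trajectory(tr, p, rng=rng)
        trajs.append(traj)
    return trajs, traits, truth


@pytest.fixture()
def linear_cohort():
    return make_linear_cohort(12, -0.1, 0.1, seed=42)
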