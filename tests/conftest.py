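"""Shared fixtures: the reference in-silico experiment and derived data.

Everything is generated at test time; expensive objects (the reference
trajectory, the ten-seed filter sweep) are session-scoped so the
acceptance tests and module tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dynqs import simulate as sim
from dynqs import particle_filter as pf
from dynqs.models import KineticParameters, ModelConstants, PlantState

settings.register_profile("ci", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("ci")

PF_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def consts() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def ref_params() -> KineticParameters:
    return sim.reference_parameters()


@pytest.fixture(scope="session")
def ref_traj():
    """Full reference plant trajectory (dynamic model, spiked feed, 32 h)."""
    return sim.simulate_plant(sim.reference_initial_state(),
                              sim.reference_parameters(),
                              sim.reference_feed(),
                              sim.reference_activation(), t_end=32.0)


@pytest.fixture(scope="session")
def ref_obs(ref_traj):
    """Observer grid (dt = 0.05 h) subsample of the reference run."""
    return ref_traj.observations(0.05)


@pytest.fixture(scope="session")
def pf_runs(ref_obs):
    """Ten-seed reference particle-filter sweep (full configuration)."""
    feed = sim.reference_feed()
    x0 = sim.reference_initial_state()
    return [pf.run_filter(ref_obs, feed, x0, seed=s) for s in PF_SEEDS]


@pytest.fixture(scope="session")
def short_obs(ref_obs):
    """Observations truncated past the batch/fed-batch transition (16 h)."""
    return ref_obs[ref_obs["t"] <= 16.0].reset_index(drop=True)


@pytest.fixture(scope="session")
def monod_dataset():
    """Noise-free Monod-plant dataset (batch + fed-batch) for LSQ fits."""
    from dynqs.lsq_prior import Dataset
    params = KineticParameters(1.05, 0.629)
    feed = sim.FeedProfile(u0=0.0022, mu_set=0.17, t_start=10.0)
    traj = sim.simulate_plant(PlantState(0.05, 8.0, 0.0, 1.0), params, feed,
                              None, t_end=16.0, model="monod", dt_out=0.05)
    offline = sim.sample_offline(traj, [1, 3, 5, 7, 9, 11, 13, 15],
                                 noise=False)
    return Dataset(offline=offline, online=traj.observations(0.05), V0=1.0)
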