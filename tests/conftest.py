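"""Shared fixtures: default configs and session-scoped simulated datasets."""

import numpy as np
import pytest

from spotspectra import (
    AcquisitionConfig,
    DiffusiveState,
    SimulationModel,
    StateGrid,
    build_likelihood_matrix,
    render_movie,
    sample_cells,
    sample_trajectories,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig(n_frames=800)


@pytest.fixture(scope="session")
def grid():
    return StateGrid()


@pytest.fixture(scope="session")
def two_state_model():
    return SimulationModel(
        states=[DiffusiveState(0.005, 0.4), DiffusiveState(3.0, 0.6)]
    )


@pytest.fixture(scope="session")
def two_state_dataset(two_state_model, acq):
    """30 simulated cells of the default 40% bound / 60% free (D=3) mixture."""
    return sample_cells(two_state_model, acq, n_cells=30, seed=123)


@pytest.fixture(scope="session")
def two_state_L(two_state_dataset, grid, acq):
    return build_likelihood_matrix(two_state_dataset, grid, acq)


@pytest.fixture(scope="session")
def movie_bundle():
    """A small rendered movie with ground truth: 64×64 px, 200 frames."""
    acq = AcquisitionConfig(fov_px=(64, 64), n_frames=200)
    model = SimulationModel(
        states=[DiffusiveState(0.005, 0.5), DiffusiveState(2.0, 0.5)],
        initial_density_per_frame=5.0,
    )
    trajs, truth = sample_trajectories(model, acq, seed=11)
    stack = render_movie(truth, acq, photons_per_spot=500, seed=12)
    return {"acq": acq, "model": model, "trajs": trajs, "truth": truth, "stack": stack}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
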