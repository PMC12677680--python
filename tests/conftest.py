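import numpy as np
import pytest

from chromotion import (
    SimulationConfig,
    TextureParams,
    Trajectory,
    simulate_nucleus,
    simulate_trajectories,
)


def trajectories_from_truth(truth, observed=True, n=None):
    """Wrap ground-truth position arrays as Trajectory objects."""
    pos = truth.observed_positions if observed else truth.true_positions
    n = truth.n_foci if n is None else n
    frames = np.arange(truth.n_frames)
    return [
        Trajectory(id=i, frames=frames, positions=pos[i],
                   sizes=np.full(truth.n_frames, truth.focus_sizes[i]))
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def brownian_truth():
    """1000 free Brownian tracks at the pluripotent-state D with 30 nm
    localization noise — the workhorse for MSD/diffusion-fit checks."""
    cfg = SimulationConfig(n_foci=1000, n_frames=101, dt=5.0, D=14.99e-5,
                           alpha=1.0, loc_noise_sigma=0.03, seed=1, noise=False)
    return simulate_trajectories(cfg, None)


@pytest.fixture(scope="session")
def nucleus_sample():
    """A mid-size simulated nucleus with a clearly bimodal two-class texture."""
    return simulate_nucleus(
        (16, 64, 64), (0.2, 0.1, 0.1),
        TextureParams(means=(100.0, 300.0), sds=(20.0, 20.0)), seed=3,
    )
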