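import numpy as np
import pytest

from hbdyn.traj_io import Trajectory


def make_water_grid(n_molecules: int, n_frames: int = 1, box_edge: float = 12.43,
                    with_velocities: bool = True, seed: int = 0) -> Trajectory:
    """Water molecules on a cubic lattice with slightly randomized velocities."""
    rng = np.random.default_rng(seed)
    per_side = int(np.ceil(n_molecules ** (1 / 3)))
    spacing = box_edge / per_side
    pos = np.zeros((n_frames, 3 * n_molecules, 3))
    symbols = []
    m = 0
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                if m >= n_molecules:
                    break
                o = np.array([i, j, k]) * spacing + 0.1
                pos[:, 3 * m, :] = o
                pos[:, 3 * m + 1, :] = o + [0.96, 0.0, 0.0]
                pos[:, 3 * m + 2, :] = o + [-0.24, 0.93, 0.0]
                symbols += ["O", "H", "H"]
                m += 1
    vel = rng.normal(0, 1e-3, pos.shape) if with_velocities else None
    return Trajectory(symbols, pos, vel, box_edge, dt=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
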