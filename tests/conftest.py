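import numpy as np
import pytest

import memdiff as m


@pytest.fixture(scope="session")
def free_field():
    """An empty 5 µm periodic box (no obstacles)."""
    return m.build_obstacle_field(5.0, 0.0, 0.101)


@pytest.fixture(scope="session")
def obstacle_field():
    """A 24% / 101 nm obstacle field, the configuration under study."""
    return m.build_obstacle_field(5.0, 0.24, 0.101, 0.0078, seed=11)


@pytest.fixture(scope="session")
def obstructed_study(obstacle_field):
    """One well-sampled obstructed simulation with its analysis curves.

    Shared between the anomalous-diffusion unit checks and the acceptance
    tests so the (comparatively expensive) simulation runs once.
    """
    cfg = m.DiffusionSimConfig(
        d_free=0.7,
        frame_interval=1 / 500,
        n_trajectories=400,
        n_frames=400,
        length_dist="fixed",
        loc_noise_sigma=0.0,
        seed=11,
    )
    trajs = m.simulate_trajectories(obstacle_field, cfg)
    curve = m.pooled_msd_from_trajectories(trajs, 150, use_true=True)
    dcurve = m.build_d_curve(curve)
    return {"config": cfg, "trajectories": trajs, "msd": curve, "dcurve": dcurve}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def brute_force_msd(positions: np.ndarray, frame_interval: float, n_max: int):
    """Independent double-loop oracle for the overlapping-window MSD."""
    pos = np.asarray(positions, float)
    N = len(pos)
    taus, msd, counts = [], [], []
    for n in range(1, n_max + 1):
        if n > N - 1:
            break
        acc = 0.0
        k = 0
        for i in range(N - n):
            dx = pos[i + n, 0] - pos[i, 0]
            dy = pos[i + n, 1] - pos[i, 1]
            acc += dx * dx + dy * dy
            k += 1
        taus.append(n * frame_interval)
        msd.append(acc / k)
        counts.append(k)
    return np.array(taus), np.array(msd), np.array(counts)
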