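import numpy as np
import pytest

from sasclip import (
    BeadStructure,
    HingeModelConfig,
    Trajectory,
    generate_hinge_trajectory,
    make_target_profile,
)


def random_structure(rng, n_beads=8, box=20.0, weights=None):
    """A random bead structure with carbon-like weights by default."""
    coords = rng.uniform(-box, box, size=(n_beads, 3))
    if weights is None:
        weights = rng.uniform(1.0, 10.0, size=n_beads)
    return BeadStructure(
        coordinates=coords,
        scattering_weight=np.asarray(weights, dtype=float),
        residue_index=np.arange(1, n_beads + 1),
        bead_role=np.array(["backbone"] * n_beads, dtype=object),
    )


def random_trajectory(rng, n_frames=10, n_beads=5, frame_interval=2.0):
    """Frames share topology but have independent random coordinates."""
    weights = rng.uniform(1.0, 10.0, size=n_beads)
    residues = np.arange(1, n_beads + 1)
    roles = np.array(["backbone"] * n_beads, dtype=object)
    frames = [
        BeadStructure(
            coordinates=rng.uniform(-15.0, 15.0, size=(n_beads, 3)),
            scattering_weight=weights,
            residue_index=residues,
            bead_role=roles,
        )
        for _ in range(n_frames)
    ]
    return Trajectory(frames=tuple(frames), frame_interval=frame_interval)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


#: Desk-scale hinge system shared by several integration tests: same state
#: structure as the default conditions, scaled down in frame count and beads.
SMALL_CONFIG = HingeModelConfig(
    beads_per_domain=6,
    n_frames=160,
    state_dwell=20,
    planted_length=40,
    guard_run=12,
    seed=11,
)


@pytest.fixture(scope="session")
def small_hinge_system():
    traj, truth = generate_hinge_trajectory(SMALL_CONFIG)
    target = make_target_profile(
        traj, truth.planted_window, seed=SMALL_CONFIG.seed + 1,
        q=np.linspace(0.01, 0.3, 40),
    )
    return traj, truth, target
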