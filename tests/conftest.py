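import numpy as np
import pytest

import cryokit as ck
from cryokit import synth


@pytest.fixture(scope="session")
def phantom():
    """Medium blob phantom at the binned pixel size (3.5 Å/voxel)."""
    return ck.make_phantom(13, box=48, voxel_size=3.5)


@pytest.fixture(scope="session")
def small_phantom():
    """Small phantom for reconstruction/weighting experiments (2.5 Å/voxel)."""
    return ck.make_phantom(9, box=32, voxel_size=2.5)


@pytest.fixture(scope="session")
def rotations():
    return ck.random_rotations(120, 7)


def single_particle_movie(phantom, n_frames=16, drift_per_frame=(0.25, -0.15),
                          noise_sigma=0.0, damage_rate=0.0, seed=3):
    """One-particle drifting movie plus its ground truth."""
    drift = synth.DriftModel.linear(n_frames, drift_per_frame)
    damage = synth.DamageModel(rate=damage_rate)
    return synth.simulate_movie(phantom, [[0.0, 0.0]], [np.eye(3)], drift,
                                damage, noise_sigma=noise_sigma, seed=seed)


@pytest.fixture(scope="session")
def drifting_movie(phantom):
    return single_particle_movie(phantom)


@pytest.fixture(scope="session")
def noisy_drifting_movie(phantom):
    return single_particle_movie(phantom, noise_sigma=2.0, seed=4)
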