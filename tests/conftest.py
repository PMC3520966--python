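import numpy as np
import pytest

from sh2dock.synthetic_data import (
    HBondScriptEntry,
    make_planted_trajectory,
    make_toy_system,
)
from sh2dock.trajectory_analysis import fit_trajectory

CLUSTER_FRACTIONS = (0.3, 0.25, 0.2, 0.15, 0.1)
SIGMA = 0.15
N_FRAMES = 1000


@pytest.fixture(scope="session")
def toy10():
    """A 10-rotatable-bond toy system with a verified planted pose."""
    return make_toy_system(10, seed=1)


@pytest.fixture(scope="session")
def toy0():
    """A rigid (0 rotatable bonds) toy system."""
    return make_toy_system(0, seed=2)


@pytest.fixture(scope="session")
def planted(toy10):
    """1000-frame planted trajectory: 5 clusters, scripted H bonds at 0.6/0.45."""
    script = [
        HBondScriptEntry(toy10.scripted_residues[0], 0.6, toy10.acceptor_atoms[0]),
        HBondScriptEntry(toy10.scripted_residues[1], 0.45, toy10.acceptor_atoms[1]),
    ]
    return make_planted_trajectory(
        toy10, n_frames=N_FRAMES, sigma=SIGMA,
        cluster_fractions=CLUSTER_FRACTIONS, hbond_script=script, seed=7,
    )


@pytest.fixture(scope="session")
def fitted(planted):
    return fit_trajectory(planted.traj)


@pytest.fixture(scope="session")
def jitter_only(toy10):
    """Single-cluster, unscripted jitter trajectory for RMSF recovery."""
    pt = make_planted_trajectory(toy10, n_frames=N_FRAMES, sigma=SIGMA, seed=11)
    return pt, fit_trajectory(pt.traj)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
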