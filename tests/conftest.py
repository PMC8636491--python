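import numpy as np
import pytest

from abdyn.synthetic import SyntheticSpec, sample_multistate_trajectory
from abdyn.trajectory_io import AtomRecord, Topology, Trajectory


@pytest.fixture
def three_state_trajectory():
    """120-frame mixture of 3 well-separated rigid states + small noise."""
    spec = SyntheticSpec(k_states=3, n_frames=120, noise_sigma=0.05, seed=1)
    traj, truth = sample_multistate_trajectory(spec)
    return traj, truth


@pytest.fixture
def toy_backbone():
    """Small all-atom-ish residue: backbone + 2 hydrogens, for selections."""
    atoms = []
    for res in (1, 2, 3):
        atoms += [
            AtomRecord("N", "N", res, "ALA", "A"),
            AtomRecord("CA", "C", res, "ALA", "A"),
            AtomRecord("C", "C", res, "ALA", "A"),
            AtomRecord("O", "O", res, "ALA", "A"),
            AtomRecord("CB", "C", res, "ALA", "A"),
            AtomRecord("HA", "H", res, "ALA", "A"),
            AtomRecord("HB1", "H", res, "ALA", "A"),
            AtomRecord("CG", "C", res, "ALA", "A"),
        ]
    top = Topology(atoms)
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 2, size=(2, top.n_atoms, 3))
    return Trajectory(top, coords)


def label_agreement(planted: np.ndarray, found: np.ndarray) -> float:
    """Best fraction of frames agreeing, over label permutations."""
    from itertools import permutations

    k = max(planted.max(), found.max()) + 1
    best = 0
    for perm in permutations(range(k)):
        mapped = np.array([perm[l] for l in planted])
        best = max(best, (mapped == found).mean())
    return best
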