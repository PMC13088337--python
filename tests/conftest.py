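import numpy as np
import pytest

from etkit.structures import Atom, Structure, Trajectory, infer_covalent_bonds
from etkit.synthetic import (
    PlantedTrajectorySpec,
    make_planted_trajectory,
    make_two_domain_structure,
)


@pytest.fixture(scope="session")
def two_domain():
    """Synthetic two-domain fixture with its construction truth record."""
    return make_two_domain_structure(seed=0)


@pytest.fixture(scope="session")
def two_domain_bonds(two_domain):
    structure, _ = two_domain
    return infer_covalent_bonds(structure)


@pytest.fixture(scope="session")
def planted_small():
    """A short planted trajectory shared by the geometry tests."""
    return make_planted_trajectory(PlantedTrajectorySpec(n_frames=300, seed=11))


def make_point_structure(coords, elements=None, resids=None, names=None):
    """Tiny ad-hoc structure from raw coordinates (test helper)."""
    coords = np.atleast_2d(np.asarray(coords, float))
    n = coords.shape[0]
    elements = elements or ["C"] * n
    resids = resids or list(range(1, n + 1))
    names = names or [f"{e.upper()}{i+1}" for i, e in enumerate(elements)]
    atoms = [
        Atom(i + 1, names[i], elements[i], "UNK", resids[i], "A", coords[i])
        for i in range(n)
    ]
    return Structure(atoms=atoms)


def make_point_trajectory(frames, elements=None):
    frames = [np.atleast_2d(np.asarray(f, float)) for f in frames]
    topo = make_point_structure(frames[0], elements=elements)
    return Trajectory(topology=topo, frames=frames)


@pytest.fixture
def point_structure_factory():
    return make_point_structure


@pytest.fixture
def point_trajectory_factory():
    return make_point_trajectory
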