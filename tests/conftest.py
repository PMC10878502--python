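import numpy as np
import pytest
from hypothesis import settings

from bindscape.trajectory_io import Particle, Topology, Trajectory

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_topology(spec):
    """Build a Topology from (name, resid[, resname, chain, domain, flexible]) rows."""
    particles = []
    for i, row in enumerate(spec):
        row = tuple(row) + ("GLY", "A", "", False)[len(row) - 2 :]
        particles.append(Particle(i, *row))
    return Topology(particles)


@pytest.fixture
def two_chain_topology():
    """Chain A: 2 residues x 1 particle; chain B: 2 residues x 1 particle."""
    return make_topology(
        [
            ("BB", 1, "ALA", "A", "core"),
            ("BB", 2, "ALA", "A", "core"),
            ("BB", 1, "GLY", "B", "receptor"),
            ("BB", 2, "GLY", "B", "receptor"),
        ]
    )


def static_trajectory(topology, coords, n_frames=10, dt=0.1, replica_id=0):
    coords = np.asarray(coords, dtype=float)
    return Trajectory(
        topology=topology,
        coordinates=np.repeat(coords[None, :, :], n_frames, axis=0),
        dt=dt,
        replica_id=replica_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
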