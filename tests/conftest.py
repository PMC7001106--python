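import numpy as np
import pytest

from memsite.core import MembraneSystem, Role, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_system(positions, roles=None, species=None, labels=None, chains=None,
                box=(10.0, 10.0, 10.0)):
    """Small helper: system from raw positions with per-particle tags."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    particles = []
    for i in range(n):
        particles.append({
            "id": i,
            "role": (roles[i] if roles is not None else Role.LIPID_HEAD),
            "species": (species[i] if species is not None else "PIP2"),
            "residue_label": (labels[i] if labels is not None else ""),
            "chain": (chains[i] if chains is not None else "A"),
        })
    return MembraneSystem.from_particles(particles, positions,
                                         np.asarray(box, dtype=float))


def make_traj(coords_per_frame, dt=1.0, **kwargs):
    """Trajectory from a (F, N, 3) array via make_system for frame 0."""
    coords = np.asarray(coords_per_frame, dtype=float)
    system = make_system(coords[0], **kwargs)
    times = np.arange(coords.shape[0]) * dt
    return Trajectory(system=system, times=times, coords=coords)
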