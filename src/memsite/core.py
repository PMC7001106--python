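"""Core domain types: particles, systems, frames, trajectories, and
periodic-boundary geometry.

A :class:`MembraneSystem` is a table of particles (id, role, species,
residue label, chain) plus an initial configuration and a periodic box.
A :class:`Trajectory` stacks frames over that fixed particle table.

Periodicity applies to the membrane-plane axes (x, y) by default; the z
axis is non-periodic because the synthetic dynamics is quasi-two-
dimensional (lipids diffuse laterally, leaflets keep their z level).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Role",
    "MembraneSystem",
    "Frame",
    "Trajectory",
    "InvalidGeometryError",
    "min_image_displacement",
    "min_image_distance",
    "DEFAULT_PERIODIC_AXES",
]

DEFAULT_PERIODIC_AXES = (0, 1)


class InvalidGeometryError(ValueError):
    """Raised for non-positive box edges and similar geometry defects."""


class Role(str, Enum):
    """What a particle stands for in the reduced membrane model."""

    PROTEIN = "protein"
    LIPID_HEAD = "lipid_head"
    LIPID_TAIL = "lipid_tail"
    LIGAND = "ligand"
    SITE_ANCHOR = "site_anchor"


def min_image_displacement(
    a: np.ndarray,
    b: np.ndarray,
    box: np.ndarray,
    periodic_axes: Iterable[int] = DEFAULT_PERIODIC_AXES,
) -> np.ndarray:
    """Minimum-image displacement ``a - b`` under an orthorhombic box.

    Parameters
    ----------
    a, b
        Coordinate arrays (..., ndim) in nm.
    box
        Box edge lengths, one per coordinate dimension (nm).
    periodic_axes
        Axes to wrap; remaining components are plain differences.

    Returns
    -------
    Displacement with every periodic component in [-L/2, L/2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise InvalidGeometryError(f"box edges must be positive, got {box}")
    d = a - b
    for ax in periodic_axes:
        L = box[ax]
        d[..., ax] -= L * np.floor(d[..., ax] / L + 0.5)
    return d


def min_image_distance(
    a: np.ndarray,
    b: np.ndarray,
    box: np.ndarray,
    periodic_axes: Iterable[int] = DEFAULT_PERIODIC_AXES,
) -> np.ndarray:
    """Euclidean norm of the minimum-image displacement."""
    d = min_image_displacement(a, b, box, periodic_axes)
    return np.linalg.norm(d, axis=-1)


@dataclass
class MembraneSystem:
    """Particle table plus an initial configuration.

    ``coordinates`` holds the starting configuration (N, 3) in nm;
    ``box`` the orthorhombic edge lengths (3,) in nm.  Particle ids must
    be unique.  ``site_anchor`` and ``protein`` particles are immobile
    in the synthetic dynamics.
    """

    ids: np.ndarray
    roles: np.ndarray  # array of Role values (object dtype)
    species: np.ndarray  # str
    residue_labels: np.ndarray  # str, e.g. "R504"
    chains: np.ndarray  # str
    coordinates: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.ids)
        if len(np.unique(self.ids)) != n:
            raise ValueError("particle ids must be unique within a system")
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{n} particles"
            )
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise InvalidGeometryError(f"invalid box: {self.box}")
        for name in ("roles", "species", "residue_labels", "chains"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)

    @property
    def n_particles(self) -> int:
        return len(self.ids)

    def select(self, role: Role | None = None, species: str | Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask of particles matching a role and/or species."""
        mask = np.ones(self.n_particles, dtype=bool)
        if role is not None:
            mask &= np.array([r == role for r in self.roles])
        if species is not None:
            if isinstance(species, str):
                species = [species]
            wanted = set(species)
            mask &= np.array([s in wanted for s in self.species])
        return mask

    def mobile_mask(self) -> np.ndarray:
        """Particles free to move: everything but protein and anchors."""
        return np.array(
            [r not in (Role.PROTEIN, Role.SITE_ANCHOR) for r in self.roles]
        )

    @classmethod
    def from_particles(
        cls,
        particles: Sequence[dict],
        coordinates: np.ndarray,
        box: np.ndarray,
    ) -> "MembraneSystem":
        """Build from a list of per-particle dicts (missing keys defaulted)."""
        n = len(particles)
        return cls(
            ids=np.array([p.get("id", i) for i, p in enumerate(particles)]),
            roles=np.array([Role(p.get("role", Role.LIPID_HEAD)) for p in particles], dtype=object),
            species=np.array([p.get("species", "") for p in particles], dtype=object),
            residue_labels=np.array([p.get("residue_label", "") for p in particles], dtype=object),
            chains=np.array([p.get("chain", "") for p in particles], dtype=object),
            coordinates=np.asarray(coordinates, dtype=float).reshape(n, 3),
            box=box,
        )


@dataclass
class Frame:
    """A single stored configuration."""

    time: float  # ns
    coordinates: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise InvalidGeometryError(f"invalid box: {self.box}")


@dataclass
class Trajectory:
    """Stacked frames over one particle table.

    ``coords`` has shape (n_frames, n_particles, 3); ``times`` must be
    strictly increasing and uniformly spaced.  Coordinates are stored
    unwrapped (diffusive observables such as the MSD need them); all
    distance computations apply the minimum-image convention instead.
    """

    system: MembraneSystem
    times: np.ndarray  # (F,) ns
    coords: np.ndarray  # (F, N, 3) nm
    boxes: np.ndarray | None = None  # (F, 3) nm; defaults to system.box

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.system.n_particles:
            raise ValueError(
                "coords must be (n_frames, n_particles, 3) matching the system"
            )
        if len(self.times) != len(self.coords):
            raise ValueError("times and coords frame counts differ")
        if len(self.times) >= 2:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame times must be uniformly spaced")
        if self.boxes is None:
            self.boxes = np.tile(self.system.box, (len(self.times), 1))
        else:
            self.boxes = np.asarray(self.boxes, dtype=float)
            if self.boxes.shape != (len(self.times), 3):
                raise ValueError("boxes must be (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Time between stored frames (ns); 0 for a single frame."""
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), coordinates=self.coords[i], box=self.boxes[i])
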