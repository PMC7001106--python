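"""Analytic in-plane potentials: planted binding wells, the protein
footprint wall, and harmonic biases.

All terms act on the membrane-plane coordinates (x, y) only; energies
are kJ/mol, forces kJ/mol/nm.  Displacements from anchors use the
minimum-image convention in the plane so wells behave correctly in
small periodic boxes.

The planted Gaussian well is the package's ground truth: a radial
attraction U(r) = -D0 exp(-r^2 / 2 sigma^2) whose amplitude D0 plays
the role of the binding free energy to be recovered by the umbrella /
WHAM and alchemical machinery downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import MembraneSystem, Role

__all__ = [
    "GaussianWell",
    "ProteinCoreWall",
    "HarmonicPoint",
    "FlatBottomRestraint",
    "UmbrellaBias",
    "LateralRestraint",
    "AlchemicalMix",
    "system_force_function",
    "total_energy",
]


def _plane_disp(xy: np.ndarray, anchor: np.ndarray, box_xy: np.ndarray | None) -> np.ndarray:
    d = np.asarray(xy, dtype=float) - np.asarray(anchor, dtype=float)
    if box_xy is not None:
        d = d - box_xy * np.floor(d / box_xy + 0.5)
    return d


@dataclass
class GaussianWell:
    """Radial attractive well, U(r) = -depth * exp(-r^2 / (2 sigma^2)).

    ``affected_species`` limits which lipid species feel the well
    (None = every mobile particle), mirroring per-species binding-site
    selectivity.
    """

    anchor: np.ndarray  # (2,) nm, in-plane site center
    depth: float  # kJ/mol, >= 0 (magnitude of the attraction)
    sigma: float  # nm
    affected_species: frozenset | None = None

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        if self.sigma <= 0:
            raise ValueError(f"well width sigma must be positive, got {self.sigma}")
        if self.depth < 0:
            raise ValueError(f"well depth must be >= 0 (magnitude), got {self.depth}")
        if self.affected_species is not None:
            self.affected_species = frozenset(self.affected_species)

    def energy(self, xy: np.ndarray, box_xy: np.ndarray | None = None) -> np.ndarray:
        d = _plane_disp(xy, self.anchor, box_xy)
        r2 = np.sum(d * d, axis=-1)
        return -self.depth * np.exp(-r2 / (2.0 * self.sigma**2))

    def force(self, xy: np.ndarray, box_xy: np.ndarray | None = None) -> np.ndarray:
        d = _plane_disp(xy, self.anchor, box_xy)
        r2 = np.sum(d * d, axis=-1, keepdims=True)
        g = np.exp(-r2 / (2.0 * self.sigma**2))
        return -(self.depth / self.sigma**2) * d * g


@dataclass
class ProteinCoreWall:
    """Soft radial wall keeping lipids out of the protein footprint.

    Harmonic repulsion for r < radius (zero outside); binding wells sit
    at the rim of this wall the way the S3/S4/S5 pocket sits at the
    protein surface.
    """

    center: np.ndarray  # (2,) nm
    radius: float  # nm
    k: float = 500.0  # kJ/mol/nm^2
    affected_species: frozenset | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0 or self.k < 0:
            raise ValueError("wall radius must be > 0 and k >= 0")

    def energy(self, xy: np.ndarray, box_xy: np.ndarray | None = None) -> np.ndarray:
        d = _plane_disp(xy, self.center, box_xy)
        r = np.linalg.norm(d, axis=-1)
        pen = np.maximum(self.radius - r, 0.0)
        return 0.5 * self.k * pen**2

    def force(self, xy: np.ndarray, box_xy: np.ndarray | None = None) -> np.ndarray:
        d = _plane_disp(xy, self.center, box_xy)
        r = np.linalg.norm(d, axis=-1, keepdims=True)
        pen = np.maximum(self.radius - r, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r > 1e-12, d / r, 0.0)
        return self.k * pen * unit  # outward push


@dataclass
class HarmonicPoint:
    """Isotropic harmonic hold at an anchor, U = k/2 * r^2."""

    anchor: np.ndarray
    k: float
    affected_species: frozenset | None = None

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        if self.k < 0:
            raise ValueError("force constant must be >= 0")

    def energy(self, xy, box_xy=None):
        d = _plane_disp(xy, self.anchor, box_xy)
        return 0.5 * self.k * np.sum(d * d, axis=-1)

    def force(self, xy, box_xy=None):
        d = _plane_disp(xy, self.anchor, box_xy)
        return -self.k * d


@dataclass
class FlatBottomRestraint:
    """Zero inside ``radius`` around the anchor, harmonic beyond.

    Used to give the bound state a finite, well-defined volume in
    alchemical runs without perturbing the well region.
    """

    anchor: np.ndarray
    radius: float
    k: float
    affected_species: frozenset | None = None

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        if self.radius < 0 or self.k < 0:
            raise ValueError("flat-bottom radius and k must be >= 0")

    def energy(self, xy, box_xy=None):
        d = _plane_disp(xy, self.anchor, box_xy)
        r = np.linalg.norm(d, axis=-1)
        exc = np.maximum(r - self.radius, 0.0)
        return 0.5 * self.k * exc**2

    def force(self, xy, box_xy=None):
        d = _plane_disp(xy, self.anchor, box_xy)
        r = np.linalg.norm(d, axis=-1, keepdims=True)
        exc = np.maximum(r - self.radius, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r > 1e-12, d / r, 0.0)
        return -self.k * exc * unit


@dataclass
class UmbrellaBias:
    """Harmonic umbrella on the signed in-plane projection.

    s = (xy - anchor) . axis; U = k/2 (s - center)^2.  ``center`` may
    be a scalar or an array broadcast against leading dims of ``xy``
    (one center per simultaneously integrated window).
    """

    anchor: np.ndarray
    axis: np.ndarray  # unit 2-vector
    center: float | np.ndarray
    k: float
    affected_species: frozenset | None = None

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError(f"umbrella axis must be a unit vector, |axis| = {n}")
        if self.k < 0:
            raise ValueError("force constant must be >= 0")

    def coordinate(self, xy, box_xy=None):
        d = _plane_disp(xy, self.anchor, box_xy)
        return np.sum(d * self.axis, axis=-1)

    def energy(self, xy, box_xy=None):
        s = self.coordinate(xy, box_xy)
        return 0.5 * self.k * (s - self.center) ** 2

    def force(self, xy, box_xy=None):
        s = self.coordinate(xy, box_xy)
        return (-self.k * (s - self.center))[..., None] * self.axis


@dataclass
class LateralRestraint:
    """Harmonic restraint on the off-axis component, U = k/2 * y^2,
    with y = (xy - anchor) . axis_perp.  Keeps the pulled lipid near
    the reaction-coordinate axis, as in umbrella protocols that
    restrain motion along the box Y axis."""

    anchor: np.ndarray
    axis_perp: np.ndarray  # unit 2-vector orthogonal to the RC axis
    k: float
    affected_species: frozenset | None = None

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.axis_perp = np.asarray(self.axis_perp, dtype=float)
        if not np.isclose(np.linalg.norm(self.axis_perp), 1.0, atol=1e-8):
            raise ValueError("lateral axis must be a unit vector")
        if self.k < 0:
            raise ValueError("force constant must be >= 0")

    def coordinate(self, xy, box_xy=None):
        d = _plane_disp(xy, self.anchor, box_xy)
        return np.sum(d * self.axis_perp, axis=-1)

    def energy(self, xy, box_xy=None):
        y = self.coordinate(xy, box_xy)
        return 0.5 * self.k * y**2

    def force(self, xy, box_xy=None):
        y = self.coordinate(xy, box_xy)
        return (-self.k * y)[..., None] * self.axis_perp


@dataclass
class AlchemicalMix:
    """Linear interpolation U_lam = (1 - lam) U_A + lam U_B between two
    site potentials; U_0 = U_A, U_1 = U_B exactly."""

    U_A: GaussianWell
    U_B: GaussianWell
    lam: float
    affected_species: frozenset | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")

    def energy(self, xy, box_xy=None):
        return (1.0 - self.lam) * self.U_A.energy(xy, box_xy) + self.lam * self.U_B.energy(xy, box_xy)

    def force(self, xy, box_xy=None):
        return (1.0 - self.lam) * self.U_A.force(xy, box_xy) + self.lam * self.U_B.force(xy, box_xy)


def _term_mask(term, system: MembraneSystem) -> np.ndarray:
    mask = system.mobile_mask()
    if getattr(term, "affected_species", None) is not None:
        sp = term.affected_species
        mask = mask & np.array([s in sp for s in system.species])
    return mask


def system_force_function(
    system: MembraneSystem,
    terms: Sequence,
) -> Callable[[np.ndarray], np.ndarray]:
    """Build ``f(xy) -> forces`` for all particles of a system.

    Per-term species masks are resolved once; immobile particles
    (protein, site anchors) always receive zero force.
    """
    box_xy = system.box[:2]
    masks = [_term_mask(t, system) for t in terms]
    mobile = system.mobile_mask()

    def force(xy: np.ndarray) -> np.ndarray:
        out = np.zeros_like(xy)
        for term, mask in zip(terms, masks):
            if mask.any():
                out[mask] += term.force(xy[mask], box_xy)
        out[~mobile] = 0.0
        return out

    return force


def total_energy(system: MembraneSystem, terms: Sequence, xy: np.ndarray) -> float:
    """Sum of all term energies for a configuration (kJ/mol)."""
    box_xy = system.box[:2]
    e = 0.0
    for term in terms:
        mask = _term_mask(term, system)
        if mask.any():
            e += float(np.sum(term.energy(xy[mask], box_xy)))
    return e
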