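"""Synthetic membrane systems with known ground truth.

This module is the stand-in for cluster-scale coarse-grained membrane
simulations: it builds mixed-composition bilayers, plants radial
binding wells of configurable depth at four symmetry-related sites on
a model protein footprint, and manufactures small deterministic
fixtures for the geometry analyses.  Because every well depth and site
anchor is chosen explicitly, downstream estimators (density mapping,
umbrella/WHAM, alchemical MBAR) can be verified against exact ground
truth.

The default bilayer composition is the in-vivo mimetic mixture used
for channel-lipid interaction studies: outer leaflet
PC:PE:SM:GM3:CHOL = 40:10:15:10:25 and inner leaflet
PC:PE:PS:PIP2:CHOL = 10:40:15:10:25, which puts the overall PIP2 mole
fraction at 5% of all lipids -- within the physiological range for a
mammalian plasma membrane.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MembraneSystem, Role, Trajectory
from .potentials import GaussianWell, ProteinCoreWall

__all__ = [
    "OUTER_COMPOSITION",
    "INNER_COMPOSITION",
    "BilayerSpec",
    "largest_remainder_counts",
    "build_bilayer",
    "make_planted_site_system",
    "make_geometry_fixtures",
]

#: Outer (extracellular / luminal) leaflet mole fractions.
OUTER_COMPOSITION = {"PC": 0.40, "PE": 0.10, "SM": 0.15, "GM3": 0.10, "CHOL": 0.25}
#: Inner (intracellular) leaflet mole fractions.
INNER_COMPOSITION = {"PC": 0.10, "PE": 0.40, "PS": 0.15, "PIP2": 0.10, "CHOL": 0.25}

#: Basic residues lining the phosphoinositide site (per protein chain),
#: and a few distal residues used as negative controls in contact
#: statistics.
SITE_RESIDUES = ["R504", "K572", "K575", "R592", "K595"]
DISTAL_RESIDUES = ["A550", "L517", "Q557"]


@dataclass
class BilayerSpec:
    """Per-leaflet species mole fractions plus box geometry.

    Fractions of each leaflet must sum to 1 (within 1e-9) and be
    non-negative.
    """

    leaflets: dict = field(default_factory=lambda: {
        "outer": dict(OUTER_COMPOSITION),
        "inner": dict(INNER_COMPOSITION),
    })
    lipids_per_leaflet: int = 200
    box: tuple = (12.0, 12.0, 6.0)

    def __post_init__(self) -> None:
        if self.lipids_per_leaflet < 1:
            raise ValueError("lipids_per_leaflet must be >= 1")
        for name, fracs in self.leaflets.items():
            if any(f < 0 for f in fracs.values()):
                raise ValueError(f"leaflet {name!r}: negative mole fraction")
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"leaflet {name!r}: mole fractions sum to {total}, not 1"
                )
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ValueError(f"invalid box {self.box}")


def largest_remainder_counts(fractions: dict, n: int) -> dict:
    """Integer species counts by largest-remainder rounding.

    Exact quotas fraction*n are floored; remaining slots go to the
    largest fractional remainders, ties broken by species name order so
    builds are deterministic.
    """
    names = sorted(fractions)
    quotas = {s: fractions[s] * n for s in names}
    counts = {s: int(np.floor(quotas[s] + 1e-12)) for s in names}
    short = n - sum(counts.values())
    remainders = sorted(names, key=lambda s: (-(quotas[s] - counts[s]), s))
    for s in remainders[:short]:
        counts[s] += 1
    return counts


def _place_in_plane(
    rng: np.random.Generator,
    n: int,
    box_xy: np.ndarray,
    min_spacing: float,
    exclude_center: np.ndarray | None,
    exclude_radius: float,
) -> np.ndarray:
    """Uniform non-overlapping points in the leaflet plane (rejection)."""
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place lipids without overlap; lower min_spacing "
                "or lipid count"
            )
        p = rng.uniform(0.0, box_xy, size=2)
        if exclude_center is not None:
            d = p - exclude_center
            d -= box_xy * np.floor(d / box_xy + 0.5)
            if np.hypot(*d) < exclude_radius:
                continue
        if placed:
            d = pts[:placed] - p
            d -= box_xy * np.floor(d / box_xy + 0.5)
            if np.min(np.hypot(d[:, 0], d[:, 1])) < min_spacing:
                continue
        pts[placed] = p
        placed += 1
    return pts


def build_bilayer(
    spec: BilayerSpec,
    seed: int = 0,
    min_spacing: float = 0.3,
    protein_radius: float | None = None,
) -> MembraneSystem:
    """Build a two-leaflet membrane system from a composition spec.

    Species counts per leaflet follow largest-remainder rounding of
    fraction * lipids_per_leaflet; positions are uniform in each
    leaflet plane with no two lipids closer than ``min_spacing`` and,
    if ``protein_radius`` is given, outside the central protein
    footprint.  The leaflet is recorded in the particle ``chain`` field.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(spec.box, dtype=float)
    center = box[:2] / 2.0
    z_levels = {"outer": box[2] / 2.0 + 1.0, "inner": box[2] / 2.0 - 1.0}
    particles, coords = [], []
    for leaflet in spec.leaflets:
        counts = largest_remainder_counts(spec.leaflets[leaflet], spec.lipids_per_leaflet)
        n_leaflet = sum(counts.values())
        pts = _place_in_plane(
            rng, n_leaflet, box[:2], min_spacing,
            center if protein_radius else None, protein_radius or 0.0,
        )
        i = 0
        for species in sorted(counts):
            for _ in range(counts[species]):
                particles.append({
                    "id": len(particles),
                    "role": Role.LIPID_HEAD,
                    "species": species,
                    "residue_label": "",
                    "chain": leaflet,
                })
                coords.append([pts[i, 0], pts[i, 1], z_levels.get(leaflet, box[2] / 2.0)])
                i += 1
    return MembraneSystem.from_particles(particles, np.array(coords), box)


def _four_fold_anchors(center: np.ndarray, radius: float) -> np.ndarray:
    """Four site anchors related by 90-degree rotation about the center."""
    angles = np.deg2rad([0.0, 90.0, 180.0, 270.0])
    return center + radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)


def make_planted_site_system(
    depth: float,
    sigma: float,
    species: str = "PIP2",
    four_fold: bool = False,
    box: tuple = (12.0, 12.0, 6.0),
    site_radius: float = 2.0,
    with_protein: bool = False,
    wall_k: float = 500.0,
    n_lipids: int | None = None,
    start: str = "bound",
    seed: int = 0,
) -> tuple[MembraneSystem, list]:
    """System with planted Gaussian binding wells of known depth.

    Parameters
    ----------
    depth, sigma
        Well magnitude (kJ/mol, >= 0) and width (nm); the potential at
        each anchor is exactly -depth.
    species
        Lipid species that feels the wells.
    four_fold
        If True, four wells related by 90-degree rotations about the
        box center at ``site_radius`` -- the tetramer mimic.  If False,
        a single well at the box center (the dilute single-site setup
        used for umbrella sampling, with no obstructing wall).
    with_protein
        Add a protein footprint: a soft radial wall potential of
        stiffness ``wall_k`` with radius ``site_radius`` plus labeled
        protein particles -- the five basic site residues clustered at
        each well anchor and a few distal control residues -- one chain
        per subunit.
    n_lipids, start
        Number of lipids of ``species`` (default: one per well) and
        whether they start ``"bound"`` (at the anchors) or
        ``"random"`` in the plane.

    Returns
    -------
    (system, potentials) where potentials contains the wells (and the
    wall when ``with_protein``).
    """
    if depth < 0:
        raise ValueError("well depth must be >= 0 (magnitude of attraction)")
    if sigma <= 0:
        raise ValueError(f"well width sigma must be positive, got {sigma}")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    center = box[:2] / 2.0
    z_mid = box[2] / 2.0
    anchors = _four_fold_anchors(center, site_radius) if four_fold else center[None, :]

    wells = [
        GaussianWell(anchor=a, depth=depth, sigma=sigma,
                     affected_species=frozenset({species}))
        for a in anchors
    ]
    potentials: list = list(wells)

    particles, coords = [], []
    for j, a in enumerate(anchors):
        particles.append({
            "id": len(particles), "role": Role.SITE_ANCHOR, "species": "ANCHOR",
            "residue_label": f"ANC{j + 1}", "chain": "ABCD"[j % 4],
        })
        coords.append([a[0], a[1], z_mid])

    if with_protein:
        potentials.append(ProteinCoreWall(center=center, radius=site_radius, k=wall_k))
        for j, a in enumerate(anchors):
            chain = "ABCD"[j % 4]
            outward = (a - center)
            norm = np.linalg.norm(outward)
            outward = outward / norm if norm > 1e-12 else np.array([1.0, 0.0])
            # five basic residues clustered at the rim around the anchor
            for m, label in enumerate(SITE_RESIDUES):
                ang = (m - 2) * 0.12  # ~7-degree steps along the rim
                rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
                pos = center + (site_radius + 0.1) * (rot @ outward)
                particles.append({
                    "id": len(particles), "role": Role.PROTEIN, "species": "PROT",
                    "residue_label": label, "chain": chain,
                })
                coords.append([pos[0], pos[1], z_mid])
            # distal control residues a quarter-turn away from the site
            rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])
            for m, label in enumerate(DISTAL_RESIDUES):
                ang = 0.7 + 0.15 * m
                rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
                pos = center + (site_radius + 0.1) * (rot @ outward)
                particles.append({
                    "id": len(particles), "role": Role.PROTEIN, "species": "PROT",
                    "residue_label": label, "chain": chain,
                })
                coords.append([pos[0], pos[1], z_mid])

    n_lip = len(anchors) if n_lipids is None else n_lipids
    z_lip = z_mid - 1.0  # inner leaflet level
    for i in range(n_lip):
        if start == "bound" and i < len(anchors):
            pos = anchors[i]
        else:
            pos = rng.uniform(0.0, box[:2])
        particles.append({
            "id": len(particles), "role": Role.LIPID_HEAD, "species": species,
            "residue_label": "", "chain": "inner",
        })
        coords.append([pos[0], pos[1], z_lip])

    system = MembraneSystem.from_particles(particles, np.array(coords), box)
    return system, potentials


def make_geometry_fixtures(kind: str, seed: int = 0, drift: float = 0.2,
                           n_frames: int = 101) -> Trajectory:
    """Deterministic small trajectories for the geometry analyses.

    ``kind="hbond"``: a static system containing exactly two geometric
    hydrogen bonds (collinear donor-H...acceptor at 0.28 nm, and a
    20-degree bent one at 0.30 nm) plus decoys that fail either the
    distance or the angle criterion.

    ``kind="ligand_pose"``: a rigid protein scaffold with four ligand
    copies whose scripted motions differ per copy -- one static, one
    stepping by ``drift`` nm at the midpoint frame, two with small /
    large thermal jitter -- all under a global rigid drift of the whole
    system so superposition onto the reference frame is actually
    exercised.  ``drift=0`` with zero jitter would leave every RMSD
    series identically zero.
    """
    if kind == "hbond":
        return _hbond_fixture(n_frames=3)
    if kind == "ligand_pose":
        return _ligand_pose_fixture(seed=seed, drift=drift, n_frames=n_frames)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _hbond_fixture(n_frames: int) -> Trajectory:
    box = np.array([6.0, 6.0, 6.0])
    rows = []  # (species, residue_label, xyz)
    # bond 1: collinear D-H...A, d(D,A) = 0.28 nm
    rows += [("DON", "R504", [1.0, 1.0, 1.0]),
             ("HYD", "R504", [1.1, 1.0, 1.0]),
             ("ACC", "LIP", [1.28, 1.0, 1.0])]
    # bond 2: d(D,A) = 0.30 nm, D-H...A deviation 20 degrees
    h2 = np.array([2.0 + 0.1 * np.cos(np.deg2rad(20.0)),
                   2.0 + 0.1 * np.sin(np.deg2rad(20.0)), 1.0])
    rows += [("DON", "K572", [2.0, 2.0, 1.0]),
             ("HYD", "K572", list(h2)),
             ("ACC", "LIP", [2.30, 2.0, 1.0])]
    # decoy 1: collinear but too far (0.50 nm)
    rows += [("DON", "K575", [3.5, 1.0, 1.0]),
             ("HYD", "K575", [3.6, 1.0, 1.0]),
             ("ACC", "LIP", [4.0, 1.0, 1.0])]
    # decoy 2: close (0.30 nm) but bent by 60 degrees
    h4 = np.array([4.5 + 0.1 * np.cos(np.deg2rad(60.0)),
                   4.5 + 0.1 * np.sin(np.deg2rad(60.0)), 1.0])
    rows += [("DON", "R592", [4.5, 4.5, 1.0]),
             ("HYD", "R592", list(h4)),
             ("ACC", "LIP", [4.8, 4.5, 1.0])]
    particles = []
    coords = []
    role_for = {"DON": Role.PROTEIN, "HYD": Role.PROTEIN, "ACC": Role.LIPID_HEAD}
    for i, (sp, lab, xyz) in enumerate(rows):
        particles.append({"id": i, "role": role_for[sp], "species": sp,
                          "residue_label": lab, "chain": "A"})
        coords.append(xyz)
    system = MembraneSystem.from_particles(particles, np.array(coords), box)
    frames = np.tile(system.coordinates, (n_frames, 1, 1))
    times = np.arange(n_frames) * 1.0
    return Trajectory(system=system, times=times, coords=frames)


def _ligand_pose_fixture(seed: int, drift: float, n_frames: int) -> Trajectory:
    rng = np.random.default_rng(seed)
    box = np.array([10.0, 10.0, 10.0])
    protein = np.array([
        [4.0, 4.0, 4.0], [6.0, 4.0, 4.2], [6.0, 6.0, 4.0], [4.0, 6.0, 4.3],
        [5.0, 5.0, 6.0], [4.5, 5.5, 5.0], [5.5, 4.5, 5.0], [5.0, 4.2, 5.5],
    ])
    lig_template = np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0], [0.0, 0.3, 0.1]])
    offsets = np.array([[3.0, 5.0, 5.0], [7.0, 5.0, 5.0], [5.0, 3.0, 5.0], [5.0, 7.0, 5.0]])
    particles = []
    for i in range(len(protein)):
        particles.append({"id": i, "role": Role.PROTEIN, "species": "PROT",
                          "residue_label": f"P{i + 1}", "chain": "A"})
    for c in range(4):
        for a in range(len(lig_template)):
            particles.append({
                "id": len(particles), "role": Role.LIGAND, "species": "CHOL",
                "residue_label": f"CHOL{c + 1}", "chain": f"L{c + 1}",
            })
    # per-copy rigid-jitter amplitudes scale with the drift so that
    # drift=0 gives identically static ligand copies: static, step,
    # small jitter, large jitter
    jitter = [0.0, 0.0, 0.1 * drift, 0.5 * drift]
    step_frame = n_frames // 2
    frames = []
    for f in range(n_frames):
        # global rigid motion: slow rotation about z plus translation
        ang = 0.002 * f
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                       [np.sin(ang), np.cos(ang), 0.0],
                       [0.0, 0.0, 1.0]])
        shift = np.array([0.005 * f, -0.003 * f, 0.002 * f])
        pivot = np.array([5.0, 5.0, 5.0])
        lig = []
        for c in range(4):
            base = lig_template + offsets[c]
            if c == 1 and f >= step_frame and drift:
                base = base + np.array([drift, 0.0, 0.0])
            if jitter[c]:
                # rigid jitter (translation only) so the copy's internal
                # geometry is preserved
                base = base + jitter[c] * rng.standard_normal(3)
            lig.append(base)
        all_xyz = np.vstack([protein] + lig)
        all_xyz = (all_xyz - pivot) @ Rz.T + pivot + shift
        frames.append(all_xyz)
    coords = np.array(frames)
    system = MembraneSystem.from_particles(particles, coords[0], box)
    times = np.arange(n_frames) * 1.0
    return Trajectory(system=system, times=times, coords=coords)
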