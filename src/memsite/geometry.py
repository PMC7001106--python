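"""Geometric characterization of bound lipids: hydrogen bonds and
superposition-based ligand RMSD series.

Hydrogen bonds use the standard geometric criterion: donor-acceptor
distance at most 0.35 nm and donor-H...acceptor deviation from
linearity at most 30 degrees (0 degrees = perfectly linear; stated
explicitly to avoid the equivalent "angle >= 150 degrees" convention).
Distances are minimum-image.

Ligand RMSD follows the usual bound-ligand stability analysis: each
frame's protein particles are least-squares superposed onto a
reference frame, the transform is applied to the whole frame, and each
ligand copy's RMSD against its reference pose is reported with no
fitting on the ligand itself -- so a loosely bound copy shows large
fluctuations while a stable one stays near zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import MembraneSystem, Role, Trajectory, min_image_displacement

__all__ = [
    "HBondCriterion",
    "detect_hbonds",
    "hbond_series",
    "superpose",
    "ligand_rmsd_series",
    "RMSDSeries",
]


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition."""

    max_distance: float = 0.35  # nm, donor-acceptor
    max_angle: float = 30.0  # degrees, D-H...A deviation from linear

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not 0.0 < self.max_angle <= 90.0:
            raise ValueError("max_angle must lie in (0, 90] degrees")


def detect_hbonds(
    coords: np.ndarray,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    box: np.ndarray,
    criterion: HBondCriterion | None = None,
) -> list[tuple[int, int]]:
    """Geometric H-bond detection in one frame.

    ``donors`` and ``hydrogens`` are parallel index arrays (hydrogen i
    is bonded to donor i); every donor-acceptor pair is tested.
    Returns (donor_index, acceptor_index) pairs satisfying the
    criterion.  All axes are treated as periodic here so the detection
    is invariant under global translation in any direction.
    """
    criterion = criterion or HBondCriterion()
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.shape != hydrogens.shape:
        raise ValueError("each hydrogen needs its donor parent (parallel arrays)")
    box = np.asarray(box, dtype=float)
    axes = (0, 1, 2)
    bonds = []
    for d, h in zip(donors, hydrogens):
        da = min_image_displacement(coords[acceptors], coords[d][None, :], box, axes)
        dist = np.linalg.norm(da, axis=1)
        dh = min_image_displacement(coords[h], coords[d], box, axes)
        ha = min_image_displacement(coords[acceptors], coords[h][None, :], box, axes)
        ha_norm = np.linalg.norm(ha, axis=1)
        dh_norm = np.linalg.norm(dh)
        with np.errstate(invalid="ignore", divide="ignore"):
            # deviation from linearity: angle between D->H and H->A
            cosang = (ha @ dh) / (ha_norm * dh_norm)
        dev = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = (dist <= criterion.max_distance) & (dev <= criterion.max_angle)
        bonds.extend((int(d), int(acceptors[j])) for j in np.flatnonzero(ok))
    return bonds


def _dha_indices(system: MembraneSystem, residue_set, lipid_selection):
    """Resolve donor/hydrogen/acceptor indices from species tags.

    Donors are species 'DON', their hydrogens 'HYD' (paired within a
    residue, in order), acceptors are the lipid head-group particles.
    """
    donors, hydrogens = [], []
    for i in range(system.n_particles):
        if system.species[i] == "DON" and (residue_set is None or
                                           system.residue_labels[i] in residue_set):
            donors.append(i)
    for d in donors:
        # hydrogen: next HYD particle of the same residue
        cand = [i for i in range(system.n_particles)
                if system.species[i] == "HYD"
                and system.residue_labels[i] == system.residue_labels[d]
                and system.chains[i] == system.chains[d]]
        if not cand:
            raise ValueError(
                f"donor {system.residue_labels[d]} has no hydrogen particle"
            )
        hydrogens.append(cand[0])
    if isinstance(lipid_selection, dict):
        amask = system.select(**lipid_selection)
    elif lipid_selection is None:
        amask = np.array([s == "ACC" for s in system.species])
    else:
        amask = np.asarray(lipid_selection, dtype=bool)
    return np.array(donors, dtype=int), np.array(hydrogens, dtype=int), np.flatnonzero(amask)


def hbond_series(
    traj: Trajectory,
    residue_set=None,
    lipid_selection=None,
    criterion: HBondCriterion | None = None,
) -> pd.DataFrame:
    """Per-residue H-bond counts with the lipid head group over time.

    Returns a DataFrame indexed by time (ns) with one column per donor
    residue; an empty residue set yields an empty table (with a
    warning) rather than an error.
    """
    import warnings

    system = traj.system
    donors, hydrogens, acceptors = _dha_indices(system, residue_set, lipid_selection)
    if len(donors) == 0:
        warnings.warn("empty residue set: no donors selected")
        return pd.DataFrame(index=pd.Index(traj.times, name="time"))
    labels = [system.residue_labels[d] for d in donors]
    counts = np.zeros((traj.n_frames, len(donors)), dtype=int)
    for f in range(traj.n_frames):
        bonds = detect_hbonds(traj.coords[f], donors, hydrogens, acceptors,
                              traj.boxes[f], criterion)
        for d, _ in bonds:
            counts[f, list(donors).index(d)] += 1
    df = pd.DataFrame(counts, columns=labels,
                      index=pd.Index(traj.times, name="time"))
    if df.columns.duplicated().any():
        df = df.T.groupby(level=0).sum().T
    return df


def superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns (rotation (3,3), translation (3,), fit RMSD) such that
    ``mobile @ R.T + t`` minimizes the RMSD over the fit selection.
    The rotation is proper (determinant +1).  Degenerate fit sets
    (fewer than 3 particles, or collinear) raise.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    sel = np.arange(len(reference)) if fit_selection is None else np.asarray(fit_selection)
    ref = reference[sel]
    mob = mobile[sel]
    if len(ref) < 3:
        raise ValueError("superposition needs at least 3 fit particles")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    # collinearity: second singular value of the centered set ~ 0
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) fit selection")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - rot.apply(mob.mean(axis=0))
    rmsd = rssd / np.sqrt(len(ref))
    return R, t, float(rmsd)


@dataclass
class RMSDSeries:
    """Per-ligand-copy RMSD (nm) versus time after protein fitting."""

    times: np.ndarray
    rmsd: np.ndarray  # (n_copies, F)
    copy_labels: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rmsd.T, columns=self.copy_labels,
                            index=pd.Index(self.times, name="time"))

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, lab in enumerate(self.copy_labels):
            ax.plot(self.times, self.rmsd[i], label=lab)
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("RMSD (nm)")
        ax.legend()
        return ax


def ligand_rmsd_series(
    traj: Trajectory,
    ligand_selection: dict | np.ndarray | None = None,
    fit_selection: dict | np.ndarray | None = None,
    reference_frame: int = 0,
) -> RMSDSeries:
    """Bound-ligand RMSD traces after superposing the protein.

    Ligand copies are grouped by chain; every copy must be present in
    every frame.  The RMSD of the reference frame against itself is
    exactly zero.
    """
    system = traj.system
    if not 0 <= reference_frame < traj.n_frames:
        raise ValueError(f"reference frame {reference_frame} does not exist")
    if ligand_selection is None:
        lmask = system.select(role=Role.LIGAND)
    elif isinstance(ligand_selection, dict):
        lmask = system.select(**ligand_selection)
    else:
        lmask = np.asarray(ligand_selection, dtype=bool)
    if fit_selection is None:
        fmask = system.select(role=Role.PROTEIN)
    elif isinstance(fit_selection, dict):
        fmask = system.select(**fit_selection)
    else:
        fmask = np.asarray(fit_selection, dtype=bool)
    if not lmask.any() or not fmask.any():
        raise ValueError("empty ligand or fit selection")
    l_idx = np.flatnonzero(lmask)
    chains = system.chains[l_idx]
    copies = {c: l_idx[chains == c] for c in dict.fromkeys(chains)}
    fit_idx = np.flatnonzero(fmask)

    ref = traj.coords[reference_frame]
    F = traj.n_frames
    out = np.zeros((len(copies), F))
    for f in range(F):
        R, t, _ = superpose(ref, traj.coords[f], fit_idx)
        moved = traj.coords[f] @ R.T + t
        for ci, (label, idx) in enumerate(copies.items()):
            d = moved[idx] - ref[idx]
            out[ci, f] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return RMSDSeries(times=traj.times.copy(), rmsd=out,
                      copy_labels=list(copies))
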