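"""Readers and writers for the text formats the pipeline touches.

Supported formats:

* PDB ``ATOM``/``HETATM`` records (fixed columns, Angstrom -> converted
  to nm on read);
* GRO fixed-column records (already nm);
* the package's own plain-text multi-frame trajectory store (documented
  below) so tests and users can diff trajectories;
* OpenDX volumetric grids for occupancy density maps.

Trajectory store layout (version 1)::

    MEMTRAJ 1
    particles <N>
    <id>\t<role>\t<species>\t<residue_label>\t<chain>     (N rows)
    box <bx> <by> <bz>
    frames <F>
    frame <time_ns>
    <x> <y> <z>                                           (N rows)
    ...

Coordinates are serialized with six decimals (sub-fm precision at nm
scale); a round trip is lossless at that precision.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import TextIO

import numpy as np

from .core import Frame, MembraneSystem, Role, Trajectory

__all__ = [
    "ParseError",
    "read_coordinates",
    "write_trajectory",
    "read_trajectory",
    "write_dx",
    "read_dx",
    "write_density_map",
    "read_density_map",
]

#: species tags treated as lipids when inferring roles from PDB/GRO
#: residue names (users can override via ``role_map``).
LIPID_RESNAMES = {
    "POPC", "POPE", "POPS", "DPSM", "DPG3", "CHOL", "PC", "PE", "PS",
    "SM", "GM3", "PIP", "PIP2", "PIP3", "POP2", "POP3",
}


class ParseError(ValueError):
    """Malformed fixed-width record; message names the line number."""


def _infer_role(resname: str, role_map: dict | None) -> Role:
    if role_map and resname in role_map:
        return Role(role_map[resname])
    if resname.upper() in LIPID_RESNAMES:
        return Role.LIPID_HEAD
    return Role.PROTEIN


def read_coordinates(
    path: str | Path,
    dialect: str,
    role_map: dict | None = None,
) -> tuple[MembraneSystem, Frame]:
    """Read a single-configuration coordinate file.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"PDB"`` or ``"GRO"``.  PDB positions are Angstrom and are
        converted to nm; GRO positions are already nm.
    role_map
        Optional residue-name -> role override used when tagging
        particles; unknown residue names default to ``protein`` unless
        they look like a lipid species.

    Returns
    -------
    (system, frame) with residue labels preserved as e.g. ``"R504"``
    (one-letter code where standard, else the raw residue name, plus
    the residue number).
    """
    dialect = dialect.upper()
    if dialect not in ("PDB", "GRO"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'PDB' or 'GRO'")
    text = Path(path).read_text()
    if dialect == "GRO":
        return _read_gro(text, role_map)
    return _read_pdb(text, role_map)


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _residue_label(resname: str, resid: int) -> str:
    one = _AA3TO1.get(resname.upper())
    return f"{one}{resid}" if one else f"{resname}{resid}"


def _read_gro(text: str, role_map: dict | None) -> tuple[MembraneSystem, Frame]:
    lines = text.splitlines()
    if len(lines) < 3:
        raise ParseError("GRO file too short: needs title, count, atoms, box")
    try:
        natoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"line 2: cannot parse atom count: {lines[1]!r}") from exc
    if len(lines) < natoms + 3:
        raise ParseError(
            f"GRO file truncated: expected {natoms} atom records plus box line"
        )
    particles, coords = [], []
    for i in range(natoms):
        lineno = i + 3
        line = lines[i + 2]
        if len(line) < 44:
            raise ParseError(f"line {lineno}: GRO record too short ({len(line)} chars)")
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            # atom name (10:15) and serial (15:20) are read but the
            # serial is regenerated: internal ids are 0-based.
            xyz = [float(line[20 + 8 * k: 28 + 8 * k]) for k in range(3)]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed GRO record: {line!r}") from exc
        particles.append({
            "id": i,
            "role": _infer_role(resname, role_map),
            "species": resname,
            "residue_label": _residue_label(resname, resid),
            "chain": "",
        })
        coords.append(xyz)
    box_line = lines[natoms + 2].split()
    try:
        box = np.array([float(v) for v in box_line[:3]])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {natoms + 3}: malformed box line") from exc
    system = MembraneSystem.from_particles(particles, np.array(coords), box)
    return system, Frame(time=0.0, coordinates=system.coordinates, box=box)


def _read_pdb(text: str, role_map: dict | None) -> tuple[MembraneSystem, Frame]:
    particles, coords = [], []
    box = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])]) / 10.0
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed CRYST1 record") from exc
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: PDB record too short ({len(line)} chars)")
        try:
            resname = line[17:20].strip()
            chain = line[21].strip()
            resid = int(line[22:26])
            # PDB coordinates are Angstrom; convert to nm.
            xyz = [float(line[30:38]) / 10.0, float(line[38:46]) / 10.0,
                   float(line[46:54]) / 10.0]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed ATOM record: {line!r}") from exc
        particles.append({
            "id": len(particles),
            "role": _infer_role(resname, role_map),
            "species": resname,
            "residue_label": _residue_label(resname, resid),
            "chain": chain,
        })
        coords.append(xyz)
    if not particles:
        raise ParseError("no ATOM/HETATM records found")
    if box is None:
        # no CRYST1: enclose with a generous pad so min-image is a no-op
        span = np.ptp(np.array(coords), axis=0)
        box = np.maximum(span * 2 + 1.0, 1.0)
    system = MembraneSystem.from_particles(particles, np.array(coords), box)
    return system, Frame(time=0.0, coordinates=system.coordinates, box=box)


# ---------------------------------------------------------------------------
# trajectory store


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the documented plain-text multi-frame store."""
    if traj.n_frames < 1:
        raise ValueError("refusing to write a trajectory with no frames")
    sys_ = traj.system
    with open(path, "w") as fh:
        fh.write("MEMTRAJ 1\n")
        fh.write(f"particles {sys_.n_particles}\n")
        for i in range(sys_.n_particles):
            fh.write(
                f"{sys_.ids[i]}\t{Role(sys_.roles[i]).value}\t{sys_.species[i]}"
                f"\t{sys_.residue_labels[i]}\t{sys_.chains[i]}\n"
            )
        fh.write("box {:.6f} {:.6f} {:.6f}\n".format(*sys_.box))
        fh.write(f"frames {traj.n_frames}\n")
        for f in range(traj.n_frames):
            fh.write(f"frame {traj.times[f]:.6f}\n")
            np.savetxt(fh, traj.coords[f], fmt="%.6f")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read the plain-text store back; validates counts and headers."""
    with open(path) as fh:
        return _read_trajectory_stream(fh)


def _expect(fh: TextIO, prefix: str) -> list[str]:
    line = fh.readline()
    if not line.startswith(prefix):
        raise ParseError(f"expected {prefix!r} header, got {line!r}")
    return line.split()


def _read_trajectory_stream(fh: TextIO) -> Trajectory:
    header = fh.readline().split()
    if header[:2] != ["MEMTRAJ", "1"]:
        raise ParseError(f"not a MEMTRAJ v1 file: {header}")
    n = int(_expect(fh, "particles")[1])
    particles = []
    for i in range(n):
        fields = fh.readline().rstrip("\n").split("\t")
        if len(fields) != 5:
            raise ParseError(f"particle row {i}: expected 5 tab-separated fields")
        particles.append({
            "id": int(fields[0]), "role": Role(fields[1]), "species": fields[2],
            "residue_label": fields[3], "chain": fields[4],
        })
    box = np.array([float(v) for v in _expect(fh, "box")[1:4]])
    n_frames = int(_expect(fh, "frames")[1])
    times = np.empty(n_frames)
    coords = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        fields = _expect(fh, "frame")
        times[f] = float(fields[1])
        for i in range(n):
            row = fh.readline().split()
            if len(row) != 3:
                raise ParseError(
                    f"frame {f}: coordinate row {i} has {len(row)} fields "
                    "(frame/particle count mismatch?)"
                )
            coords[f, i] = [float(v) for v in row]
    system = MembraneSystem.from_particles(particles, coords[0], box)
    return Trajectory(system=system, times=times, coords=coords)


# ---------------------------------------------------------------------------
# OpenDX volumetric grids


def write_dx(
    path: str | Path,
    origin: np.ndarray,
    spacing: float,
    values: np.ndarray,
    comment: str = "occupancy density",
) -> None:
    """Write a 3D grid in OpenDX format.

    ``values`` has shape (nx, ny, nz); the data body follows the OpenDX
    convention of the **last** grid index (z) varying fastest, i.e. the
    C-order ravel of the array, three values per line.  Files written
    this way load in VMD.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.size == 0:
        raise ValueError("refusing to write an empty or non-3D grid")
    nx, ny, nz = values.shape
    origin = np.asarray(origin, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*origin))
        fh.write(f"delta {spacing:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {spacing:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} data follows\n"
        )
        flat = values.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')


def read_dx(path: str | Path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read an OpenDX grid; returns (origin, spacing, values)."""
    counts = None
    origin = None
    deltas = []
    data: list[float] = []
    n_items = 0
    in_data = False
    for lineno, line in enumerate(open(path), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if in_data:
            if s.startswith("attribute") or s.startswith("object"):
                in_data = False
                continue
            data.extend(float(v) for v in s.split())
            if len(data) >= n_items:
                in_data = False
            continue
        if s.startswith("object 1"):
            counts = tuple(int(v) for v in s.split()[-3:])
        elif s.startswith("origin"):
            origin = np.array([float(v) for v in s.split()[1:4]])
        elif s.startswith("delta"):
            deltas.append([float(v) for v in s.split()[1:4]])
        elif "data follows" in s:
            n_items = int(s.split()[-3])
            in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ParseError(f"{path}: incomplete OpenDX header")
    if len(data) != n_items:
        raise ParseError(f"{path}: expected {n_items} data values, got {len(data)}")
    spacing = deltas[0][0]
    values = np.array(data).reshape(counts, order="C")
    return origin, spacing, values


def write_density_map(dmap, path: str | Path) -> None:
    """Serialize a :class:`~memsite.mapping.DensityMap` as OpenDX."""
    write_dx(path, dmap.origin, dmap.spacing, dmap.values,
             comment=f"memsite density map, normalization={dmap.normalization}")


def read_density_map(path: str | Path):
    from .mapping import DensityMap  # local import avoids a cycle

    origin, spacing, values = read_dx(path)
    return DensityMap(origin=origin, spacing=spacing, values=values,
                      n_frames=1, normalization="raw_counts")
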