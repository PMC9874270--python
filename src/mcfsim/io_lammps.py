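"""LAMMPS-format text interchange: data files (molecular dialect),
trajectory dumps and XYZ export.

Atom type 1 is collagen, type 2 is mineral.  Mineral beads are written
with molecule id 0 (the file format has no negative sentinel); readers
map molecule 0 of type 2 back to the internal sentinel -1.
Coordinates are printed at %.6f, and read(write(x)) reproduces the
printed values exactly.
"""

from __future__ import annotations

import numpy as np

from .fibril_geometry import (
    BeadTopology,
    Box,
    MINERAL_MOLECULE_ID,
    SPECIES_COLLAGEN,
    SPECIES_MINERAL,
)
from .mineralizer import MassModel

__all__ = [
    "write_data",
    "read_data",
    "write_dump",
    "read_dump",
    "write_xyz",
    "ParseError",
]


class ParseError(ValueError):
    def __init__(self, msg: str, line: int | None = None):
        if line is not None:
            msg = f"line {line}: {msg}"
        super().__init__(msg)


def write_data(topology: BeadTopology, masses: MassModel, path,
               comment: str = "") -> None:
    """Write a LAMMPS data file (Atoms # molecular)."""
    n = topology.n_beads
    nb = len(topology.bonds)
    na = len(topology.angles)
    box = topology.box
    with open(path, "w") as fh:
        fh.write(f"# mcfsim data file {comment}\n\n")
        fh.write(f"{n} atoms\n{nb} bonds\n{na} angles\n\n")
        fh.write("2 atom types\n1 bond types\n1 angle types\n\n")
        fh.write(f"{box.lo[0]:.6f} {box.hi[0]:.6f} xlo xhi\n")
        fh.write(f"{box.lo[1]:.6f} {box.hi[1]:.6f} ylo yhi\n")
        fh.write(f"{box.lo[2]:.6f} {box.hi[2]:.6f} zlo zhi\n\n")
        fh.write("Masses\n\n")
        fh.write(f"1 {masses.m_collagen:.6f}\n2 {masses.m_mineral:.6f}\n\n")
        fh.write("Atoms # molecular\n\n")
        for i in range(n):
            mol = int(topology.molecule_id[i])
            mol_out = 0 if mol == MINERAL_MOLECULE_ID else mol + 1
            typ = 2 if topology.species[i] == SPECIES_MINERAL else 1
            p = topology.positions[i]
            fh.write(f"{i + 1} {mol_out} {typ} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        if nb:
            fh.write("\nBonds\n\n")
            for b in range(nb):
                i, j = topology.bonds[b]
                fh.write(f"{b + 1} 1 {i + 1} {j + 1}\n")
        if na:
            fh.write("\nAngles\n\n")
            for a in range(na):
                i, j, k = topology.angles[a]
                fh.write(f"{a + 1} 1 {i + 1} {j + 1} {k + 1}\n")


def read_data(path) -> tuple[BeadTopology, MassModel]:
    """Read a LAMMPS data file written by :func:`write_data`."""
    with open(path) as fh:
        lines = fh.readlines()
    n = nb = na = None
    lo = np.zeros(3)
    hi = np.zeros(3)
    section = None
    masses = {}
    atoms = {}
    bonds = []
    angles = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("#")[0].strip() if not raw.lstrip().startswith("#") else ""
        if ln == 1:
            continue  # title line
        if not line:
            continue
        low = line.lower()
        if low.endswith(" atoms"):
            n = int(line.split()[0]); continue
        if low.endswith(" bonds"):
            nb = int(line.split()[0]); continue
        if low.endswith(" angles"):
            na = int(line.split()[0]); continue
        if low.endswith("types"):
            continue
        if low.endswith("xlo xhi") or low.endswith("ylo yhi") or low.endswith("zlo zhi"):
            parts = line.split()
            ax = {"x": 0, "y": 1, "z": 2}[parts[2][0]]
            lo[ax], hi[ax] = float(parts[0]), float(parts[1])
            continue
        if low == "masses":
            section = "masses"; continue
        if low.startswith("atoms"):
            section = "atoms"; continue
        if low == "bonds":
            section = "bonds"; continue
        if low == "angles":
            section = "angles"; continue
        parts = line.split()
        try:
            if section == "masses":
                masses[int(parts[0])] = float(parts[1])
            elif section == "atoms":
                aid = int(parts[0])
                atoms[aid] = (
                    int(parts[1]), int(parts[2]),
                    float(parts[3]), float(parts[4]), float(parts[5]),
                )
            elif section == "bonds":
                bonds.append((int(parts[2]) - 1, int(parts[3]) - 1))
            elif section == "angles":
                angles.append(
                    (int(parts[2]) - 1, int(parts[3]) - 1, int(parts[4]) - 1)
                )
            else:
                raise ParseError(f"unexpected content {line!r}", ln)
        except (ValueError, IndexError) as exc:
            raise ParseError(f"cannot parse {line!r} ({exc})", ln) from None
    if n is None or len(atoms) != n:
        raise ParseError(f"expected {n} atoms, found {len(atoms)}")
    if nb is not None and len(bonds) != nb:
        raise ParseError(f"expected {nb} bonds, found {len(bonds)}")
    if na is not None and len(angles) != na:
        raise ParseError(f"expected {na} angles, found {len(angles)}")
    pos = np.empty((n, 3))
    species = np.empty(n, dtype=np.uint8)
    mol = np.empty(n, dtype=np.int64)
    for aid in range(1, n + 1):
        if aid not in atoms:
            raise ParseError(f"missing atom id {aid}")
        m, typ, x, y, z = atoms[aid]
        pos[aid - 1] = (x, y, z)
        species[aid - 1] = SPECIES_MINERAL if typ == 2 else SPECIES_COLLAGEN
        mol[aid - 1] = MINERAL_MOLECULE_ID if typ == 2 else m - 1
    box = Box(lo=lo, hi=hi, periodic=np.array([False, False, False]))
    topo = BeadTopology(
        positions=pos, species=species, molecule_id=mol,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
        box=box,
    )
    mm = MassModel(
        m_collagen=masses.get(1, MassModel().m_collagen),
        m_mineral=masses.get(2, MassModel().m_mineral),
    )
    return topo, mm


def write_dump(frames, timesteps, topology: BeadTopology, path) -> None:
    """LAMMPS text dump (id type mol x y z) with one block per frame."""
    box = topology.box
    with open(path, "w") as fh:
        for frame, ts in zip(frames, timesteps):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{int(ts)}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{topology.n_beads}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for ax in range(3):
                fh.write(f"{box.lo[ax]:.6f} {box.hi[ax]:.6f}\n")
            fh.write("ITEM: ATOMS id type mol x y z\n")
            for i in range(topology.n_beads):
                mol = int(topology.molecule_id[i])
                mol_out = 0 if mol == MINERAL_MOLECULE_ID else mol + 1
                typ = 2 if topology.species[i] == SPECIES_MINERAL else 1
                p = frame[i]
                fh.write(
                    f"{i + 1} {typ} {mol_out} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n"
                )


def read_dump(path):
    """Read a text dump; returns (frames, timesteps).

    Raises :class:`ParseError` naming the frame index on truncation.
    """
    frames = []
    timesteps = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            assert lines[i].startswith("ITEM: TIMESTEP")
            ts = int(lines[i + 1])
            assert lines[i + 2].startswith("ITEM: NUMBER OF ATOMS")
            natoms = int(lines[i + 3])
            assert lines[i + 4].startswith("ITEM: BOX BOUNDS")
            j = i + 8  # skip 3 bounds lines
            assert lines[j].startswith("ITEM: ATOMS")
            pos = np.empty((natoms, 3))
            for k in range(natoms):
                parts = lines[j + 1 + k].split()
                aid = int(parts[0])
                pos[aid - 1] = [float(parts[3]), float(parts[4]), float(parts[5])]
            frames.append(pos)
            timesteps.append(ts)
            i = j + 1 + natoms
            frame_idx += 1
        except (AssertionError, IndexError, ValueError) as exc:
            raise ParseError(
                f"truncated or malformed dump at frame {frame_idx} ({exc})"
            ) from None
    if np.any(np.diff(timesteps) < 0):
        raise ParseError("dump timesteps are not monotone")
    return frames, timesteps


def write_xyz(frames, topology: BeadTopology, path, comment: str = "") -> None:
    """Multi-frame XYZ export; element C for collagen, M for mineral."""
    sym = np.where(topology.species == SPECIES_MINERAL, "M", "C")
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{topology.n_beads}\n")
            fh.write(f"frame {f} {comment}\n")
            for i in range(topology.n_beads):
                p = frame[i]
                fh.write(f"{sym[i]} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
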