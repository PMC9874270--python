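"""Idealized staggered collagen fibril generator.

A collagen fibril is modelled as a bundle of coarse-grained bead chains
("protofibrils", one chain = one tropocollagen molecule) arranged on a
quasi-hexagonal cross-section lattice.  Along the axis, chains on each
lateral site repeat in tandem with period 5*D and are staggered between
sites by integer multiples of the D-period (Hodge–Petruska packing), so
that each D-period splits into a low-density *gap* interval and a
high-density *overlap* interval.

Default geometry: bead spacing 14 Å, 219 beads per molecule (contour
305.2 nm), D = 67 nm, lateral spacing 15.3 Å — a 20 nm diameter then
holds ≈155 molecules per 5D structural period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FibrilSpec",
    "Box",
    "BeadTopology",
    "ProtofibrilIndex",
    "STAGGER_RULES",
    "build_idealized_fibril",
    "label_gap_overlap",
    "assign_protofibril_ids",
    "read_bead_axes",
    "write_bead_axes",
    "topology_from_axes",
]

SPECIES_COLLAGEN = 0
SPECIES_MINERAL = 1
MINERAL_MOLECULE_ID = -1

#: axial stagger index as a function of the hex lattice coordinates (i, j).
#: Every rule must hit all 5 phases within a small neighbourhood.
STAGGER_RULES = {
    "i+2j": lambda i, j: (i + 2 * j) % 5,
    "2i+j": lambda i, j: (2 * i + j) % 5,
    "i+3j": lambda i, j: (i + 3 * j) % 5,
    "3i+j": lambda i, j: (3 * i + j) % 5,
    "i-j": lambda i, j: (i - j) % 5,
}


class GeometryError(ValueError):
    """Raised for invalid fibril specifications or degenerate builds."""


@dataclass(frozen=True)
class FibrilSpec:
    """Parameters of the idealized fibril.

    Attributes
    ----------
    diameter_nm:
        Fibril diameter (nm); lateral lattice sites are kept within this
        circle.
    length_periods:
        Fibril length as a multiple of the D-period.
    D_nm:
        Axial D-period (nm).
    bead_spacing_A:
        Distance between consecutive beads of a molecule (Å).
    beads_per_molecule:
        Beads per tropocollagen molecule.
    lateral_spacing_A:
        Hexagonal lattice constant of the cross-section (Å).
    stagger_rule:
        Key into :data:`STAGGER_RULES`.
    seed:
        Reserved for randomized variants; the default build is fully
        deterministic and does not consume it.
    periodic_z:
        If True the fibril is built as an axially periodic cell
        (molecules wrap across z = 0/L and ``length_periods`` must be a
        multiple of 5); if False molecules are clipped at the fibril
        ends, which yields chain fragments near the boundaries.
    """

    diameter_nm: float = 20.0
    length_periods: int = 5
    D_nm: float = 67.0
    bead_spacing_A: float = 14.0
    beads_per_molecule: int = 219
    lateral_spacing_A: float = 15.3
    stagger_rule: str = "i+2j"
    seed: int = 0
    periodic_z: bool = True

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise GeometryError("diameter must be positive")
        if self.D_nm <= 0:
            raise GeometryError("D-period must be positive")
        if self.bead_spacing_A <= 0:
            raise GeometryError("bead spacing must be positive")
        if self.beads_per_molecule < 3:
            raise GeometryError("need at least 3 beads per molecule")
        if self.length_periods < 1:
            raise GeometryError("length must be at least one D-period")
        if self.stagger_rule not in STAGGER_RULES:
            raise GeometryError(f"unknown stagger rule {self.stagger_rule!r}")
        if self.contour_A >= 5.0 * self.D_A:
            raise GeometryError(
                "molecule contour must be shorter than 5 D-periods "
                "(otherwise no gap region exists)"
            )
        if self.periodic_z and self.length_periods % 5 != 0:
            raise GeometryError(
                "periodic builds require length_periods to be a multiple of 5"
            )

    @property
    def D_A(self) -> float:
        return self.D_nm * 10.0

    @property
    def radius_A(self) -> float:
        return self.diameter_nm * 10.0 / 2.0

    @property
    def length_A(self) -> float:
        return self.length_periods * self.D_A

    @property
    def contour_A(self) -> float:
        return (self.beads_per_molecule - 1) * self.bead_spacing_A

    @property
    def gap_fraction(self) -> float:
        """Gap length as a fraction of D: (5D - contour)/D."""
        return (5.0 * self.D_A - self.contour_A) / self.D_A


@dataclass
class Box:
    lo: np.ndarray
    hi: np.ndarray
    periodic: np.ndarray  # bool per axis

    @property
    def lengths(self) -> np.ndarray:
        return self.hi - self.lo

    def copy(self) -> "Box":
        return Box(self.lo.copy(), self.hi.copy(), self.periodic.copy())


@dataclass
class BeadTopology:
    """Bead positions plus bonded topology of a (mineralized) fibril.

    Collagen beads come first and are contiguous per molecule, ordered
    along the chain; mineral beads (if any) form the tail of the arrays
    and carry ``molecule_id == -1`` and no bonds/angles.
    """

    positions: np.ndarray  # (N, 3) float64, Å
    species: np.ndarray  # (N,) uint8
    molecule_id: np.ndarray  # (N,) int64
    bonds: np.ndarray  # (Nb, 2) int64
    angles: np.ndarray  # (Na, 3) int64
    box: Box
    region_label: np.ndarray | None = None  # (N,) uint8, 0=overlap 1=gap
    meta: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def collagen_mask(self) -> np.ndarray:
        return self.species == SPECIES_COLLAGEN

    @property
    def mineral_mask(self) -> np.ndarray:
        return self.species == SPECIES_MINERAL

    @property
    def n_molecules(self) -> int:
        ids = self.molecule_id[self.collagen_mask]
        return int(np.unique(ids).size)

    def molecule_indices(self) -> list[np.ndarray]:
        """Bead index arrays per collagen molecule, chain-ordered."""
        out = []
        mask = self.collagen_mask
        ids = self.molecule_id[mask]
        idx = np.nonzero(mask)[0]
        for m in np.unique(ids):
            out.append(idx[ids == m])
        return out

    def copy(self) -> "BeadTopology":
        return BeadTopology(
            self.positions.copy(),
            self.species.copy(),
            self.molecule_id.copy(),
            self.bonds.copy(),
            self.angles.copy(),
            self.box.copy(),
            None if self.region_label is None else self.region_label.copy(),
            dict(self.meta),
        )

    def validate(self) -> None:
        """Check the chain-topology invariants."""
        n = self.n_beads
        if self.bonds.size and (self.bonds.min() < 0 or self.bonds.max() >= n):
            raise GeometryError("bond index out of range")
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() >= n):
            raise GeometryError("angle index out of range")
        mol = self.molecule_id
        for b in self.bonds:
            if mol[b[0]] != mol[b[1]] or mol[b[0]] < 0:
                raise GeometryError("bonds must connect beads of one molecule")
        n_bonds = sum(len(ix) - 1 for ix in self.molecule_indices())
        n_angles = sum(max(len(ix) - 2, 0) for ix in self.molecule_indices())
        if n_bonds != len(self.bonds) or n_angles != len(self.angles):
            raise GeometryError("bond/angle counts inconsistent with molecules")


@dataclass
class ProtofibrilIndex:
    """Radial ordering of the molecules.

    ``protofibril_id`` maps molecule_id -> ID in 1..n, sorted so that
    the mean distance from the fibril axis is non-decreasing in ID.
    """

    molecule_ids: np.ndarray  # (n,) the molecule ids, sorted ascending
    protofibril_id: dict  # molecule_id -> 1..n
    mean_radius: np.ndarray  # (n,) Å, indexed by (ID - 1)
    bead_protofibril_id: np.ndarray  # per bead; 0 for mineral beads

    @property
    def n(self) -> int:
        return self.molecule_ids.size


def _hex_sites(radius: float, a: float) -> list[tuple[int, int, float, float]]:
    nmax = int(math.ceil(radius / a)) + 2
    sites = []
    s3 = math.sqrt(3.0) / 2.0
    for j in range(-nmax, nmax + 1):
        for i in range(-nmax, nmax + 1):
            x = a * (i + 0.5 * j)
            y = a * s3 * j
            if x * x + y * y <= radius * radius + 1e-9:
                sites.append((i, j, x, y))
    return sites


def build_idealized_fibril(spec: FibrilSpec) -> BeadTopology:
    """Place staggered bead chains on a hexagonal lattice.

    Deterministic given ``spec``.  Gap/overlap labels are attached via
    :func:`label_gap_overlap` (called automatically).
    """
    sites = _hex_sites(spec.radius_A, spec.lateral_spacing_A)
    if not sites:
        raise GeometryError(
            f"diameter {spec.diameter_nm} nm too small for one lattice site "
            f"at spacing {spec.lateral_spacing_A} Å"
        )
    rule = STAGGER_RULES[spec.stagger_rule]
    D = spec.D_A
    L = spec.length_A
    dz = spec.bead_spacing_A
    nb = spec.beads_per_molecule

    pos_chunks: list[np.ndarray] = []
    mol_chunks: list[np.ndarray] = []
    mol_counter = 0
    m_idx = np.arange(nb)
    for i, j, x, y in sites:
        s = rule(i, j)
        if spec.periodic_z:
            for k in range(spec.length_periods // 5):
                z0 = s * D + k * 5.0 * D
                z = np.mod(z0 + m_idx * dz, L)
                chunk = np.empty((nb, 3))
                chunk[:, 0] = x
                chunk[:, 1] = y
                chunk[:, 2] = z
                pos_chunks.append(chunk)
                mol_chunks.append(np.full(nb, mol_counter, dtype=np.int64))
                mol_counter += 1
        else:
            k_lo = int(math.floor((-s * D - spec.contour_A) / (5.0 * D))) - 1
            k_hi = int(math.ceil((L - s * D) / (5.0 * D))) + 1
            for k in range(k_lo, k_hi + 1):
                z0 = s * D + k * 5.0 * D
                z = z0 + m_idx * dz
                inside = (z >= -1e-9) & (z <= L + 1e-9)
                n_in = int(inside.sum())
                if n_in < 3:  # fragments shorter than one angle are dropped
                    continue
                chunk = np.empty((n_in, 3))
                chunk[:, 0] = x
                chunk[:, 1] = y
                chunk[:, 2] = z[inside]
                pos_chunks.append(chunk)
                mol_chunks.append(np.full(n_in, mol_counter, dtype=np.int64))
                mol_counter += 1

    positions = np.vstack(pos_chunks)
    molecule_id = np.concatenate(mol_chunks)
    species = np.zeros(len(positions), dtype=np.uint8)

    bonds = []
    angles = []
    start = 0
    for chunk in mol_chunks:
        n = len(chunk)
        ix = np.arange(start, start + n)
        bonds.append(np.column_stack([ix[:-1], ix[1:]]))
        if n >= 3:
            angles.append(np.column_stack([ix[:-2], ix[1:-1], ix[2:]]))
        start += n
    bonds_arr = np.vstack(bonds).astype(np.int64)
    angles_arr = (
        np.vstack(angles).astype(np.int64) if angles else np.empty((0, 3), np.int64)
    )

    pad = 45.0  # room for the largest pair cutoff on the free surface
    box = Box(
        lo=np.array([-spec.radius_A - pad, -spec.radius_A - pad, 0.0]),
        hi=np.array([spec.radius_A + pad, spec.radius_A + pad, L]),
        periodic=np.array([False, False, spec.periodic_z]),
    )
    topo = BeadTopology(
        positions=positions,
        species=species,
        molecule_id=molecule_id,
        bonds=bonds_arr,
        angles=angles_arr,
        box=box,
        meta={
            "D_A": D,
            "gap_fraction": spec.gap_fraction,
            "length_periods": spec.length_periods,
            "stagger_rule": spec.stagger_rule,
            "spec": spec,
        },
    )
    return label_gap_overlap(topo, spec)


def label_gap_overlap(
    topology: BeadTopology, spec: FibrilSpec | None = None, g: float | None = None
) -> BeadTopology:
    """Label every bead as belonging to a gap or overlap interval.

    Each axial D-period is partitioned into a gap interval of length
    ``g*D`` (the sub-interval left vacant by the staggered packing) and
    an overlap interval of length ``(1-g)*D``.  With molecules starting
    at integer multiples of D from z = 0, the gap interval of each
    period is ``z mod D in [(1-g)*D, D)``.
    """
    if "D_A" not in topology.meta:
        raise GeometryError("topology lacks stagger metadata (D_A); "
                            "build it with build_idealized_fibril or attach meta")
    D = topology.meta["D_A"]
    if g is None:
        g = spec.gap_fraction if spec is not None else topology.meta["gap_fraction"]
    frac = np.mod(topology.positions[:, 2], D) / D
    label = (frac >= 1.0 - g).astype(np.uint8)
    topology.region_label = label
    topology.meta["gap_fraction"] = g
    return topology


def gap_centers(topology: BeadTopology) -> np.ndarray:
    """Axial midpoints (Å) of the gap interval of every D-period."""
    D = topology.meta["D_A"]
    g = topology.meta["gap_fraction"]
    n = int(topology.meta["length_periods"])
    p = np.arange(n)
    return (p + 1.0 - g / 2.0) * D


def assign_protofibril_ids(topology: BeadTopology) -> ProtofibrilIndex:
    """Order molecules by mean distance from the fibril axis.

    IDs 1..n are assigned with higher IDs at larger radius; ties are
    broken by the azimuthal angle of the molecule centroid and then by
    molecule id, so the assignment is deterministic.
    """
    mols = topology.molecule_indices()
    if not mols:
        raise GeometryError("no collagen molecules present")
    ids = np.array([topology.molecule_id[ix[0]] for ix in mols])
    radii = np.empty(len(mols))
    azim = np.empty(len(mols))
    for k, ix in enumerate(mols):
        xy = topology.positions[ix, :2]
        radii[k] = np.mean(np.hypot(xy[:, 0], xy[:, 1]))
        cx, cy = xy[:, 0].mean(), xy[:, 1].mean()
        azim[k] = math.atan2(cy, cx)
    order = np.lexsort((ids, azim, radii))
    proto = {int(ids[k]): rank + 1 for rank, k in enumerate(order)}
    mean_radius = radii[order]

    bead_pid = np.zeros(topology.n_beads, dtype=np.int64)
    for mid, pid in proto.items():
        bead_pid[topology.molecule_id == mid] = pid
    return ProtofibrilIndex(
        molecule_ids=np.sort(ids),
        protofibril_id=proto,
        mean_radius=mean_radius,
        bead_protofibril_id=bead_pid,
    )


def open_chain_ends(topology: BeadTopology) -> BeadTopology:
    """Convert a z-periodic build into an open-ended (gripped) fibril.

    Chains that wrap across the z boundary are split at the wrap point
    into separate molecules; the bonds and angles spanning the boundary
    are removed.  Used before a uniaxial tension run, which needs free,
    non-periodic ends.
    """
    L = topology.box.lengths[2]
    pos = topology.positions
    new_mol = topology.molecule_id.copy()
    drop_bond = np.zeros(len(topology.bonds), dtype=bool)
    for b, (i, j) in enumerate(topology.bonds):
        if abs(pos[j, 2] - pos[i, 2]) > L / 2.0:
            drop_bond[b] = True
    drop_angle = np.zeros(len(topology.angles), dtype=bool)
    for a, (i, jj, k) in enumerate(topology.angles):
        if (abs(pos[jj, 2] - pos[i, 2]) > L / 2.0
                or abs(pos[k, 2] - pos[jj, 2]) > L / 2.0):
            drop_angle[a] = True
    # re-number molecule fragments after cutting the wrap bonds
    next_id = int(new_mol.max()) + 1 if new_mol.size else 0
    for b in np.nonzero(drop_bond)[0]:
        i, j = topology.bonds[b]
        mid = new_mol[j]
        if mid < 0:
            continue
        # everything downstream of the cut (same molecule, index >= j)
        sel = (topology.molecule_id == topology.molecule_id[j]) & (
            np.arange(topology.n_beads) >= j
        )
        new_mol[sel] = next_id
        next_id += 1
    out = topology.copy()
    out.molecule_id = new_mol
    out.bonds = topology.bonds[~drop_bond]
    out.angles = topology.angles[~drop_angle]
    out.box.periodic[2] = False
    # bookkeeping for per-angle/per-bond attributes of the parent topology
    out.meta["kept_bonds"] = np.nonzero(~drop_bond)[0]
    out.meta["kept_angles"] = np.nonzero(~drop_angle)[0]
    # keep fragments with >=3 beads only is not enforced here: short
    # fragments simply carry fewer bonds/angles.
    return out


def wrap_z(topology: BeadTopology) -> BeadTopology:
    """Wrap bead z-coordinates into the (periodic) axial box in place."""
    lo = topology.box.lo[2]
    L = topology.box.lengths[2]
    topology.positions[:, 2] = np.mod(topology.positions[:, 2] - lo, L) + lo
    return topology


# ---------------------------------------------------------------------------
# plain-text bead-axis import/export (stand-in for externally derived axes)


def write_bead_axes(topology: BeadTopology, path) -> None:
    """Write collagen bead axes as whitespace-delimited (mol, x, y, z)."""
    mask = topology.collagen_mask
    with open(path, "w") as fh:
        fh.write("# molecule_id x y z (Å)\n")
        for mid, p in zip(topology.molecule_id[mask], topology.positions[mask]):
            fh.write(f"{int(mid)} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_bead_axes(path) -> tuple[np.ndarray, np.ndarray]:
    """Read (molecule_id, x, y, z) rows; returns (mol_ids, positions)."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 4:
        raise GeometryError("bead-axis file must have 4 columns: mol x y z")
    return data[:, 0].astype(np.int64), data[:, 1:4].astype(np.float64)


def topology_from_axes(
    mol_ids: np.ndarray,
    positions: np.ndarray,
    D_A: float | None = None,
    gap_fraction: float | None = None,
) -> BeadTopology:
    """Build a chain topology from imported bead-axis coordinates.

    Beads are re-ordered so that each molecule is contiguous and sorted
    along its chain (by file order within a molecule); consecutive beads
    are bonded.
    """
    order = np.argsort(mol_ids, kind="stable")
    mol_ids = mol_ids[order]
    positions = positions[order]
    bonds, angles = [], []
    start = 0
    for m in np.unique(mol_ids):
        n = int((mol_ids == m).sum())
        ix = np.arange(start, start + n)
        if n >= 2:
            bonds.append(np.column_stack([ix[:-1], ix[1:]]))
        if n >= 3:
            angles.append(np.column_stack([ix[:-2], ix[1:-1], ix[2:]]))
        start += n
    pad = 45.0
    lo = positions.min(axis=0) - pad
    hi = positions.max(axis=0) + pad
    box = Box(lo=lo, hi=hi, periodic=np.array([False, False, False]))
    meta = {}
    if D_A is not None:
        meta["D_A"] = D_A
        meta["length_periods"] = int(round((hi[2] - lo[2]) / D_A))
    if gap_fraction is not None:
        meta["gap_fraction"] = gap_fraction
    topo = BeadTopology(
        positions=np.ascontiguousarray(positions),
        species=np.zeros(len(positions), dtype=np.uint8),
        molecule_id=mol_ids.copy(),
        bonds=np.vstack(bonds).astype(np.int64) if bonds else np.empty((0, 2), np.int64),
        angles=np.vstack(angles).astype(np.int64) if angles else np.empty((0, 3), np.int64),
        box=box,
        meta=meta,
    )
    return topo
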