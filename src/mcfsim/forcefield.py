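"""Coarse-grained force field: bilinear breakable bonds, harmonic angles
and truncated Lennard-Jones pairs.

The bond potential is

    U(r) = 1/2 k0 (r - r0)^2              r <  r1
         = 1/2 k1 (r - rbar1)^2 + U_off   r1 <= r < r2
         = 0                              r >= r2

``rbar1`` is closed by force continuity at the switch distance r1,
``U_off`` by energy continuity; the drop to zero at the breaking
distance r2 is discontinuous by construction (the stored bond energy is
released on rupture).  Angles are harmonic in the angle itself; pairs
are plain truncated (unshifted) LJ with per-species-pair parameters.

Default parameters (kcal/mol, Å) are the calibrated collagen /
hydroxyapatite coarse-grained set; see :func:`default_forcefield`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .fibril_geometry import BeadTopology

__all__ = [
    "BondParams",
    "AngleParams",
    "PairParams",
    "ForceField",
    "default_forcefield",
    "derive_bond_branch",
    "bond_energy_force",
    "angle_energy",
    "angle_forces",
    "pair_energy_force",
    "assign_theta0",
    "system_energy_forces",
    "SystemForces",
]


@dataclass(frozen=True)
class BondParams:
    k0: float = 17.13      # kcal/mol/Å^2, small-deformation stiffness
    k1: float = 97.66      # kcal/mol/Å^2, large-deformation stiffness
    r0: float = 14.00      # Å, small-deformation equilibrium distance
    r1: float = 18.20      # Å, regime switch distance
    r2: float = 21.00      # Å, breaking distance
    rbar1: float | None = None       # large-deformation equilibrium distance
    energy_offset: float | None = None

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 < self.r2):
            raise ValueError("bond distances must satisfy r0 < r1 < r2")
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError("bond stiffnesses must be positive")


def derive_bond_branch(p: BondParams) -> BondParams:
    """Fill ``rbar1`` and ``energy_offset`` from the continuity closure.

    Force continuity at r1:  k0 (r1 - r0) = k1 (r1 - rbar1)
        =>  rbar1 = r1 - (k0/k1)(r1 - r0)
    Energy continuity at r1 fixes the offset on the second branch.
    """
    rbar1 = p.r1 - (p.k0 / p.k1) * (p.r1 - p.r0)
    offset = 0.5 * p.k0 * (p.r1 - p.r0) ** 2 - 0.5 * p.k1 * (p.r1 - rbar1) ** 2
    return replace(p, rbar1=rbar1, energy_offset=offset)


@dataclass(frozen=True)
class AngleParams:
    k_theta: float = 14.98        # kcal/mol/rad^2
    theta0_min_deg: float = 164.0
    theta0_max_deg: float = 180.0

    def __post_init__(self) -> None:
        if self.k_theta <= 0:
            raise ValueError("angle stiffness must be positive")


@dataclass(frozen=True)
class PairParams:
    epsilon: float
    sigma: float
    r_cutoff: float

    def __post_init__(self) -> None:
        if min(self.epsilon, self.sigma, self.r_cutoff) <= 0:
            raise ValueError("pair parameters must be positive")
        if self.sigma >= self.r_cutoff:
            raise ValueError("sigma must be below the cutoff")


@dataclass(frozen=True)
class ForceField:
    bond: BondParams
    angle: AngleParams
    pair_cc: PairParams  # collagen-collagen
    pair_mm: PairParams  # HAp-HAp
    pair_cm: PairParams  # collagen-HAp (applied symmetrically)

    def pair_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        eps = np.array(
            [[self.pair_cc.epsilon, self.pair_cm.epsilon],
             [self.pair_cm.epsilon, self.pair_mm.epsilon]]
        )
        sig = np.array(
            [[self.pair_cc.sigma, self.pair_cm.sigma],
             [self.pair_cm.sigma, self.pair_mm.sigma]]
        )
        rc = np.array(
            [[self.pair_cc.r_cutoff, self.pair_cm.r_cutoff],
             [self.pair_cm.r_cutoff, self.pair_mm.r_cutoff]]
        )
        return eps, sig, rc

    @property
    def max_cutoff(self) -> float:
        return max(self.pair_cc.r_cutoff, self.pair_mm.r_cutoff,
                   self.pair_cm.r_cutoff, self.bond.r2)


def default_forcefield() -> ForceField:
    """Calibrated collagen/HAp coarse-grained parameter set."""
    return ForceField(
        bond=derive_bond_branch(BondParams()),
        angle=AngleParams(),
        pair_cc=PairParams(epsilon=6.87, sigma=14.72, r_cutoff=21.00),
        pair_mm=PairParams(epsilon=193.7, sigma=10.28, r_cutoff=13.85),
        pair_cm=PairParams(epsilon=137.1, sigma=9.88, r_cutoff=20.00),
    )


# ---------------------------------------------------------------------------
# scalar evaluators (reference semantics; kernels mirror these)


def bond_energy_force(r: float, p: BondParams) -> tuple[float, float]:
    """Energy and radial force F = -dU/dr of the bilinear bond."""
    if r <= 0:
        raise ValueError("distance must be positive")
    if p.rbar1 is None or p.energy_offset is None:
        p = derive_bond_branch(p)
    if r >= p.r2:
        return 0.0, 0.0
    if r < p.r1:
        return 0.5 * p.k0 * (r - p.r0) ** 2, -p.k0 * (r - p.r0)
    return (
        0.5 * p.k1 * (r - p.rbar1) ** 2 + p.energy_offset,
        -p.k1 * (r - p.rbar1),
    )


def angle_energy(theta: float, p: AngleParams, theta0: float) -> float:
    """Harmonic angle energy (theta, theta0 in radians)."""
    return 0.5 * p.k_theta * (theta - theta0) ** 2


def angle_forces(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, k_theta: float, theta0: float
) -> tuple[float, np.ndarray]:
    """Energy and Cartesian forces (3,3) on the beads of one angle."""
    pos = np.vstack([p1, p2, p3]).astype(float)
    angles = np.array([[0, 1, 2]], dtype=np.int64)
    forces = np.zeros((3, 3))
    stress = np.zeros((3, 6))
    U = _kernels.angle_kernel(
        pos, angles, k_theta, np.array([theta0]), 1e30, 1e30, False, forces, stress
    )
    return float(U), forces


def pair_energy_force(r: float, p: PairParams) -> tuple[float, float]:
    """Truncated LJ energy and radial force at separation r."""
    if r <= 0:
        raise ValueError("distance must be positive")
    if r >= p.r_cutoff:
        return 0.0, 0.0
    sr6 = (p.sigma / r) ** 6
    U = 4.0 * p.epsilon * (sr6 * sr6 - sr6)
    F = -(24.0 * p.epsilon / r) * (sr6 - 2.0 * sr6 * sr6)
    return U, F


# ---------------------------------------------------------------------------
# system-level assembly


def assign_theta0(topology: BeadTopology, ff: ForceField) -> np.ndarray:
    """Per-angle equilibrium angle: the as-built geometry clamped to the
    calibrated range (straight synthetic fibrils give 180°).  Radians."""
    pos = topology.positions
    Lz = topology.box.lengths[2]
    pbc = bool(topology.box.periodic[2])
    a = topology.angles
    if len(a) == 0:
        return np.empty(0)
    d1 = pos[a[:, 0]] - pos[a[:, 1]]
    d3 = pos[a[:, 2]] - pos[a[:, 1]]
    if pbc:
        d1[:, 2] -= Lz * np.round(d1[:, 2] / Lz)
        d3[:, 2] -= Lz * np.round(d3[:, 2] / Lz)
    c = np.einsum("ij,ij->i", d1, d3) / (
        np.linalg.norm(d1, axis=1) * np.linalg.norm(d3, axis=1)
    )
    theta = np.arccos(np.clip(c, -1.0, 1.0))
    lo = math.radians(ff.angle.theta0_min_deg)
    hi = math.radians(ff.angle.theta0_max_deg)
    return np.clip(theta, lo, hi)


@dataclass
class SystemForces:
    U_bond: float
    U_angle: float
    U_pair: float
    forces: np.ndarray        # (N,3) kcal/mol/Å
    per_bead_stress: np.ndarray  # (N,6) kcal/mol (stress * volume)
    broken: np.ndarray        # per-bond "has ever exceeded r2" flags

    @property
    def U_total(self) -> float:
        return self.U_bond + self.U_angle + self.U_pair


def _exclusion_mask(topology: BeadTopology, pairs: np.ndarray) -> np.ndarray:
    """True for pairs to KEEP (1-2 and 1-3 intra-molecular excluded)."""
    mol = topology.molecule_id
    i, j = pairs[:, 0], pairs[:, 1]
    same_mol = (mol[i] == mol[j]) & (mol[i] >= 0)
    near = np.abs(i - j) <= 2
    return ~(same_mol & near)


def all_pairs(topology: BeadTopology, cutoff: float,
              positions: np.ndarray | None = None) -> np.ndarray:
    """O(N^2) candidate pair list within ``cutoff`` (oracle path).

    Lexicographically sorted (i < j), exclusions applied — the same
    canonical order the neighbor list produces, so force sums match
    bit for bit.
    """
    pos = topology.positions if positions is None else positions
    n = len(pos)
    i, j = np.triu_indices(n, k=1)
    d = pos[j] - pos[i]
    if bool(topology.box.periodic[2]):
        Lz = topology.box.lengths[2]
        d[:, 2] -= Lz * np.round(d[:, 2] / Lz)
    keep = np.einsum("ij,ij->i", d, d) <= cutoff * cutoff
    pairs = np.column_stack([i[keep], j[keep]]).astype(np.int64)
    pairs = pairs[_exclusion_mask(topology, pairs)]
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def system_energy_forces(
    positions: np.ndarray,
    topology: BeadTopology,
    ff: ForceField,
    *,
    pairs: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    broken: np.ndarray | None = None,
    permanent: bool = False,
) -> SystemForces:
    """Total energy, forces and per-bead virial of a configuration.

    ``pairs`` may come from a neighbor list (skin-padded lists are fine:
    out-of-range pairs contribute exactly zero); if omitted, an O(N^2)
    list is built.  ``positions`` may differ from the topology's stored
    coordinates (e.g. a trajectory frame).
    """
    n = len(positions)
    if n != topology.n_beads:
        raise ValueError("positions inconsistent with topology size")
    if theta0 is None:
        theta0 = assign_theta0(topology, ff)
    if broken is None:
        broken = np.zeros(len(topology.bonds), dtype=np.bool_)
    if pairs is None:
        pairs = all_pairs(topology, ff.max_cutoff, positions=positions)
    forces = np.zeros((n, 3))
    stress = np.zeros((n, 6))
    Lz = topology.box.lengths[2]
    pbc = bool(topology.box.periodic[2])
    b = ff.bond
    if b.rbar1 is None:
        b = derive_bond_branch(b)
    U_bond = _kernels.bond_kernel(
        positions, topology.bonds, b.k0, b.k1, b.r0, b.rbar1, b.energy_offset,
        b.r1, b.r2, Lz, pbc, permanent, broken, forces, stress,
    )
    U_angle = _kernels.angle_kernel(
        positions, topology.angles, ff.angle.k_theta, theta0, b.r2,
        Lz, pbc, forces, stress,
    )
    eps, sig, rc = ff.pair_tables()
    U_pair = _kernels.pair_kernel(
        positions, pairs, topology.species.astype(np.int64), eps, sig, rc,
        Lz, pbc, forces, stress,
    )
    return SystemForces(U_bond, U_angle, U_pair, forces, stress, broken)
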