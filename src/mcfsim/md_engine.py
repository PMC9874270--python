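"""Velocity-Verlet integrator with Nosé-Hoover-chain / Langevin
thermostatting, an axial Berendsen-style barostat for equilibration, and
the constant-strain-rate uniaxial tension protocol.

Ensembles
---------
``nve``    plain velocity Verlet (energy-conservation checks).
``nvt``    Nosé-Hoover chains (default, deterministic) or Langevin.
``npt-z``  NVT plus a weak Berendsen barostat that rescales the periodic
           axial box toward a target axial stress (~1 bar), used for the
           equilibration stage.

During tension the moving-grip beads are displaced rigidly at constant
velocity, the fixed-grip beads are immobile, and only the free beads are
integrated and thermostatted.  Engineering strain is measured against
the initial free length between the inner grip faces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .fibril_geometry import BeadTopology
from .forcefield import ForceField, assign_theta0, derive_bond_branch
from .neighbors import NeighborList
from .units import FORCE_TO_ACC, KB, KCAL_PER_MOL_A3_TO_MPA, PER_S_TO_PER_FS

__all__ = [
    "SimState",
    "TensionProtocol",
    "Trajectory",
    "init_velocities",
    "minimize",
    "integrate",
    "run_tension",
    "make_state",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimState:
    positions: np.ndarray  # (N,3) Å
    velocities: np.ndarray  # (N,3) Å/fs
    masses: np.ndarray  # (N,) amu
    box: "object"  # fibril_geometry.Box
    time: float = 0.0

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(), self.velocities.copy(),
            self.masses.copy(), self.box.copy(), self.time,
        )


def make_state(topology: BeadTopology, masses) -> SimState:
    """Initial state (zero velocities) from a topology and a MassModel."""
    m = np.where(
        topology.species == 0, masses.m_collagen, masses.m_mineral
    ).astype(float)
    return SimState(
        positions=topology.positions.copy(),
        velocities=np.zeros_like(topology.positions),
        masses=m,
        box=topology.box.copy(),
    )


def init_velocities(state: SimState, T: float, seed: int = 0,
                    mask: np.ndarray | None = None) -> None:
    """Maxwell-Boltzmann velocities at T, zero net momentum, rescaled to
    the exact target temperature."""
    rng = np.random.default_rng(seed)
    n = len(state.masses)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    sigma = np.sqrt(KB * T * FORCE_TO_ACC / state.masses[mask])
    v = rng.standard_normal((int(mask.sum()), 3)) * sigma[:, None]
    v -= (state.masses[mask, None] * v).sum(axis=0) / state.masses[mask].sum()
    ke2 = float((state.masses[mask, None] * v * v).sum()) / FORCE_TO_ACC
    ndof = 3 * int(mask.sum()) - 3
    t_now = ke2 / (ndof * KB)
    if t_now > 0:
        v *= math.sqrt(T / t_now)
    state.velocities[:] = 0.0
    state.velocities[mask] = v


@dataclass(frozen=True)
class TensionProtocol:
    """Uniaxial tension: pull the top 2.5 %-length end region at constant
    velocity, hold the bottom end region fixed."""

    strain_rate_s: float = 2.5e6      # engineering strain rate, 1/s
    grip_fraction: float = 0.025      # fraction of total length per end
    target_strain: float = 0.6
    sample_interval: int = 100        # steps between samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.grip_fraction < 0.5:
            raise ValueError("grip fraction must be in (0, 0.5)")
        if self.strain_rate_s <= 0:
            raise ValueError("strain rate must be positive")

    @property
    def strain_rate_fs(self) -> float:
        return self.strain_rate_s * PER_S_TO_PER_FS

    def pulling_velocity_A_fs(self, reference_length_A: float) -> float:
        """Grip velocity (Å/fs) for a given reference (gauge) length."""
        return self.strain_rate_fs * reference_length_A


class NoseHooverChain:
    """Nosé-Hoover chain (length 3 by default) acting on a bead subset."""

    def __init__(self, ndof: int, T: float, tau: float, chain: int = 3):
        self.ndof = ndof
        self.kT = KB * T
        self.Q = np.full(chain, self.kT * tau * tau)
        self.Q[0] *= ndof
        self.vxi = np.zeros(chain)
        self.xi = np.zeros(chain)

    def half_step(self, ke2: float, dt: float) -> float:
        """Advance the chain by dt/2; returns the velocity scale factor."""
        M = len(self.Q)
        dt2, dt4, dt8 = dt / 2.0, dt / 4.0, dt / 8.0
        G = np.empty(M)
        G[0] = (ke2 - self.ndof * self.kT) / self.Q[0]
        for k in range(1, M):
            G[k] = (self.Q[k - 1] * self.vxi[k - 1] ** 2 - self.kT) / self.Q[k]
        self.vxi[M - 1] += G[M - 1] * dt4
        for k in range(M - 2, -1, -1):
            e = math.exp(-dt8 * self.vxi[k + 1])
            self.vxi[k] = (self.vxi[k] * e + G[k] * dt4) * e
        s = math.exp(-dt2 * self.vxi[0])
        ke2 *= s * s
        self.xi += dt2 * self.vxi
        G[0] = (ke2 - self.ndof * self.kT) / self.Q[0]
        for k in range(M - 1):
            e = math.exp(-dt8 * self.vxi[k + 1])
            self.vxi[k] = (self.vxi[k] * e + G[k] * dt4) * e
            G[k + 1] = (self.Q[k] * self.vxi[k] ** 2 - self.kT) / self.Q[k + 1]
        self.vxi[M - 1] += G[M - 1] * dt4
        return s


@dataclass
class Trajectory:
    """Sampled observables of one run (arrays indexed by sample)."""

    time: np.ndarray
    strain: np.ndarray
    temperature: np.ndarray
    potential: np.ndarray
    total_energy: np.ndarray
    stress: np.ndarray            # (K,6) global, MPa, tensile positive
    phase_stress: np.ndarray      # (K,2,6) MPa per species (collagen, mineral)
    volume: np.ndarray            # Å^3 (fibril volume used for stress)
    box_lz: np.ndarray
    mol_com_z: np.ndarray         # (K, n_mol) Å
    mol_szz: np.ndarray           # (K, n_mol) MPa, per-protofibril mean
    mol_bond_strain: np.ndarray   # (K, n_mol) mean r/r0 - 1
    n_broken_bonds: np.ndarray
    n_broken_molecules: np.ndarray
    mol_slot_ids: np.ndarray      # molecule_id per column
    broken: np.ndarray            # final per-bond break flags
    mol_broken: np.ndarray        # final per-molecule break flags
    final_state: SimState
    frames: list = field(default_factory=list)
    frame_times: list = field(default_factory=list)


def fibril_volume(positions: np.ndarray, species: np.ndarray,
                  box, percentile: float = 95.0) -> float:
    """Current fibril volume pi R^2 L.

    R is the given percentile of the collagen radial distances (robust
    to stray surface beads); L is the axial box length when z is
    periodic, otherwise the current bead span.
    """
    col = positions[species == 0]
    if len(col) == 0:  # mineral-only system: fall back to all beads
        col = positions
    with np.errstate(invalid="ignore"):
        r = np.percentile(np.hypot(col[:, 0], col[:, 1]), percentile)
    if not np.isfinite(r):
        r = 0.0
    if bool(box.periodic[2]):
        L = box.lengths[2]
    else:
        L = positions[:, 2].max() - positions[:, 2].min()
    # degenerate single-chain / single-plane systems: keep V positive
    return math.pi * max(r, 1.0) ** 2 * max(L, 1.0)


def minimize(state: SimState, topology: BeadTopology, ff: ForceField,
             max_steps: int = 300, step_cap: float = 0.2,
             force_tol: float = 1.0, theta0=None) -> float:
    """Capped steepest-descent relaxation (removes steric overlaps left
    by lattice-based mineral placement before dynamics starts)."""
    if theta0 is None:
        theta0 = assign_theta0(topology, ff)
    nl = NeighborList(topology, ff.max_cutoff, skin=4.0)
    eng = _ForceEngine(topology, ff, theta0, nl,
                       broken=np.zeros(len(topology.bonds), np.bool_),
                       permanent=False)
    pos = state.positions
    alpha = 1e-3
    U_prev, F, _ = eng.evaluate(pos)
    for _ in range(max_steps):
        fmax = float(np.abs(F).max()) if F.size else 0.0
        if fmax < force_tol:
            break
        step = F * alpha
        maxdisp = float(np.abs(step).max())
        if maxdisp > step_cap:
            step *= step_cap / maxdisp
        trial = pos + step
        U, F_new, _ = eng.evaluate(trial)
        if U <= U_prev:
            pos[:] = trial
            U_prev, F = U, F_new
            alpha *= 1.2
        else:
            alpha *= 0.5
            if alpha < 1e-8:
                break
    state.positions = pos
    return U_prev


class _ForceEngine:
    """Caches the per-step invariants of the force evaluation.

    ``nl=None`` selects the O(N^2) all-pairs path (oracle/testing)."""

    def __init__(self, topology, ff: ForceField, theta0,
                 nl: NeighborList | None, broken, permanent: bool):
        self.topology = topology
        b = ff.bond if ff.bond.rbar1 is not None else derive_bond_branch(ff.bond)
        self.bond = b
        self.k_theta = ff.angle.k_theta
        self.theta0 = theta0
        self.eps, self.sig, self.rc = ff.pair_tables()
        self.species = topology.species.astype(np.int64)
        self.nl = nl
        self.broken = broken
        self.permanent = permanent
        self.Lz = float(topology.box.lengths[2])
        self.pbc_z = bool(topology.box.periodic[2])

    def evaluate(self, positions):
        n = len(positions)
        forces = np.zeros((n, 3))
        stress = np.zeros((n, 6))
        b = self.bond
        U = _kernels.bond_kernel(
            positions, self.topology.bonds, b.k0, b.k1, b.r0, b.rbar1,
            b.energy_offset, b.r1, b.r2, self.Lz, self.pbc_z,
            self.permanent, self.broken, forces, stress,
        )
        U += _kernels.angle_kernel(
            positions, self.topology.angles, self.k_theta, self.theta0,
            b.r2, self.Lz, self.pbc_z, forces, stress,
        )
        if self.nl is not None:
            pairs = self.nl.get(positions)
        else:
            from .forcefield import all_pairs
            pairs = all_pairs(self.topology, float(self.rc.max()),
                              positions=positions)
        U += _kernels.pair_kernel(
            positions, pairs, self.species, self.eps, self.sig, self.rc,
            self.Lz, self.pbc_z, forces, stress,
        )
        return U, forces, stress


def _molecule_slots(topology: BeadTopology):
    """Map beads and bonds onto dense molecule slots 0..n_mol-1."""
    mol = topology.molecule_id
    ids = np.unique(mol[mol >= 0])
    slot_of = {int(m): k for k, m in enumerate(ids)}
    bead_slot = np.full(topology.n_beads, -1, dtype=np.int64)
    for m, k in slot_of.items():
        bead_slot[mol == m] = k
    bond_slot = bead_slot[topology.bonds[:, 0]] if len(topology.bonds) else np.empty(0, np.int64)
    return ids, bead_slot, bond_slot


def integrate(
    state: SimState,
    topology: BeadTopology,
    ff: ForceField,
    n_steps: int,
    dt: float = 10.0,
    ensemble: str = "nvt",
    T: float = 300.0,
    thermostat: str = "nhc",
    tau: float | None = None,
    seed: int = 0,
    sample_every: int = 100,
    fixed: np.ndarray | None = None,
    pulled: np.ndarray | None = None,
    pull_velocity: float = 0.0,
    strain_per_fs: float = 0.0,
    permanent_breaks: bool = False,
    broken: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    barostat_tau: float = 1000.0,
    barostat_beta: float = 1e-5,   # MPa^-1 coupling of the z barostat
    p_target_mpa: float = 0.101325,  # 1 bar
    barostat_every: int = 10,
    frame_every: int = 0,
    neighbor_skin: float = 4.0,
    use_neighbor_list: bool = True,
) -> Trajectory:
    """Advance the system ``n_steps`` with velocity Verlet.

    Deterministic for a fixed seed (NHC uses no randomness at all).
    Samples are taken every ``sample_every`` steps, including step 0.
    """
    if ensemble not in ("nve", "nvt", "npt-z"):
        raise ValueError(f"unknown ensemble {ensemble!r}")
    if ensemble == "npt-z" and not bool(state.box.periodic[2]):
        raise SimulationError("npt-z requires a z-periodic box")
    n = topology.n_beads
    if len(state.positions) != n:
        raise SimulationError("state inconsistent with topology")
    if theta0 is None:
        theta0 = assign_theta0(topology, ff)
    if broken is None:
        broken = np.zeros(len(topology.bonds), dtype=np.bool_)

    free = np.ones(n, dtype=bool)
    if fixed is not None:
        free[fixed] = False
    if pulled is not None:
        free[pulled] = False
    n_free = int(free.sum())
    ndof = max(3 * n_free - 3, 1)

    if use_neighbor_list:
        nl = NeighborList(topology, ff.max_cutoff, skin=neighbor_skin)
        nl.check_cutoff(ff.max_cutoff)
    else:
        nl = None
    eng = _ForceEngine(topology, ff, theta0, nl, broken, permanent_breaks)

    pos = state.positions
    vel = state.velocities
    m = state.masses[:, None]
    inv_m = FORCE_TO_ACC / m

    if pulled is not None:
        vel[pulled] = 0.0
        vel[pulled, 2] = pull_velocity
    if fixed is not None:
        vel[fixed] = 0.0

    nhc = None
    rng = None
    use_thermo = ensemble in ("nvt", "npt-z")
    if tau is None:
        tau = 100.0 * dt
    if use_thermo and thermostat == "nhc":
        nhc = NoseHooverChain(ndof, T, tau)
    elif use_thermo and thermostat == "langevin":
        rng = np.random.default_rng(seed)
        c1 = math.exp(-dt / tau)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * T * FORCE_TO_ACC / state.masses[free])
    elif use_thermo:
        raise ValueError(f"unknown thermostat {thermostat!r}")

    ids, bead_slot, bond_slot = _molecule_slots(topology)
    n_mol = len(ids)
    col_per_slot = np.bincount(bead_slot[bead_slot >= 0], minlength=n_mol).astype(float)
    mass_per_slot = np.bincount(
        bead_slot[bead_slot >= 0], weights=state.masses[bead_slot >= 0], minlength=n_mol
    )
    bonds_per_slot = np.bincount(bond_slot, minlength=n_mol).astype(float) if len(bond_slot) else np.ones(n_mol)
    bonds_per_slot[bonds_per_slot == 0] = 1.0
    species = topology.species
    r0 = eng.bond.r0

    rec: dict[str, list] = {k: [] for k in (
        "time", "strain", "temperature", "potential", "total_energy",
        "stress", "phase_stress", "volume", "box_lz", "mol_com_z",
        "mol_szz", "mol_bond_strain", "n_broken_bonds", "n_broken_molecules",
    )}
    frames: list[np.ndarray] = []
    frame_times: list[float] = []

    def ke2_free() -> float:
        return _kernels.kinetic_energy_kernel(vel, state.masses, free) / FORCE_TO_ACC

    def bond_lengths() -> np.ndarray:
        d = pos[topology.bonds[:, 1]] - pos[topology.bonds[:, 0]]
        if eng.pbc_z:
            d[:, 2] -= eng.Lz * np.round(d[:, 2] / eng.Lz)
        return np.linalg.norm(d, axis=1)

    def sample(step: int, U: float, stress_arr: np.ndarray) -> None:
        if not np.isfinite(pos).all() or np.abs(pos).max() > 1e9:
            raise SimulationError(
                f"diverged (non-finite or runaway coordinates) at step {step} "
                f"(t = {state.time} fs)"
            )
        V = fibril_volume(pos, species, state.box)
        conv = KCAL_PER_MOL_A3_TO_MPA
        glob = stress_arr.sum(axis=0) / V * conv
        ph = np.zeros((2, 6))
        for sp in (0, 1):
            sel = species == sp
            n_sp = int(sel.sum())
            if n_sp:
                frac = n_sp / n
                ph[sp] = stress_arr[sel].sum(axis=0) / (V * frac) * conv
        szz_sum = np.bincount(
            bead_slot[bead_slot >= 0], weights=stress_arr[bead_slot >= 0, 2],
            minlength=n_mol,
        )
        mol_szz = szz_sum / col_per_slot * (n / V) * conv
        com = np.bincount(
            bead_slot[bead_slot >= 0],
            weights=pos[bead_slot >= 0, 2] * state.masses[bead_slot >= 0],
            minlength=n_mol,
        ) / mass_per_slot
        bl = bond_lengths() if len(topology.bonds) else np.empty(0)
        if len(bl):
            bs = np.bincount(bond_slot, weights=bl / r0 - 1.0, minlength=n_mol)
            mol_bs = bs / bonds_per_slot
            nb_broken = int(broken.sum())
            mol_broken_now = np.zeros(n_mol, dtype=bool)
            if nb_broken:
                mol_broken_now[np.unique(bond_slot[broken])] = True
            nm_broken = int(mol_broken_now.sum())
        else:
            mol_bs = np.zeros(n_mol)
            nb_broken = nm_broken = 0
        ke2 = ke2_free()
        rec["time"].append(state.time)
        rec["strain"].append(strain_per_fs * state.time)
        rec["temperature"].append(ke2 / (ndof * KB))
        rec["potential"].append(U)
        rec["total_energy"].append(U + 0.5 * ke2)
        rec["stress"].append(glob)
        rec["phase_stress"].append(ph)
        rec["volume"].append(V)
        rec["box_lz"].append(state.box.lengths[2])
        rec["mol_com_z"].append(com)
        rec["mol_szz"].append(mol_szz)
        rec["mol_bond_strain"].append(mol_bs)
        rec["n_broken_bonds"].append(nb_broken)
        rec["n_broken_molecules"].append(nm_broken)
        if frame_every and step % frame_every == 0:
            frames.append(pos.copy())
            frame_times.append(state.time)

    U, F, S = eng.evaluate(pos)
    t0 = state.time
    sample(0, U, S)

    # grips are enforced by re-imposing their exact coordinates after
    # each full-array update (cheaper than masked updates on every step)
    has_grips = fixed is not None or pulled is not None
    if fixed is not None:
        fixed_pos0 = pos[fixed].copy()
    if pulled is not None:
        pulled_xy0 = pos[pulled, :2].copy()
        pulled_z0 = pos[pulled, 2].copy()

    def impose_grips(step: int) -> None:
        if fixed is not None:
            pos[fixed] = fixed_pos0
            vel[fixed] = 0.0
        if pulled is not None:
            pos[pulled, :2] = pulled_xy0
            pos[pulled, 2] = pulled_z0 + pull_velocity * step * dt
            vel[pulled, :2] = 0.0
            vel[pulled, 2] = pull_velocity

    for step in range(1, n_steps + 1):
        if nhc is not None:
            s = nhc.half_step(ke2_free(), dt)
            vel *= s
        vel += 0.5 * dt * F * inv_m
        pos += dt * vel
        if has_grips:
            impose_grips(step)
        U, F, S = eng.evaluate(pos)
        vel += 0.5 * dt * F * inv_m
        if nhc is not None:
            s = nhc.half_step(ke2_free(), dt)
            vel *= s
        elif rng is not None:
            noise = rng.standard_normal((n_free, 3))
            vel[free] = c1 * vel[free] + c2[:, None] * noise
        if has_grips:
            impose_grips(step)
        if ensemble == "npt-z" and step % barostat_every == 0:
            V = fibril_volume(pos, species, state.box)
            szz = float(S[:, 2].sum()) / V * KCAL_PER_MOL_A3_TO_MPA
            p_zz = -szz  # pressure convention
            mu = 1.0 - (barostat_every * dt / barostat_tau) * barostat_beta * (
                p_target_mpa - p_zz
            )
            mu = min(max(mu, 1.0 - 1e-4), 1.0 + 1e-4)
            zc = 0.5 * (state.box.lo[2] + state.box.hi[2])
            pos[:, 2] = zc + (pos[:, 2] - zc) * mu
            state.box.lo[2] = zc + (state.box.lo[2] - zc) * mu
            state.box.hi[2] = zc + (state.box.hi[2] - zc) * mu
            eng.Lz = float(state.box.lengths[2])
            if nl is not None:
                nl.Lz = eng.Lz
                nl.pairs = None  # box changed: force rebuild
        state.time = t0 + step * dt
        if step % sample_every == 0 or step == n_steps:
            sample(step, U, S)

    mol_broken = np.zeros(n_mol, dtype=bool)
    if len(topology.bonds) and broken.any():
        mol_broken[np.unique(bond_slot[broken])] = True

    return Trajectory(
        time=np.array(rec["time"]),
        strain=np.array(rec["strain"]),
        temperature=np.array(rec["temperature"]),
        potential=np.array(rec["potential"]),
        total_energy=np.array(rec["total_energy"]),
        stress=np.array(rec["stress"]),
        phase_stress=np.array(rec["phase_stress"]),
        volume=np.array(rec["volume"]),
        box_lz=np.array(rec["box_lz"]),
        mol_com_z=np.array(rec["mol_com_z"]),
        mol_szz=np.array(rec["mol_szz"]),
        mol_bond_strain=np.array(rec["mol_bond_strain"]),
        n_broken_bonds=np.array(rec["n_broken_bonds"]),
        n_broken_molecules=np.array(rec["n_broken_molecules"]),
        mol_slot_ids=ids,
        broken=broken,
        mol_broken=mol_broken,
        final_state=state,
        frames=frames,
        frame_times=frame_times,
    )


def select_grips(positions: np.ndarray, grip_fraction: float):
    """Bead index arrays (fixed_bottom, pulled_top) for the end regions."""
    z = positions[:, 2]
    zmin, zmax = float(z.min()), float(z.max())
    span = zmax - zmin
    lo_face = zmin + grip_fraction * span
    hi_face = zmax - grip_fraction * span
    if lo_face >= hi_face:
        raise ValueError("grip regions overlap")
    fixed = np.nonzero(z <= lo_face)[0]
    pulled = np.nonzero(z >= hi_face)[0]
    return fixed, pulled, hi_face - lo_face


def run_tension(
    state: SimState,
    topology: BeadTopology,
    ff: ForceField,
    protocol: TensionProtocol,
    dt: float = 10.0,
    T: float = 300.0,
    thermostat: str = "nhc",
    frame_every: int = 0,
    n_steps: int | None = None,
    theta0: np.ndarray | None = None,
) -> Trajectory:
    """Constant-strain-rate uniaxial tension on an open-ended fibril.

    The engineering strain is grip displacement over the initial free
    length between the inner grip faces; the grip velocity is
    strain_rate x free length, so strain(t) = rate * t exactly.
    """
    if bool(state.box.periodic[2]):
        raise SimulationError("tension requires non-periodic z (open ends)")
    fixed, pulled, L_free0 = select_grips(state.positions, protocol.grip_fraction)
    v = protocol.pulling_velocity_A_fs(L_free0)
    rate = protocol.strain_rate_fs
    if n_steps is None:
        n_steps = int(math.ceil(protocol.target_strain / (rate * dt)))
    traj = integrate(
        state, topology, ff, n_steps, dt=dt, ensemble="nvt", T=T,
        thermostat=thermostat, seed=protocol.seed,
        sample_every=protocol.sample_interval,
        fixed=fixed, pulled=pulled, pull_velocity=v, strain_per_fs=rate,
        permanent_breaks=False, frame_every=frame_every, theta0=theta0,
    )
    # re-express strain relative to the start of this run
    traj.strain = traj.strain - traj.strain[0]
    return traj
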