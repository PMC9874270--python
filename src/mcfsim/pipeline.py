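"""High-level pipeline: build -> mineralize -> relax -> equilibrate ->
open ends -> uniaxial tension -> observables.

This is the programmatic counterpart of the command-line stages; the
CLI, the test suite and the result-reproduction script all drive the
same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fibril_geometry import (
    BeadTopology,
    FibrilSpec,
    ProtofibrilIndex,
    assign_protofibril_ids,
    build_idealized_fibril,
    open_chain_ends,
    wrap_z,
)
from .forcefield import ForceField, assign_theta0, default_forcefield
from .md_engine import (
    SimState,
    TensionProtocol,
    Trajectory,
    init_velocities,
    integrate,
    make_state,
    minimize,
    run_tension,
)
from .mechanics_analysis import (
    StressStrainCurve,
    curve_metrics,
    phase_curves,
    residual_strain,
    sliding_and_com,
)
from .mineralizer import (
    MassModel,
    MineralPattern,
    fill_fcc_region,
    tune_cutoff,
)

__all__ = ["TensionCase", "TensionCaseResult", "build_mineralized",
           "equilibrate_fibril", "simulate_tension_case"]


@dataclass(frozen=True)
class TensionCase:
    """One study condition: fibril geometry + mineralization + protocol."""

    spec: FibrilSpec = FibrilSpec()
    target_w: float = 0.0
    l_mineral: float = 0.44
    r_mineral_nm: float | None = None  # default: the fibril radius
    temperature_K: float = 300.0
    dt_fs: float = 10.0
    minimize_steps: int = 300
    equilibration_steps: int = 10000
    tension_strain_rate_s: float = 5.0e8
    tension_target_strain: float = 0.5
    grip_fraction: float = 0.025
    sample_interval: int = 200
    thermostat: str = "nhc"
    seed: int = 0


@dataclass
class TensionCaseResult:
    topology: BeadTopology          # as-built (periodic) structure
    open_topology: BeadTopology     # equilibrated, open-ended structure
    equilibration: Trajectory
    tension: Trajectory
    curve: StressStrainCurve
    index: ProtofibrilIndex
    residual: dict                  # residual strain after equilibration
    sliding: np.ndarray             # (K, n_mol) non-affine sliding, Å
    phase: "object"                 # phase_curves DataFrame

    def mean_abs_sliding(self, max_strain: float | None = None) -> float:
        """Time-mean of the per-protofibril |sliding| average, optionally
        restricted to strains up to ``max_strain``."""
        sel = np.ones(len(self.tension.strain), dtype=bool)
        if max_strain is not None:
            sel = self.tension.strain <= max_strain
        return float(np.abs(self.sliding[sel]).mean())


def build_mineralized(case: TensionCase, masses: MassModel) -> BeadTopology:
    topo = build_idealized_fibril(case.spec)
    if case.target_w > 0:
        r_m = case.r_mineral_nm or case.spec.diameter_nm / 2.0
        pattern = MineralPattern(
            l_mineral=case.l_mineral, r_mineral_nm=r_m, target_w=case.target_w
        )
        topo = tune_cutoff(fill_fcc_region(topo, pattern), pattern, masses).topology
    return topo


def equilibrate_fibril(
    topo: BeadTopology,
    ff: ForceField,
    masses: MassModel,
    case: TensionCase,
    theta0: np.ndarray,
) -> Trajectory:
    """Minimize then NPT-z (periodic builds) / NVT equilibration."""
    state = make_state(topo, masses)
    minimize(state, topo, ff, max_steps=case.minimize_steps, theta0=theta0)
    init_velocities(state, case.temperature_K, seed=case.seed)
    return integrate(
        state, topo, ff, n_steps=case.equilibration_steps, dt=case.dt_fs,
        ensemble="npt-z" if bool(topo.box.periodic[2]) else "nvt",
        T=case.temperature_K, thermostat=case.thermostat, seed=case.seed,
        sample_every=case.sample_interval, theta0=theta0,
    )


def simulate_tension_case(
    case: TensionCase,
    ff: ForceField | None = None,
    masses: MassModel | None = None,
    frame_every: int = 0,
) -> TensionCaseResult:
    """Run one full tension experiment and collect the observables.

    The per-angle equilibrium angles are fixed from the as-built
    geometry (180° for the straight synthetic fibril) and carried
    through every stage, so thermal curvature picked up during
    equilibration is not re-baselined.
    """
    ff = ff or default_forcefield()
    masses = masses or MassModel()
    topo = build_mineralized(case, masses)
    theta0 = assign_theta0(topo, ff)

    eq = equilibrate_fibril(topo, ff, masses, case, theta0)

    # carry the equilibrated geometry into an open-ended copy; the wrap
    # cut is decided on the *equilibrated* coordinates
    eq_topo = topo.copy()
    eq_topo.positions = eq.final_state.positions.copy()
    eq_topo.box = eq.final_state.box.copy()
    wrap_z(eq_topo)
    open_topo = open_chain_ends(eq_topo)
    theta0_open = theta0[open_topo.meta["kept_angles"]]
    resid = residual_strain(open_topo)

    protocol = TensionProtocol(
        strain_rate_s=case.tension_strain_rate_s,
        grip_fraction=case.grip_fraction,
        target_strain=case.tension_target_strain,
        sample_interval=case.sample_interval,
        seed=case.seed,
    )
    state = SimState(
        positions=open_topo.positions.copy(),
        velocities=eq.final_state.velocities.copy(),
        masses=eq.final_state.masses.copy(),
        box=open_topo.box.copy(),
        time=0.0,
    )
    state.box.lo[2] = eq_topo.box.lo[2]
    state.box.hi[2] = eq_topo.box.hi[2]
    state.box.periodic[2] = False
    traj = run_tension(
        state, open_topo, ff, protocol, dt=case.dt_fs, T=case.temperature_K,
        thermostat=case.thermostat, frame_every=frame_every, theta0=theta0_open,
    )
    curve = curve_metrics(traj.strain, traj.stress[:, 2])
    index = assign_protofibril_ids(open_topo)
    z_fixed = float(open_topo.positions[:, 2].min())
    slide = sliding_and_com(traj.mol_com_z, traj.strain, z_fixed)
    return TensionCaseResult(
        topology=topo, open_topology=open_topo, equilibration=eq,
        tension=traj, curve=curve, index=index, residual=resid,
        sliding=slide["sliding"], phase=phase_curves(traj),
    )
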