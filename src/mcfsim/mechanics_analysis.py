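"""Observables: per-bead virial stress, phase-resolved stress,
stress-strain metrics, protofibril sliding / centre-of-mass, fracture
accounting, mineralized-protofibril classification and residual strain.

Conventions
-----------
* Stress is configurational (virial) only — no kinetic term — in
  tensile-positive sign convention, reported in MPa.
* The fibril volume is pi R^2 L with R the 95th-percentile collagen
  radial distance and L the current axial extent.
* "Shear stress" of a phase is sqrt(s_xz^2 + s_yz^2) of its tensor.
* The secant modulus is stress/strain at 4 % strain; toughness is the
  area under the curve up to the fracture strain; the fracture strain
  is where the (smoothed) stress first falls below 10 % of the UTS
  after the peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fibril_geometry import BeadTopology, ProtofibrilIndex
from .forcefield import BondParams, ForceField, system_energy_forces
from .md_engine import Trajectory, fibril_volume
from .units import KCAL_PER_MOL_A3_TO_MPA

__all__ = [
    "StressRecord",
    "StressStrainCurve",
    "per_bead_virial",
    "phase_stress",
    "curve_metrics",
    "sliding_and_com",
    "fracture_accounting",
    "classify_protofibrils",
    "residual_strain",
    "phase_curves",
]


@dataclass
class StressRecord:
    strain: float
    per_bead: np.ndarray        # (N,6) kcal/mol (stress * volume)
    volume: float               # Å^3
    global_stress: np.ndarray   # (6,) MPa

    def tensor(self) -> np.ndarray:
        s = self.global_stress
        return np.array([
            [s[0], s[3], s[4]],
            [s[3], s[1], s[5]],
            [s[4], s[5], s[2]],
        ])


def per_bead_virial(
    positions: np.ndarray,
    topology: BeadTopology,
    ff: ForceField,
    strain: float = 0.0,
    volume: float | None = None,
    **kwargs,
) -> StressRecord:
    """Per-bead virial tensors and the global stress of one frame."""
    sf = system_energy_forces(positions, topology, ff, **kwargs)
    if volume is None:
        volume = fibril_volume(positions, topology.species, topology.box)
    glob = sf.per_bead_stress.sum(axis=0) / volume * KCAL_PER_MOL_A3_TO_MPA
    return StressRecord(strain, sf.per_bead_stress, volume, glob)


def phase_stress(record: StressRecord, topology: BeadTopology) -> dict:
    """Per-species stress with volume proportional to bead fraction.

    Returns {"collagen": {...}, "mineral": {...}, "global": {...}};
    each entry carries the full tensor (MPa), the tensile component
    sigma_zz and the axial shear sqrt(s_xz^2+s_yz^2).  The
    bead-fraction-weighted sum of phase tensors equals the global
    tensor identically.
    """
    n = topology.n_beads
    out = {}
    conv = KCAL_PER_MOL_A3_TO_MPA
    for name, sp in (("collagen", 0), ("mineral", 1)):
        sel = topology.species == sp
        n_sp = int(sel.sum())
        if n_sp == 0:
            out[name] = {"tensor": np.zeros(6), "tensile": 0.0, "shear": 0.0,
                         "fraction": 0.0}
            continue
        frac = n_sp / n
        t = record.per_bead[sel].sum(axis=0) / (record.volume * frac) * conv
        out[name] = {
            "tensor": t,
            "tensile": float(t[2]),
            "shear": float(math.hypot(t[4], t[5])),
            "fraction": frac,
        }
    g = record.global_stress
    out["global"] = {"tensor": g, "tensile": float(g[2]),
                     "shear": float(math.hypot(g[4], g[5])), "fraction": 1.0}
    return out


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(y) < 3:
        return y.astype(float)
    w = min(window if window % 2 == 1 else window + 1, len(y) // 2 * 2 - 1)
    if w <= 1:
        return y.astype(float)
    pad = w // 2
    ypad = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    kernel = np.ones(w) / w
    return np.convolve(ypad, kernel, mode="valid")


@dataclass
class StressStrainCurve:
    strain: np.ndarray
    stress: np.ndarray            # raw, MPa
    stress_smooth: np.ndarray
    secant_modulus: float         # MPa, sigma(0.04)/0.04
    uts: float                    # MPa
    uts_strain: float
    fracture_strain: float | None
    toughness: float | None       # MPa (== MJ/m^3 per unit strain)
    residual_stress: float        # MPa at zero applied strain

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"strain": self.strain, "stress_MPa": self.stress,
             "stress_smooth_MPa": self.stress_smooth}
        )


def curve_metrics(strain: np.ndarray, stress: np.ndarray,
                  smooth_window: int = 11) -> StressStrainCurve:
    """Derived metrics of a sampled stress-strain curve.

    Fracture metrics are None when the curve never drops below 10 % of
    its UTS after the peak (no post-peak data).
    """
    strain = np.asarray(strain, float)
    stress = np.asarray(stress, float)
    if len(strain) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(strain) < 0):
        raise ValueError("strain must be non-decreasing")
    ss = _smooth(stress, smooth_window)
    if strain[-1] < 0.04:
        secant = float("nan")
    else:
        secant = float(np.interp(0.04, strain, ss)) / 0.04
    i_uts = int(np.argmax(ss))
    uts = float(ss[i_uts])
    frac_strain = None
    toughness = None
    if uts > 0:
        post = np.nonzero(ss[i_uts:] < 0.10 * uts)[0]
        if len(post):
            i_drop = i_uts + post[0]
            frac_strain = float(strain[i_drop - 1]) if i_drop > 0 else float(strain[0])
            sel = strain <= frac_strain + 1e-15
            toughness = float(np.trapezoid(ss[sel], strain[sel]))
    return StressStrainCurve(
        strain=strain, stress=stress, stress_smooth=ss,
        secant_modulus=secant, uts=uts, uts_strain=float(strain[i_uts]),
        fracture_strain=frac_strain, toughness=toughness,
        residual_stress=float(ss[0]),
    )


def phase_curves(traj: Trajectory) -> pd.DataFrame:
    """Tensile/shear stress of each phase vs strain from a trajectory."""
    ph = traj.phase_stress
    return pd.DataFrame({
        "strain": traj.strain,
        "stress_MPa": traj.stress[:, 2],
        "collagen_tensile_MPa": ph[:, 0, 2],
        "collagen_shear_MPa": np.hypot(ph[:, 0, 4], ph[:, 0, 5]),
        "mineral_tensile_MPa": ph[:, 1, 2],
        "mineral_shear_MPa": np.hypot(ph[:, 1, 4], ph[:, 1, 5]),
    })


def sliding_and_com(
    mol_com_z: np.ndarray,
    strain: np.ndarray,
    z_fixed: float,
    current_length: np.ndarray | None = None,
    z_min: float | None = None,
) -> dict:
    """Non-affine protofibril sliding and scaled centre of mass.

    sliding_i(t) = [com_i(t) - com_i(0)] - strain(t) * [com_i(0) - z_fixed]

    so a purely affine stretch (about the fixed grip) gives exactly zero
    for every protofibril.  The scaled COM is (com - z_min)/L(t).
    """
    com0 = mol_com_z[0]
    affine = strain[:, None] * (com0[None, :] - z_fixed)
    sliding = (mol_com_z - com0[None, :]) - affine
    out = {"sliding": sliding}
    if current_length is not None:
        zm = z_min if z_min is not None else z_fixed
        out["scaled_com"] = (mol_com_z - zm) / current_length[:, None]
    return out


def fracture_accounting(traj: Trajectory) -> pd.DataFrame:
    """Broken-protofibril counts vs strain (monotone non-decreasing)."""
    return pd.DataFrame({
        "strain": traj.strain,
        "n_broken_bonds": traj.n_broken_bonds,
        "n_broken_protofibrils": traj.n_broken_molecules,
    })


def axial_position_profile(
    positions: np.ndarray,
    topology: BeadTopology,
    index: ProtofibrilIndex,
    per_bead_szz: np.ndarray | None = None,
    mineralized: dict | None = None,
) -> pd.DataFrame:
    """Axial-position vs protofibril-ID table for fracture plots.

    One row per collagen bead: protofibril ID, axial position, and
    (optionally) the bead tensile stress and the mineralized flag of its
    protofibril.
    """
    mask = topology.collagen_mask
    pid = index.bead_protofibril_id[mask]
    data = {"protofibril_id": pid, "z_A": positions[mask, 2]}
    if per_bead_szz is not None:
        data["stress_zz"] = per_bead_szz[mask]
    if mineralized is not None:
        mol = topology.molecule_id[mask]
        data["mineralized"] = np.array([mineralized[int(m)] for m in mol])
    return pd.DataFrame(data).sort_values(
        ["protofibril_id", "z_A"], kind="stable"
    ).reset_index(drop=True)


def classify_protofibrils(
    topology: BeadTopology, cutoff: float = 20.0
) -> dict:
    """Mineralized flag per molecule: at least one mineral bead within
    the collagen-HAp interaction cutoff of any of the molecule's beads."""
    minerals = topology.positions[topology.mineral_mask]
    flags = {}
    if len(minerals) == 0:
        for ix in topology.molecule_indices():
            flags[int(topology.molecule_id[ix[0]])] = False
        return flags
    if bool(topology.box.periodic[2]):
        L = topology.box.lengths[2]
        minerals = np.vstack([
            minerals,
            minerals + np.array([0.0, 0.0, L]),
            minerals - np.array([0.0, 0.0, L]),
        ])
    tree = cKDTree(minerals)
    for ix in topology.molecule_indices():
        d, _ = tree.query(topology.positions[ix], k=1)
        flags[int(topology.molecule_id[ix[0]])] = bool((d < cutoff).any())
    return flags


def residual_strain(
    topology: BeadTopology,
    positions: np.ndarray | None = None,
    r0: float | None = None,
) -> dict:
    """Per-protofibril and fibril-mean residual (stored bond) strain.

    The residual strain of a protofibril is the mean bond strain
    r/r0 - 1 over its bonds; the fibril value is the bond-count-weighted
    mean, i.e. the mean over all bonds.
    """
    if positions is None:
        positions = topology.positions
    if r0 is None:
        r0 = BondParams().r0
    d = positions[topology.bonds[:, 1]] - positions[topology.bonds[:, 0]]
    if bool(topology.box.periodic[2]):
        L = topology.box.lengths[2]
        d[:, 2] -= L * np.round(d[:, 2] / L)
    r = np.linalg.norm(d, axis=1)
    strain = r / r0 - 1.0
    mol_of_bond = topology.molecule_id[topology.bonds[:, 0]]
    per_mol = {}
    for m in np.unique(mol_of_bond):
        per_mol[int(m)] = float(strain[mol_of_bond == m].mean())
    return {"per_protofibril": per_mol, "fibril": float(strain.mean())}
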