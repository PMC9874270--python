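"""Mineralization patterning: FCC hydroxyapatite fill, proximity carving
and mass-fraction tuning.

Mineral beads are placed on a face-centred-cubic lattice inside
cylindrical mineralization regions of axial extent ``l_mineral * D``
(one per D-period, centred on the gap midpoint) and radius
``r_mineral``.  Beads too close to collagen are then carved away; the
carve cutoff is tuned by bisection until the mineral mass fraction
(degree of mineralization, w/w) reaches its target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .fibril_geometry import (
    BeadTopology,
    SPECIES_MINERAL,
    MINERAL_MOLECULE_ID,
    gap_centers,
)

__all__ = [
    "MineralPattern",
    "MassModel",
    "MineralizationError",
    "fill_fcc_region",
    "carve_by_cutoff",
    "tune_cutoff",
    "mineral_mass_fractions",
    "default_lattice_constant",
]

# HAp-HAp Lennard-Jones sigma; the FCC nearest-neighbour distance is set
# to the LJ minimum 2^(1/6)*sigma, giving a = sqrt(2)*2^(1/6)*sigma.
_SIGMA_HAP = 10.28


def default_lattice_constant(sigma: float = _SIGMA_HAP) -> float:
    return math.sqrt(2.0) * 2.0 ** (1.0 / 6.0) * sigma


class MineralizationError(ValueError):
    pass


@dataclass(frozen=True)
class MineralPattern:
    """Mineralization pattern parameters.

    ``l_mineral`` is the axial region length as a fraction of D
    (0.44 confines mineral to the gap region at the default geometry;
    1.0 mineralizes the whole period).  ``r_mineral_nm`` is the region
    radius; at most the fibril radius.  ``target_w`` is the mineral mass
    fraction (0.05 and 0.35 are the two degrees studied).
    """

    l_mineral: float = 0.44
    r_mineral_nm: float = 10.0
    target_w: float = 0.35
    lattice_constant_A: float = default_lattice_constant()
    carve_cutoff_A: float | None = None
    center_rule: str = "gap-centered"

    def __post_init__(self) -> None:
        if not 0.0 < self.l_mineral <= 1.0:
            raise MineralizationError("l_mineral must be in (0, 1] of D")
        if self.r_mineral_nm <= 0:
            raise MineralizationError("r_mineral must be positive")
        if not 0.0 <= self.target_w < 1.0:
            raise MineralizationError("target_w must be in [0, 1)")
        if self.lattice_constant_A <= 0:
            raise MineralizationError("lattice constant must be positive")
        if self.center_rule != "gap-centered":
            raise MineralizationError(f"unknown center_rule {self.center_rule!r}")


@dataclass(frozen=True)
class MassModel:
    """Bead masses (amu).

    The tropocollagen mass (~285 kDa) spread over 219 beads gives
    ~1301 amu per collagen bead; mineral beads default to the same mass
    so that w/w equals the bead-count fraction.
    """

    m_collagen: float = 285000.0 / 219.0
    m_mineral: float = 285000.0 / 219.0

    def __post_init__(self) -> None:
        if self.m_collagen <= 0 or self.m_mineral <= 0:
            raise MineralizationError("bead masses must be positive")


def _fcc_points(a: float, origin: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """FCC lattice points of cell edge ``a`` covering a box at ``origin``."""
    ncell = np.ceil(extent / a).astype(int) + 1
    ii, jj, kk = np.meshgrid(
        np.arange(ncell[0]), np.arange(ncell[1]), np.arange(ncell[2]), indexing="ij"
    )
    base = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float) * a
    offs = np.array(
        [[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]
    ) * a
    pts = (base[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    return pts + origin


def fill_fcc_region(topology: BeadTopology, pattern: MineralPattern) -> BeadTopology:
    """Overlay every gap region with an FCC-filled mineralization cylinder.

    One cylinder per D-period, centred axially on the gap midpoint,
    extending symmetrically (into the overlap region once
    ``l_mineral > gap_fraction``).  The lattice is anchored at the
    region corner.  Returns a new topology with mineral beads appended.
    """
    if topology.region_label is None:
        raise MineralizationError("topology must be gap/overlap labeled first")
    if topology.mineral_mask.any():
        raise MineralizationError("topology already contains mineral beads")
    D = topology.meta["D_A"]
    r_m = pattern.r_mineral_nm * 10.0
    spec = topology.meta.get("spec")
    if spec is not None and r_m > spec.radius_A + 1e-9:
        raise MineralizationError(
            f"r_mineral {pattern.r_mineral_nm} nm exceeds the fibril radius"
        )
    a = pattern.lattice_constant_A
    L = topology.box.lengths[2]
    periodic = bool(topology.box.periodic[2])
    half = pattern.l_mineral * D / 2.0

    chunks = []
    for zc in gap_centers(topology):
        zlo, zhi = zc - half, zc + half
        if not periodic and (zlo < topology.box.lo[2] - 1e-9 or zhi > topology.box.hi[2] + 1e-9):
            raise MineralizationError(
                f"mineralization region [{zlo:.1f}, {zhi:.1f}] Å lies outside the box"
            )
        origin = np.array([-r_m, -r_m, zlo])
        extent = np.array([2 * r_m, 2 * r_m, zhi - zlo])
        pts = _fcc_points(a, origin, extent)
        inside = (
            (pts[:, 0] ** 2 + pts[:, 1] ** 2 <= r_m * r_m + 1e-9)
            & (pts[:, 2] >= zlo - 1e-9)
            & (pts[:, 2] <= zhi + 1e-9)
        )
        chunks.append(pts[inside])
    minerals = np.vstack(chunks)
    if periodic:
        minerals[:, 2] = np.mod(minerals[:, 2], L)

    # de-duplicate beads from abutting/overlapping regions
    if len(minerals) > 1:
        tree = cKDTree(minerals)
        close = tree.query_pairs(0.5 * a, output_type="ndarray")
        if len(close):
            drop = np.zeros(len(minerals), dtype=bool)
            for i, j in close[np.lexsort((close[:, 1], close[:, 0]))]:
                if not drop[i]:
                    drop[j] = True
            minerals = minerals[~drop]

    n_m = len(minerals)
    out = topology.copy()
    out.positions = np.vstack([topology.positions, minerals])
    out.species = np.concatenate(
        [topology.species, np.full(n_m, SPECIES_MINERAL, dtype=np.uint8)]
    )
    out.molecule_id = np.concatenate(
        [topology.molecule_id, np.full(n_m, MINERAL_MOLECULE_ID, dtype=np.int64)]
    )
    # label the new beads
    g = topology.meta["gap_fraction"]
    frac = np.mod(minerals[:, 2], D) / D
    m_label = (frac >= 1.0 - g).astype(np.uint8)
    out.region_label = np.concatenate([topology.region_label, m_label])
    out.meta["l_mineral"] = pattern.l_mineral
    out.meta["r_mineral_nm"] = pattern.r_mineral_nm
    return out


def _mineral_collagen_distances(topology: BeadTopology) -> np.ndarray:
    """Minimum distance from each mineral bead to any collagen bead."""
    col = topology.positions[topology.collagen_mask]
    mins = topology.positions[topology.mineral_mask]
    if len(mins) == 0:
        return np.empty(0)
    if bool(topology.box.periodic[2]):
        L = topology.box.lengths[2]
        images = [col]
        for shift in (-L, L):
            img = col.copy()
            img[:, 2] += shift
            images.append(img)
        col = np.vstack(images)
    tree = cKDTree(col)
    d, _ = tree.query(mins, k=1)
    return d


def carve_by_cutoff(topology: BeadTopology, cutoff: float) -> BeadTopology:
    """Remove mineral beads closer than ``cutoff`` to any collagen bead."""
    if cutoff < 0:
        raise MineralizationError("carve cutoff must be non-negative")
    d = _mineral_collagen_distances(topology)
    keep_mineral = d >= cutoff
    return _select_minerals(topology, keep_mineral)


def _select_minerals(topology: BeadTopology, keep_mineral: np.ndarray) -> BeadTopology:
    n_col = int(topology.collagen_mask.sum())
    keep = np.concatenate([np.ones(n_col, dtype=bool), keep_mineral])
    out = topology.copy()
    out.positions = topology.positions[keep]
    out.species = topology.species[keep]
    out.molecule_id = topology.molecule_id[keep]
    if topology.region_label is not None:
        out.region_label = topology.region_label[keep]
    # collagen beads keep their indices (minerals are the array tail)
    return out


def mineral_mass_fractions(topology: BeadTopology, masses: MassModel) -> dict:
    """Total / gap / overlap mineral mass fractions (of total system mass)."""
    if topology.region_label is None:
        raise MineralizationError("topology must be gap/overlap labeled")
    m_col = float(topology.collagen_mask.sum()) * masses.m_collagen
    mineral = topology.mineral_mask
    m_min = float(mineral.sum()) * masses.m_mineral
    total = m_col + m_min
    if total == 0:
        return {"total_w": 0.0, "gap_w": 0.0, "overlap_w": 0.0}
    gap_m = float((mineral & (topology.region_label == 1)).sum()) * masses.m_mineral
    ovl_m = float((mineral & (topology.region_label == 0)).sum()) * masses.m_mineral
    return {
        "total_w": m_min / total,
        "gap_w": gap_m / total,
        "overlap_w": ovl_m / total,
    }


@dataclass
class TuneResult:
    cutoff: float
    topology: BeadTopology
    achieved_w: float
    iterations: int


def tune_cutoff(
    topology: BeadTopology,
    pattern: MineralPattern,
    masses: MassModel,
    tol: float = 0.0025,
    max_iter: int = 60,
) -> TuneResult:
    """Bisection over the carve cutoff to hit ``pattern.target_w``.

    The achieved w/w is a non-increasing step function of the cutoff;
    each mineral bead's nearest-collagen distance is computed once, so
    every bisection step is a simple threshold count.  Raises if the
    target exceeds the uncarved maximum.
    """
    target = pattern.target_w
    d = _mineral_collagen_distances(topology)
    m_col = float(topology.collagen_mask.sum()) * masses.m_collagen

    def w_at(c: float) -> float:
        m_min = float((d >= c).sum()) * masses.m_mineral
        return m_min / (m_col + m_min)

    w0 = w_at(0.0)
    if target > w0 + 1e-12:
        raise MineralizationError(
            f"target w/w {target:.4f} unachievable; maximum without carving is {w0:.4f}"
        )
    if target == 0.0:
        carved = _select_minerals(topology, np.zeros(len(d), dtype=bool))
        return TuneResult(float(d.max() + 1.0) if len(d) else 0.0, carved, 0.0, 0)

    lo, hi = 0.0, float(d.max()) + 1.0  # w(lo) >= target > 0 = w(hi)
    best_c, best_err = lo, abs(w0 - target)
    it = 0
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        w = w_at(mid)
        err = abs(w - target)
        if err < best_err - 1e-15:
            best_c, best_err = mid, err
        if err <= tol:
            best_c, best_err = mid, err
            break
        if w > target:
            lo = mid
        else:
            hi = mid
    achieved = w_at(best_c)
    carved = _select_minerals(topology, d >= best_c)
    return TuneResult(best_c, carved, achieved, it)
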