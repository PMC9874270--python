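"""Numba kernels for the force/energy/virial inner loops.

All kernels accumulate into caller-provided ``forces`` (N,3) and
``stress`` (N,6) arrays and return the potential energy of their term.
The per-bead stress is the configurational virial in tensile-positive
convention, in units of kcal/mol (stress * volume); component order is
xx, yy, zz, xy, xz, yz.  Only the z axis may be periodic (axial cell).
"""

import math

from numba import njit

__all__ = ["bond_kernel", "angle_kernel", "pair_kernel", "kinetic_energy_kernel"]


@njit(cache=True)
def bond_kernel(pos, bonds, k0, k1, r0, rbar1, offset, r1, r2,
                Lz, pbc_z, permanent, broken, forces, stress):
    """Bilinear breakable bond: harmonic (k0, r0) below r1, harmonic
    (k1, rbar1) plus energy offset between r1 and r2, zero beyond r2.

    ``broken`` flags are set whenever a bond is found at r >= r2; in
    ``permanent`` mode flagged bonds are skipped for good, otherwise the
    potential is stateless and re-engages if the bond shortens again.
    """
    U = 0.0
    for b in range(bonds.shape[0]):
        if permanent and broken[b]:
            continue
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if pbc_z:
            dz -= Lz * round(dz / Lz)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= r2:
            broken[b] = True
            continue
        if r < r1:
            dU = k0 * (r - r0)
            U += 0.5 * k0 * (r - r0) * (r - r0)
        else:
            dU = k1 * (r - rbar1)
            U += 0.5 * k1 * (r - rbar1) * (r - rbar1) + offset
        inv_r = 1.0 / r
        fx = -dU * dx * inv_r   # force on bead j
        fy = -dU * dy * inv_r
        fz = -dU * dz * inv_r
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        w = 0.5 * dU * inv_r  # half per bead, tensile positive
        stress[i, 0] += w * dx * dx
        stress[j, 0] += w * dx * dx
        stress[i, 1] += w * dy * dy
        stress[j, 1] += w * dy * dy
        stress[i, 2] += w * dz * dz
        stress[j, 2] += w * dz * dz
        stress[i, 3] += w * dx * dy
        stress[j, 3] += w * dx * dy
        stress[i, 4] += w * dx * dz
        stress[j, 4] += w * dx * dz
        stress[i, 5] += w * dy * dz
        stress[j, 5] += w * dy * dz
    return U


@njit(cache=True)
def angle_kernel(pos, angles, k_theta, theta0, r2_bond,
                 Lz, pbc_z, forces, stress):
    """Harmonic angle U = 1/2 k (theta - theta0)^2 with per-angle theta0.

    An angle is inactive whenever either of its two constituent bonds is
    longer than the bond cutoff ``r2_bond`` (a broken chain carries no
    bending stiffness).  Near-collinear geometry is handled by clamping
    sin(theta), which reproduces the finite theta -> pi limit.
    """
    U = 0.0
    for a in range(angles.shape[0]):
        i1 = angles[a, 0]
        i2 = angles[a, 1]
        i3 = angles[a, 2]
        d1x = pos[i1, 0] - pos[i2, 0]
        d1y = pos[i1, 1] - pos[i2, 1]
        d1z = pos[i1, 2] - pos[i2, 2]
        d3x = pos[i3, 0] - pos[i2, 0]
        d3y = pos[i3, 1] - pos[i2, 1]
        d3z = pos[i3, 2] - pos[i2, 2]
        if pbc_z:
            d1z -= Lz * round(d1z / Lz)
            d3z -= Lz * round(d3z / Lz)
        r1 = math.sqrt(d1x * d1x + d1y * d1y + d1z * d1z)
        r3 = math.sqrt(d3x * d3x + d3y * d3y + d3z * d3z)
        if r1 >= r2_bond or r3 >= r2_bond:
            continue
        c = (d1x * d3x + d1y * d3y + d1z * d3z) / (r1 * r3)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = math.acos(c)
        dth = th - theta0[a]
        U += 0.5 * k_theta * dth * dth
        s = math.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        dU = k_theta * dth  # dU/dtheta
        a1 = dU / (s * r1)
        a3 = dU / (s * r3)
        # unit vectors
        u1x, u1y, u1z = d1x / r1, d1y / r1, d1z / r1
        u3x, u3y, u3z = d3x / r3, d3y / r3, d3z / r3
        f1x = a1 * (u3x - c * u1x)
        f1y = a1 * (u3y - c * u1y)
        f1z = a1 * (u3z - c * u1z)
        f3x = a3 * (u1x - c * u3x)
        f3y = a3 * (u1y - c * u3y)
        f3z = a3 * (u1z - c * u3z)
        forces[i1, 0] += f1x
        forces[i1, 1] += f1y
        forces[i1, 2] += f1z
        forces[i3, 0] += f3x
        forces[i3, 1] += f3y
        forces[i3, 2] += f3z
        forces[i2, 0] -= f1x + f3x
        forces[i2, 1] -= f1y + f3y
        forces[i2, 2] -= f1z + f3z
        # virial (tensile positive): W_ab = -(d1_a f1_b + d3_a f3_b), 1/3 each
        third = 1.0 / 3.0
        wxx = -(d1x * f1x + d3x * f3x) * third
        wyy = -(d1y * f1y + d3y * f3y) * third
        wzz = -(d1z * f1z + d3z * f3z) * third
        wxy = -(d1x * f1y + d3x * f3y) * third
        wxz = -(d1x * f1z + d3x * f3z) * third
        wyz = -(d1y * f1z + d3y * f3z) * third
        for idx in (i1, i2, i3):
            stress[idx, 0] += wxx
            stress[idx, 1] += wyy
            stress[idx, 2] += wzz
            stress[idx, 3] += wxy
            stress[idx, 4] += wxz
            stress[idx, 5] += wyz
    return U


@njit(cache=True)
def pair_kernel(pos, pairs, species, eps_t, sig_t, rc_t,
                Lz, pbc_z, forces, stress):
    """Truncated (unshifted) Lennard-Jones over an explicit pair list.

    Parameters are species-pair tables (2x2).  Pairs beyond their
    cutoff contribute exactly zero, so a skin-padded list is safe.
    """
    U = 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if pbc_z:
            dz -= Lz * round(dz / Lz)
        r2 = dx * dx + dy * dy + dz * dz
        si = species[i]
        sj = species[j]
        rc = rc_t[si, sj]
        if r2 >= rc * rc:
            continue
        eps = eps_t[si, sj]
        sig = sig_t[si, sj]
        sr2 = sig * sig / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        U += 4.0 * eps * (sr12 - sr6)
        r = math.sqrt(r2)
        dU = 24.0 * eps * (sr6 - 2.0 * sr12) / r  # dU/dr
        inv_r = 1.0 / r
        fx = -dU * dx * inv_r
        fy = -dU * dy * inv_r
        fz = -dU * dz * inv_r
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        w = 0.5 * dU * inv_r
        stress[i, 0] += w * dx * dx
        stress[j, 0] += w * dx * dx
        stress[i, 1] += w * dy * dy
        stress[j, 1] += w * dy * dy
        stress[i, 2] += w * dz * dz
        stress[j, 2] += w * dz * dz
        stress[i, 3] += w * dx * dy
        stress[j, 3] += w * dx * dy
        stress[i, 4] += w * dx * dz
        stress[j, 4] += w * dx * dz
        stress[i, 5] += w * dy * dz
        stress[j, 5] += w * dy * dz
    return U


@njit(cache=True)
def kinetic_energy_kernel(vel, masses, mask):
    """Sum m v^2 over masked beads (amu Å^2/fs^2; divide by the
    acceleration constant for kcal/mol)."""
    acc = 0.0
    for i in range(vel.shape[0]):
        if mask[i]:
            acc += masses[i] * (
                vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1] + vel[i, 2] * vel[i, 2]
            )
    return acc
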