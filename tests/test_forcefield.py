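"""Force-field terms: bilinear bond closure/continuity, harmonic angle
gradients, truncated LJ, and the system assembly against independent
brute-force references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcfsim.fibril_geometry import BeadTopology, Box
from mcfsim.forcefield import (
    AngleParams,
    BondParams,
    PairParams,
    angle_energy,
    angle_forces,
    assign_theta0,
    bond_energy_force,
    derive_bond_branch,
    pair_energy_force,
    system_energy_forces,
)


@pytest.fixture(scope="module")
def bond():
    return derive_bond_branch(BondParams())


class TestBondBranch:
    def test_closure_values(self, bond):
        assert bond.rbar1 == pytest.approx(18.20 - (17.13 / 97.66) * 4.20,
                                           rel=1e-12)
        offset = 0.5 * 17.13 * 4.2 ** 2 - 0.5 * 97.66 * (18.2 - bond.rbar1) ** 2
        assert bond.energy_offset == pytest.approx(offset, rel=1e-12)

    def test_equal_stiffness_degenerates(self):
        p = derive_bond_branch(BondParams(k0=17.13, k1=17.13))
        assert p.rbar1 == pytest.approx(p.r0, rel=1e-12)
        assert p.energy_offset == pytest.approx(0.0, abs=1e-12)

    def test_continuity_at_switch(self, bond):
        eps = 1e-9
        U_lo, F_lo = bond_energy_force(bond.r1 - eps, bond)
        U_hi, F_hi = bond_energy_force(bond.r1 + eps, bond)
        assert U_lo == pytest.approx(U_hi, abs=1e-6)
        assert F_lo == pytest.approx(F_hi, abs=1e-6)

    def test_rupture_discontinuity_documented(self, bond):
        """The drop at r2 equals the stored bond energy just below r2."""
        U_stored, _ = bond_energy_force(bond.r2 - 1e-12, bond)
        assert bond_energy_force(bond.r2, bond) == (0.0, 0.0)
        assert U_stored > 700.0  # large stored energy released on rupture


class TestBondEvaluation:
    def test_equilibrium(self, bond):
        assert bond_energy_force(14.0, bond) == (0.0, 0.0)

    def test_small_branch_value(self, bond):
        U, F = bond_energy_force(15.0, bond)
        assert U == pytest.approx(0.5 * 17.13, rel=1e-12)
        assert F == pytest.approx(-17.13, rel=1e-12)

    def test_beyond_cutoff_zero(self, bond):
        assert bond_energy_force(21.5, bond) == (0.0, 0.0)

    @given(st.floats(10.0, 25.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_force_is_energy_gradient(self, r):
        bond = derive_bond_branch(BondParams())
        if min(abs(r - bond.r1), abs(r - bond.r2)) < 1e-3:
            return  # gradient check invalid across the kink/cutoff
        h = 1e-6
        Up, _ = bond_energy_force(r + h, bond)
        Um, _ = bond_energy_force(r - h, bond)
        _, F = bond_energy_force(r, bond)
        assert F == pytest.approx(-(Up - Um) / (2 * h), rel=1e-5, abs=1e-7)


class TestAngle:
    def test_zero_at_equilibrium(self):
        p = AngleParams()
        th0 = np.pi
        assert angle_energy(th0, p, th0) == 0.0
        U, F = angle_forces([0, 0, 0], [14, 0, 0], [28, 0, 0], p.k_theta, th0)
        assert U == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(F, 0.0, atol=1e-9)

    def test_ten_degree_deflection_energy(self):
        p = AngleParams()
        dth = np.deg2rad(10.0)
        U = angle_energy(np.pi - dth, p, np.pi)
        assert U == pytest.approx(0.5 * 14.98 * dth ** 2, rel=1e-12)
        assert U == pytest.approx(0.228, abs=5e-4)

    @pytest.mark.parametrize("trial", range(5))
    def test_forces_match_finite_differences(self, trial):
        rng = np.random.default_rng(trial)
        pts = rng.normal(size=(3, 3)) * 4 + np.array(
            [[0, 0, 0], [8, 0, 0], [16, 0, 0]], float
        )
        th0 = np.deg2rad(172.0)
        _, F = angle_forces(pts[0], pts[1], pts[2], 14.98, th0)
        h = 1e-6
        for a in range(3):
            for c in range(3):
                p = pts.copy(); p[a, c] += h
                Up, _ = angle_forces(p[0], p[1], p[2], 14.98, th0)
                p = pts.copy(); p[a, c] -= h
                Um, _ = angle_forces(p[0], p[1], p[2], 14.98, th0)
                fd = -(Up - Um) / (2 * h)
                assert F[a, c] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_net_force_and_torque_vanish(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(3, 3)) * 5 + np.array(
            [[0, 0, 0], [9, 0, 0], [18, 0, 0]], float
        )
        _, F = angle_forces(pts[0], pts[1], pts[2], 14.98, np.deg2rad(170))
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-10)
        torque = np.cross(pts, F).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-9)

    def test_collinear_limit_finite(self):
        U, F = angle_forces([0, 0, 0], [14, 0, 0], [28, 0, 0], 14.98,
                            np.deg2rad(170))
        assert np.isfinite(F).all()


class TestPair:
    @pytest.mark.parametrize("pair_name,eps,sig", [
        ("pair_cc", 6.87, 14.72),
        ("pair_mm", 193.7, 10.28),
        ("pair_cm", 137.1, 9.88),
    ])
    def test_minimum_depth_and_location(self, ff, pair_name, eps, sig):
        p = getattr(ff, pair_name)
        rmin = 2.0 ** (1.0 / 6.0) * sig
        U, F = pair_energy_force(rmin, p)
        assert U == pytest.approx(-eps, rel=1e-12)
        assert F == pytest.approx(0.0, abs=1e-10)

    def test_zero_crossing_at_sigma(self, ff):
        U, _ = pair_energy_force(14.72, ff.pair_cc)
        assert U == pytest.approx(0.0, abs=1e-9)

    def test_zero_beyond_cutoff(self, ff):
        assert pair_energy_force(21.0, ff.pair_cc) == (0.0, 0.0)
        assert pair_energy_force(25.0, ff.pair_cc) == (0.0, 0.0)

    def test_nonpositive_distance_errors(self, ff):
        with pytest.raises(ValueError):
            pair_energy_force(0.0, ff.pair_cc)

    def test_invalid_params_error(self):
        with pytest.raises(ValueError):
            PairParams(epsilon=1.0, sigma=22.0, r_cutoff=21.0)


def random_cloud(n, seed, with_minerals=True):
    """A random mixed bead cloud (minimum separation ~7 Å, so forces stay
    physical) with a couple of short chains."""
    rng = np.random.default_rng(seed)
    pos = np.empty((n, 3))
    species = np.zeros(n, np.uint8)
    mol = np.full(n, -1, dtype=np.int64)
    # two 5-bead chains at realistic spacing, then a loose random cloud
    for c, start in enumerate((0, 5)):
        mol[start:start + 5] = c
        base = np.array([15.0 + 25.0 * c, 20.0, 5.0])
        for k in range(5):
            pos[start + k] = base + np.array([0, 0, 14.5 * k]) \
                + rng.normal(scale=0.5, size=3)
    count = 10
    while count < n:  # rejection sampling keeps separations physical
        cand = rng.uniform(0, 60, size=3)
        if (np.linalg.norm(pos[:count] - cand, axis=1) > 9.0).all():
            pos[count] = cand
            count += 1
    if with_minerals:
        species[n // 2:] = 1
        mol[n // 2:] = -1
    bonds = []
    angles = []
    for start in (0, 5):
        ix = np.arange(start, start + 5)
        bonds += [[ix[k], ix[k + 1]] for k in range(4)]
        angles += [[ix[k], ix[k + 1], ix[k + 2]] for k in range(3)]
    return BeadTopology(
        positions=pos, species=species, molecule_id=mol,
        bonds=np.array(bonds, np.int64), angles=np.array(angles, np.int64),
        box=Box(np.full(3, -10.0), np.full(3, 70.0), np.array([False] * 3)),
    )


def reference_forces(topology, ff, theta0):
    """Independent plain-python/numpy evaluation of all force terms."""
    pos = topology.positions
    n = len(pos)
    F = np.zeros((n, 3))
    U = 0.0
    b = derive_bond_branch(ff.bond)
    for (i, j) in topology.bonds:
        d = pos[j] - pos[i]
        r = np.linalg.norm(d)
        Ub, Fb = bond_energy_force(r, b)
        U += Ub
        F[j] += Fb * d / r
        F[i] -= Fb * d / r
    for a, (i, j, k) in enumerate(topology.angles):
        Ua, Fa = angle_forces(pos[i], pos[j], pos[k], ff.angle.k_theta,
                              theta0[a])
        U += Ua
        F[i] += Fa[0]; F[j] += Fa[1]; F[k] += Fa[2]
    tables = {(0, 0): ff.pair_cc, (1, 1): ff.pair_mm,
              (0, 1): ff.pair_cm, (1, 0): ff.pair_cm}
    mol = topology.molecule_id
    for i in range(n):
        for j in range(i + 1, n):
            if mol[i] == mol[j] and mol[i] >= 0 and abs(i - j) <= 2:
                continue
            d = pos[j] - pos[i]
            r = np.linalg.norm(d)
            p = tables[(int(topology.species[i]), int(topology.species[j]))]
            if r >= p.r_cutoff:
                continue
            Up, Fp = pair_energy_force(r, p)
            U += Up
            F[j] += Fp * d / r
            F[i] -= Fp * d / r
    return U, F


class TestSystemAssembly:
    def test_bonded_dimer_at_equilibrium(self, dimer, ff):
        sf = system_energy_forces(dimer.positions, dimer, ff)
        assert sf.U_total == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sf.forces, 0.0, atol=1e-12)

    def test_newtons_third_law(self, ff):
        topo = random_cloud(50, seed=3)
        sf = system_energy_forces(topo.positions, topo, ff)
        np.testing.assert_allclose(sf.forces.sum(axis=0), 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_reference(self, ff, seed):
        """Kernel forces equal a brute-force python reference."""
        topo = random_cloud(50, seed=seed)
        theta0 = assign_theta0(topo, ff)
        sf = system_energy_forces(topo.positions, topo, ff)
        U_ref, F_ref = reference_forces(topo, ff, theta0)
        assert sf.U_total == pytest.approx(U_ref, rel=1e-10)
        np.testing.assert_allclose(sf.forces, F_ref, rtol=1e-9, atol=1e-9)

    def test_mixed_pair_symmetry(self, ff):
        """Collagen-mineral LJ applied identically in both orders."""
        eps, sig, rc = ff.pair_tables()
        np.testing.assert_array_equal(eps, eps.T)
        np.testing.assert_array_equal(sig, sig.T)
        np.testing.assert_array_equal(rc, rc.T)

    def test_size_mismatch_errors(self, dimer, ff):
        with pytest.raises(ValueError):
            system_energy_forces(np.zeros((3, 3)), dimer, ff)

    def test_theta0_clamped_to_calibrated_range(self, ff):
        topo = random_cloud(20, seed=5)
        th0 = assign_theta0(topo, ff)
        assert (th0 >= np.deg2rad(164.0) - 1e-12).all()
        assert (th0 <= np.pi + 1e-12).all()
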