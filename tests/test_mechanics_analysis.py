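"""Observable extraction: virial stress against strain-derivative
oracles, phase decomposition closure, curve metrics, sliding, fracture
bookkeeping, classification and residual strain."""

import numpy as np
import pytest

from mcfsim.fibril_geometry import (
    BeadTopology,
    Box,
    FibrilSpec,
    assign_protofibril_ids,
    build_idealized_fibril,
)
from mcfsim.forcefield import system_energy_forces
from mcfsim.md_engine import integrate, make_state
from mcfsim.mechanics_analysis import (
    axial_position_profile,
    classify_protofibrils,
    curve_metrics,
    per_bead_virial,
    phase_stress,
    residual_strain,
    sliding_and_com,
)
from tests.conftest import make_dimer
from tests.test_forcefield import random_cloud


class TestVirial:
    def test_isolated_bead_zero_tensor(self, ff):
        topo = make_dimer(r=50.0)  # beyond every cutoff
        topo.bonds = np.empty((0, 2), np.int64)
        topo.molecule_id = np.array([0, 1], np.int64)
        rec = per_bead_virial(topo.positions, topo, ff)
        np.testing.assert_allclose(rec.per_bead, 0.0, atol=1e-14)

    def test_stretched_dimer_axial_virial(self, ff):
        """sigma_zz * V = r * F = 15 * 17.13 for a bond at 15 Å along z
        (tensile positive)."""
        topo = make_dimer(r=15.0)
        rec = per_bead_virial(topo.positions, topo, ff)
        W_zz = rec.per_bead[:, 2].sum()
        assert W_zz == pytest.approx(15.0 * 17.13, rel=1e-12)
        assert W_zz > 0  # tension is positive

    @pytest.mark.parametrize("seed", [0, 1])
    def test_global_stress_matches_strain_derivative(self, ff, seed):
        """Sum of per-bead virials equals the numerical d(U)/d(strain)."""
        topo = random_cloud(60, seed=seed)
        sf = system_energy_forces(topo.positions, topo, ff)
        W_zz = sf.per_bead_stress[:, 2].sum()
        h = 1e-6

        def U_at(scale):
            p = topo.positions.copy()
            p[:, 2] *= scale
            return system_energy_forces(p, topo, ff).U_total

        dUde = (U_at(1 + h) - U_at(1 - h)) / (2 * h)
        assert W_zz == pytest.approx(dUde, rel=0.01)

    def test_chain_virial_oracle(self, ff):
        """20-bead chain under stretch: virial vs strain derivative."""
        n = 20
        pos = np.zeros((n, 3))
        pos[:, 2] = np.arange(n) * 14.9  # slightly stretched bonds
        ix = np.arange(n)
        topo = BeadTopology(
            positions=pos, species=np.zeros(n, np.uint8),
            molecule_id=np.zeros(n, np.int64),
            bonds=np.column_stack([ix[:-1], ix[1:]]).astype(np.int64),
            angles=np.column_stack([ix[:-2], ix[1:-1], ix[2:]]).astype(np.int64),
            box=Box(np.full(3, -500.0), np.full(3, 500.0),
                    np.array([False] * 3)),
        )
        sf = system_energy_forces(pos, topo, ff)
        h = 1e-6
        Up = system_energy_forces(pos * [1, 1, 1 + h], topo, ff).U_total
        Um = system_energy_forces(pos * [1, 1, 1 - h], topo, ff).U_total
        assert sf.per_bead_stress[:, 2].sum() == pytest.approx(
            (Up - Um) / (2 * h), rel=0.01
        )


class TestPhaseStress:
    def test_all_collagen_equals_global(self, ff):
        topo = random_cloud(40, seed=2, with_minerals=False)
        rec = per_bead_virial(topo.positions, topo, ff)
        ph = phase_stress(rec, topo)
        np.testing.assert_allclose(ph["collagen"]["tensor"],
                                   ph["global"]["tensor"], atol=1e-12)
        assert ph["mineral"]["fraction"] == 0.0

    def test_weighted_recombination_identity(self, ff):
        topo = random_cloud(60, seed=3)
        rec = per_bead_virial(topo.positions, topo, ff)
        ph = phase_stress(rec, topo)
        combined = (
            ph["collagen"]["fraction"] * ph["collagen"]["tensor"]
            + ph["mineral"]["fraction"] * ph["mineral"]["tensor"]
        )
        np.testing.assert_allclose(combined, ph["global"]["tensor"],
                                   rtol=1e-10, atol=1e-10)


class TestCurveMetrics:
    def test_linear_curve_secant(self):
        e = np.linspace(0, 0.1, 101)
        E = 5000.0
        c = curve_metrics(e, E * e, smooth_window=1)
        assert c.secant_modulus == pytest.approx(E, rel=1e-9)
        assert c.uts == pytest.approx(E * 0.1)
        assert c.fracture_strain is None  # no post-peak drop
        assert c.toughness is None

    def test_triangle_curve_metrics(self):
        """Rise to (0.2, 100), fall to (0.4, 0): UTS 100, fracture at the
        10%-of-UTS drop (0.38), toughness = trapezoid up to 0.38."""
        e = np.linspace(0, 0.4, 401)
        s = np.where(e <= 0.2, 500.0 * e, 100.0 - 500.0 * (e - 0.2))
        c = curve_metrics(e, s, smooth_window=1)
        assert c.uts == pytest.approx(100.0)
        assert c.fracture_strain == pytest.approx(0.38, abs=2e-3)
        # independent trapezoid oracle over the kept range
        keep = e <= c.fracture_strain + 1e-12
        assert c.toughness == pytest.approx(np.trapezoid(s[keep], e[keep]),
                                            rel=1e-12)
        assert c.toughness == pytest.approx(19.9, abs=0.05)
        assert c.residual_stress == 0.0

    def test_all_zero_curve(self):
        e = np.linspace(0, 0.1, 50)
        c = curve_metrics(e, np.zeros_like(e), smooth_window=1)
        assert c.secant_modulus == 0.0
        assert c.uts == 0.0
        assert c.toughness is None

    def test_input_validation(self):
        with pytest.raises(ValueError):
            curve_metrics(np.array([0.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            curve_metrics(np.array([0.0, 0.1, 0.05]),
                          np.array([0.0, 1.0, 2.0]))


class TestSliding:
    def setup_method(self):
        self.com0 = np.array([100.0, 500.0, 900.0])
        self.strain = np.array([0.0, 0.1, 0.2])
        self.z_fixed = 0.0

    def test_affine_deformation_gives_zero(self):
        com = self.com0[None, :] * (1 + self.strain[:, None])
        out = sliding_and_com(com, self.strain, self.z_fixed)
        np.testing.assert_allclose(out["sliding"], 0.0, atol=1e-12)

    def test_translation_of_whole_trajectory_invariant(self):
        com = self.com0[None, :] * (1 + self.strain[:, None])
        out0 = sliding_and_com(com, self.strain, self.z_fixed)
        out1 = sliding_and_com(com + 37.0, self.strain, self.z_fixed + 37.0)
        np.testing.assert_allclose(out0["sliding"], out1["sliding"],
                                   atol=1e-12)

    def test_constructed_excess_displacement(self):
        com = self.com0[None, :] * (1 + self.strain[:, None])
        com[-1, 1] += 50.0  # one protofibril displaced beyond affine
        out = sliding_and_com(com, self.strain, self.z_fixed)
        np.testing.assert_allclose(out["sliding"][-1],
                                   [0.0, 50.0, 0.0], atol=1e-12)

    def test_scaled_com_in_unit_interval(self):
        com = self.com0[None, :] * (1 + self.strain[:, None])
        L = np.array([1000.0, 1100.0, 1200.0])
        out = sliding_and_com(com, self.strain, self.z_fixed,
                              current_length=L, z_min=0.0)
        assert ((out["scaled_com"] >= 0) & (out["scaled_com"] <= 1)).all()


class TestFracture:
    def test_no_breaks_without_overstretch(self, small_fibril, ff, masses):
        state = make_state(small_fibril, masses)
        traj = integrate(state, small_fibril, ff, n_steps=50, dt=10.0,
                         ensemble="nve", sample_every=10)
        assert traj.n_broken_bonds[-1] == 0
        assert traj.n_broken_molecules[-1] == 0

    def test_overstretched_bond_breaks_one_protofibril(self, ff, masses):
        topo = make_dimer(r=21.5)  # beyond r2 = 21 Å
        state = make_state(topo, masses)
        traj = integrate(state, topo, ff, n_steps=5, dt=10.0,
                         ensemble="nve", sample_every=1,
                         permanent_breaks=True)
        assert traj.n_broken_bonds[-1] == 1
        assert traj.n_broken_molecules[-1] == 1
        assert traj.mol_broken.sum() == 1

    def test_break_counts_monotone(self, ff, masses):
        """A pulled chain accumulates breaks monotonically."""
        n = 10
        pos = np.zeros((n, 3))
        pos[:, 2] = np.arange(n) * 14.0
        ix = np.arange(n)
        topo = BeadTopology(
            positions=pos, species=np.zeros(n, np.uint8),
            molecule_id=np.zeros(n, np.int64),
            bonds=np.column_stack([ix[:-1], ix[1:]]).astype(np.int64),
            angles=np.empty((0, 3), np.int64),
            box=Box(np.full(3, -1e4), np.full(3, 1e4), np.array([False] * 3)),
        )
        state = make_state(topo, masses)
        traj = integrate(
            state, topo, ff, n_steps=4000, dt=10.0, ensemble="nve",
            sample_every=50, fixed=np.array([0]), pulled=np.array([n - 1]),
            pull_velocity=5e-3, permanent_breaks=True,
        )
        assert traj.n_broken_bonds[-1] >= 1
        assert (np.diff(traj.n_broken_bonds) >= 0).all()
        assert (np.diff(traj.n_broken_molecules) >= 0).all()


class TestClassification:
    def test_no_minerals_all_false(self, mini_fibril):
        flags = classify_protofibrils(mini_fibril)
        assert flags and not any(flags.values())

    def test_single_nearby_mineral_flags_one(self, mini_fibril):
        topo = mini_fibril.copy()
        mols = topo.molecule_indices()
        target = topo.positions[mols[0][0]] + np.array([5.0, 0.0, 0.0])
        topo.positions = np.vstack([topo.positions, target])
        topo.species = np.concatenate([topo.species, [1]]).astype(np.uint8)
        topo.molecule_id = np.concatenate([topo.molecule_id, [-1]])
        flags = classify_protofibrils(topo, cutoff=20.0)
        # molecules within 20 Å of that mineral (its own site and the
        # immediate lattice neighbours at 15.3 Å may both qualify)
        assert flags[int(topo.molecule_id[mols[0][0]])] is True

    def test_smaller_mineral_radius_flags_fewer_protofibrils(self, masses):
        """Mineral arranged at smaller radius mineralizes fewer
        protofibrils (the arrangement-classification mechanism)."""
        from mcfsim.mineralizer import (MineralPattern, fill_fcc_region,
                                        tune_cutoff)
        spec = FibrilSpec(diameter_nm=20.0)
        base = build_idealized_fibril(spec)
        counts = {}
        for r_nm in (3.0, 10.0):
            pat = MineralPattern(l_mineral=1.0, r_mineral_nm=r_nm,
                                 target_w=0.15)
            carved = tune_cutoff(fill_fcc_region(base, pat), pat,
                                 masses).topology
            flags = classify_protofibrils(carved)
            counts[r_nm] = sum(flags.values())
        assert counts[3.0] < counts[10.0]


class TestResidualStrain:
    def test_as_built_fibril_zero(self, mini_fibril):
        out = residual_strain(mini_fibril)
        assert out["fibril"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_stretch_value(self, ff):
        topo = make_dimer(r=14.14)
        out = residual_strain(topo)
        assert out["fibril"] == pytest.approx(0.01, abs=1e-9)
        assert out["per_protofibril"][0] == pytest.approx(0.01, abs=1e-9)


class TestAxialProfile:
    def test_schema_and_ordering(self, mini_fibril, ff):
        index = assign_protofibril_ids(mini_fibril)
        rec = per_bead_virial(mini_fibril.positions, mini_fibril, ff)
        szz = rec.per_bead[:, 2]
        flags = classify_protofibrils(mini_fibril)
        df = axial_position_profile(mini_fibril.positions, mini_fibril,
                                    index, per_bead_szz=szz,
                                    mineralized=flags)
        assert list(df.columns) == ["protofibril_id", "z_A", "stress_zz",
                                    "mineralized"]
        assert len(df) == int(mini_fibril.collagen_mask.sum())
        assert (np.diff(df["protofibril_id"]) >= 0).all()
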