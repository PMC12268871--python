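"""Pair potentials, total energy, forces and parameter gradients."""

import numpy as np
import pytest

from regcg.cgmodel import (
    NonbondedParams,
    PairEntry,
    compile_system,
    dU_dtheta,
    forces,
    total_energy,
    u_att,
    u_elec,
    u_rep,
)
from regcg.units import KE

from conftest import place, two_bead_system


class TestPairPotentials:
    def test_elec_zero_charge(self):
        _, params = two_bead_system()
        assert u_elec(1.0, 0.0, 1.0, params) == 0.0

    def test_elec_screened_coulomb_value(self):
        # hand evaluation: (138.935/17.5) * exp(-1.274) at R = 1 nm, unit charges
        _, params = two_bead_system()
        expected = KE / 17.5 * np.exp(-1.274)
        assert u_elec(1.0, 1.0, 1.0, params) == pytest.approx(expected, rel=1e-12)

    def test_elec_vanishes_beyond_cutoff(self):
        _, params = two_bead_system()
        assert u_elec(2.51, 1.0, 1.0, params) == 0.0
        assert u_elec(2.49, 1.0, 1.0, params) != 0.0

    def test_elec_rejects_nonpositive_distance(self):
        _, params = two_bead_system()
        with pytest.raises(ValueError):
            u_elec(0.0, 1.0, 1.0, params)

    def test_rep_boundary_continuity(self):
        # cosine bracket vanishes at R = R_rep: only B/R^4 survives
        B = 0.0025104
        assert u_rep(1.0, 41.84, 1.0, B) == pytest.approx(B, rel=1e-12)
        eps = 1e-9
        assert u_rep(1.0 - eps, 41.84, 1.0, B) == pytest.approx(B, rel=1e-5)

    def test_rep_half_range_value(self):
        # A(1 + cos(pi/2)) + B/(1/2)^4 = A + 16 B
        A, B = 41.84, 0.0025104
        assert u_rep(0.5, A, 1.0, B) == pytest.approx(A + 16 * B, rel=1e-12)

    def test_rep_diverges_at_contact(self):
        assert u_rep(1e-4, 41.84, 1.0, 0.0025104) > 1e9

    def test_att_peak_and_tail(self):
        C, R_att, sigma = -5.0, 1.0, 0.2
        peak = u_att(R_att, C, R_att, sigma)
        assert peak == pytest.approx(C / (sigma * np.sqrt(2 * np.pi)), rel=1e-12)
        assert abs(u_att(R_att + 6 * sigma, C, R_att, sigma) / peak) < 1e-7

    def test_att_linear_in_amplitude(self):
        assert u_att(0.83, -7.0, 1.0, 0.2) == pytest.approx(
            3.5 * u_att(0.83, -2.0, 1.0, 0.2), rel=1e-12
        )

    def test_att_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            u_att(1.0, -5.0, 1.0, 0.0)


class TestTotalEnergy:
    def test_beyond_cutoff_no_nonbonded(self):
        topo, params = two_bead_system()
        eb = total_energy(place(3.0), topo, params)
        assert eb.U_elec == eb.U_rep == eb.U_att == 0.0
        assert eb.V_bind == 0.0

    def test_single_monomer_only_bonded(self):
        topo, params = two_bead_system(spring=(500.0, 0.5), same_monomer=True)
        eb = total_energy(place(0.6), topo, params)
        assert eb.U_bond == pytest.approx(0.5 * 500 * 0.1**2)
        assert eb.U_elec == eb.U_rep == eb.U_att == 0.0
        assert eb.V_bind == 0.0

    def test_matches_brute_force_pair_sum(self, dimer):
        # independent hand enumeration over all inter-monomer pairs
        topo, params = dimer.topology, dimer.params
        coords = dimer.ensemble.coords[17]
        eb = total_energy(coords, topo, params)
        u_nb = 0.0
        for i in range(topo.n_beads):
            for j in range(i + 1, topo.n_beads):
                if topo.monomer_id[i] == topo.monomer_id[j]:
                    continue
                r = float(np.linalg.norm(coords[i] - coords[j]))
                if r > params.cutoff:
                    continue
                e = params.entry(topo.bead_type[i], topo.bead_type[j])
                u_nb += u_elec(r, topo.charge[i], topo.charge[j], params)
                u_nb += u_rep(r, e.A, e.R_rep, params.B)
                u_nb += u_att(r, e.C, e.R_att, params.sigma)
        assert eb.U_elec + eb.U_rep + eb.U_att == pytest.approx(u_nb, rel=1e-10)
        assert eb.V_bind == pytest.approx(u_nb, rel=1e-10)

    def test_additivity_bitwise(self, dimer):
        eb = total_energy(dimer.ensemble.coords[3], dimer.topology, dimer.params)
        assert eb.U_total == eb.U_bond + eb.U_elec + eb.U_rep + eb.U_att

    def test_vbind_rigid_motion_invariant(self, dimer):
        from scipy.spatial.transform import Rotation

        coords = dimer.ensemble.coords[5]
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.2]).as_matrix()
        moved = coords @ rot.T + np.array([1.5, -2.0, 0.7])
        eb0 = total_energy(coords, dimer.topology, dimer.params)
        eb1 = total_energy(moved, dimer.topology, dimer.params)
        assert eb1.V_bind == pytest.approx(eb0.V_bind, rel=1e-10)
        assert eb1.U_total == pytest.approx(eb0.U_total, rel=1e-10)

    def test_designated_pair_restriction(self):
        # three monomers: V_bind of pair (0,1) excludes monomer 2
        from regcg.fixtures import FixtureSpec, make_multimer_reference

        fx = make_multimer_reference(FixtureSpec(kind="multimer", n_frames=5, seed=3))
        coords = fx.ensemble.coords[0]
        all_pairs = total_energy(coords, fx.topology, fx.params)
        pair01 = total_energy(coords, fx.topology, fx.params, vbind_pair=(0, 1))
        assert pair01.V_bind != pytest.approx(all_pairs.V_bind)
        assert abs(pair01.V_bind) < abs(all_pairs.V_bind)

    def test_shape_mismatch_rejected(self, dimer):
        with pytest.raises(ValueError):
            total_energy(np.zeros((3, 3)), dimer.topology, dimer.params)


class TestForces:
    def test_matches_finite_difference(self, dimer):
        topo, params = dimer.topology, dimer.params
        coords = dimer.ensemble.coords[11]
        f = forces(coords, topo, params)
        h = 1e-6
        for bead in (0, 4, 7):
            for ax in range(3):
                cp = coords.copy()
                cp[bead, ax] += h
                up = total_energy(cp, topo, params).U_total
                cp[bead, ax] -= 2 * h
                um = total_energy(cp, topo, params).U_total
                assert f[bead, ax] == pytest.approx(-(up - um) / (2 * h), rel=1e-5, abs=1e-4)

    def test_newton_third_law(self):
        topo, params = two_bead_system()
        f = forces(place(0.9), topo, params)
        np.testing.assert_allclose(f[0] + f[1], 0.0, atol=1e-12)

    def test_spring_equilibrium_zero_force(self):
        topo, params = two_bead_system(spring=(500.0, 0.8), same_monomer=True)
        f = forces(place(0.8), topo, params)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)

    def test_overlap_rejected(self):
        topo, params = two_bead_system()
        with pytest.raises(ValueError):
            forces(np.zeros((2, 3)), topo, params)

    def test_kernel_agrees_with_reference_implementation(self, dimer):
        # the compiled fast path must reproduce the numpy energies/forces
        from regcg import _kernels

        topo, params = dimer.topology, dimer.params
        sys = compile_system(topo, params)
        coords = dimer.ensemble.coords[29]
        f_np = forces(coords, topo, params, system=sys)
        eb = total_energy(coords, topo, params, system=sys)
        f_k = np.zeros_like(coords)
        g_k = np.zeros(max(sys.n_theta, 1))
        ub, ue, ur, ua, vb = _kernels.pair_forces_energy(
            coords, sys.pi, sys.pj, sys.qq, sys.A, sys.R_rep, sys.R_att, sys.b_on,
            sys.slot, sys.slot_c, sys.slot_theta, sys.vbind_mask,
            sys.sigma, sys.B, sys.kappa_D, sys.cutoff,
            sys.spring_i, sys.spring_j, sys.spring_k, sys.spring_r0,
            f_k, g_k,
        )
        np.testing.assert_allclose(f_k, f_np, rtol=1e-12, atol=1e-9)
        assert (ub, ue, ur, ua) == pytest.approx(
            (eb.U_bond, eb.U_elec, eb.U_rep, eb.U_att), rel=1e-12
        )
        assert vb == pytest.approx(eb.V_bind, rel=1e-12)
        np.testing.assert_allclose(
            g_k[: sys.n_theta], dU_dtheta(coords, topo, params, system=sys), rtol=1e-12
        )


class TestParameterGradient:
    def test_single_pair_at_well_center(self):
        topo, params = two_bead_system()
        g = dU_dtheta(place(1.0), topo, params)
        assert g == pytest.approx([1.0 / (0.2 * np.sqrt(2 * np.pi))], rel=1e-12)

    def test_finite_difference_in_C(self, dimer):
        coords = dimer.ensemble.coords[2]
        params = dimer.params.copy()
        g = dU_dtheta(coords, dimer.topology, params)
        theta = params.get_theta()
        h = 1e-5
        for k in range(theta.size):
            tp = theta.copy()
            tp[k] += h
            params.set_theta(tp)
            up = total_energy(coords, dimer.topology, params).U_total
            tp[k] -= 2 * h
            params.set_theta(tp)
            um = total_energy(coords, dimer.topology, params).U_total
            params.set_theta(theta)
            assert g[k] == pytest.approx((up - um) / (2 * h), rel=1e-7)

    def test_out_of_range_parameter_zero(self):
        topo, params = two_bead_system()
        g = dU_dtheta(place(3.0), topo, params)  # beyond cutoff
        np.testing.assert_array_equal(g, [0.0])


class TestValidation:
    def test_inter_monomer_spring_rejected(self):
        import regcg.cgmodel as cm

        with pytest.raises(ValueError, match="different monomers"):
            cm.CGTopology(
                monomer_id=np.array([0, 1]),
                bead_type=["X", "Y"],
                charge=np.zeros(2),
                mass=np.ones(2),
                spring_i=np.array([0]),
                spring_j=np.array([1]),
                spring_k=np.array([100.0]),
                spring_r0=np.array([0.5]),
            )

    def test_negative_A_rejected(self):
        with pytest.raises(ValueError):
            NonbondedParams(pairs={("X", "X"): PairEntry(A=-1.0, R_rep=0.5)})

    def test_theta_roundtrip(self, dimer):
        params = dimer.params.copy()
        theta = params.get_theta()
        params.set_theta(theta * 2)
        np.testing.assert_allclose(params.get_theta(), theta * 2)
        with pytest.raises(ValueError):
            params.set_theta(theta[:-1])
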