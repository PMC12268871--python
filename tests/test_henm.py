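"""Heteroelastic network fitting."""

import numpy as np
import pytest

from regcg.cgmodel import CGTopology, NonbondedParams
from regcg.ensemble import Ensemble
from regcg.henm import (
    HENMState,
    build_spring_network,
    default_gamma,
    henm_fit,
    henm_update,
    spring_msd,
)
from regcg.simulate import SimSettings, run
from regcg.units import KB

from conftest import place


def _single_spring_topology(k, r0=0.5):
    return CGTopology(
        monomer_id=np.zeros(2, dtype=int),
        bead_type=["A", "A"],
        charge=np.zeros(2),
        mass=np.full(2, 300.0),
        spring_i=np.array([0]),
        spring_j=np.array([1]),
        spring_k=np.array([float(k)]),
        spring_r0=np.array([r0]),
    )


class TestSpringMSD:
    def test_static_frames(self):
        ens = Ensemble(coords=np.repeat(place(0.7)[None], 4, axis=0))
        assert spring_msd(ens, [0], [1])[0] == pytest.approx(0.49)

    def test_alternating_distances(self):
        coords = np.stack([place(1.0), place(2.0)])
        ens = Ensemble(coords=coords)
        assert spring_msd(ens, [0], [1])[0] == pytest.approx(2.5)

    def test_gaussian_displacement_moment(self):
        # 1D displacement with mean d and variance s^2: <R^2> = d^2 + s^2
        rng = np.random.default_rng(1)
        n = 10_000
        d, s = 0.8, 0.1
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = d + rng.normal(scale=s, size=n)
        got = spring_msd(Ensemble(coords=coords), [0], [1])[0]
        se = np.std(coords[:, 1, 0] ** 2) / np.sqrt(n)
        assert abs(got - (d**2 + s**2)) < 3 * se


class TestUpdate:
    def _state(self, k=500.0, msd_aa=0.3):
        karr = np.array([k])
        msd = np.array([msd_aa])
        return HENMState(
            spring_i=np.array([0]), spring_j=np.array([1]),
            k=karr, r0=np.array([0.5]), msd_aa=msd,
            gamma=default_gamma(karr, msd),
        )

    def test_matched_fluctuations_keep_k(self):
        st = self._state()
        new = henm_update(st, np.array([0.3]))
        assert new.k[0] == pytest.approx(st.k[0])

    def test_excess_fluctuation_stiffens(self):
        st = self._state()
        new = henm_update(st, np.array([0.36]))
        assert new.k[0] > st.k[0]

    def test_deficient_fluctuation_softens(self):
        st = self._state()
        new = henm_update(st, np.array([0.24]))
        assert new.k[0] < st.k[0]

    def test_nonpositive_compliance_clamps_to_kmax(self):
        st = self._state(k=9.9e4)
        new = henm_update(st, np.array([30.0]))  # drives 1/k <= 0
        assert new.k[0] == st.k_max
        assert new.clamped[0]

    def test_single_spring_fixed_point_recovery(self):
        # iterate measure/update against a simulated reference; 5% on k.
        # short rest length keeps the fluctuation part of <R^2> (the part k
        # controls) from being swamped by the r0^2 offset
        k_true, r0 = 400.0, 0.2
        topo_true = _single_spring_topology(k_true, r0)
        params = NonbondedParams(pairs={})
        ref = run(topo_true, params, place(r0),
                  SimSettings(temperature=310.0, n_steps=1_000_000, stride=50, seed=2))
        msd_aa = spring_msd(ref, [0], [1])

        k = np.array([900.0])  # start well off
        st = HENMState(
            spring_i=np.array([0]), spring_j=np.array([1]),
            k=k, r0=np.array([r0]), msd_aa=msd_aa,
            gamma=default_gamma(k, msd_aa),
        )
        ks = []
        for it in range(40):
            topo = _single_spring_topology(st.k[0], r0)
            ens = run(topo, params, place(r0),
                      SimSettings(temperature=310.0, n_steps=200_000, stride=50,
                                  seed=100 + it))
            st = henm_update(st, spring_msd(ens, [0], [1]))
            ks.append(st.k[0])
        k_fit = 1.0 / np.mean(1.0 / np.array(ks[-25:]))
        assert abs(k_fit - k_true) / k_true < 0.05


class TestMonotoneResponse:
    def test_msd_decreases_with_stiffness(self):
        # the sampled map k -> <R^2> must be monotone for the update sign
        params = NonbondedParams(pairs={})
        msds = []
        for k in [100.0, 300.0, 900.0, 2700.0]:
            topo = _single_spring_topology(k)
            ens = run(topo, params, place(0.5),
                      SimSettings(temperature=310.0, n_steps=100_000, stride=50, seed=7))
            msds.append(spring_msd(ens, [0], [1])[0])
        assert all(a > b for a, b in zip(msds, msds[1:]))


class TestFit:
    def test_network_recovery_from_fine_chain(self):
        from regcg.fixtures import FixtureSpec, make_fine_chain

        chain = make_fine_chain(FixtureSpec(kind="chain", n_frames=4000, seed=5))
        topo0 = chain.bead_topology.with_springs(
            chain.bead_topology.spring_i,
            chain.bead_topology.spring_j,
            np.full(chain.true_k.size, 500.0),
            chain.bead_topology.spring_r0,
        )
        result = henm_fit(
            topo0, chain.bead_ensemble,
            SimSettings(temperature=310.0, n_steps=200_000, stride=50, seed=6),
            n_iterations=25,
        )
        rel = np.abs(result.topology.spring_k - chain.true_k) / chain.true_k
        assert np.median(rel) < 0.10

    def test_two_stiffness_classes_ordering(self):
        # soft and stiff springs must come out in the right order everywhere
        native = np.stack([np.zeros(4), np.arange(4) * 0.5, np.zeros(4)], axis=1)
        k_true = np.array([200.0, 1200.0, 200.0])
        topo_true = CGTopology(
            monomer_id=np.zeros(4, dtype=int),
            bead_type=list("ABCD"),
            charge=np.zeros(4), mass=np.full(4, 300.0),
            spring_i=np.array([0, 1, 2]), spring_j=np.array([1, 2, 3]),
            spring_k=k_true, spring_r0=np.full(3, 0.5),
        )
        params = NonbondedParams(pairs={})
        ref = run(topo_true, params, native,
                  SimSettings(temperature=310.0, n_steps=300_000, stride=50, seed=8))
        topo0 = topo_true.with_springs(
            topo_true.spring_i, topo_true.spring_j, np.full(3, 500.0), topo_true.spring_r0
        )
        result = henm_fit(topo0, ref,
                          SimSettings(temperature=310.0, n_steps=200_000, stride=50, seed=9),
                          n_iterations=25)
        k = result.topology.spring_k
        assert k[1] > k[0] and k[1] > k[2]

    def test_frozen_reference_clamps_stiff(self):
        # a fluctuation-free reference drives every spring to k_max
        ref = Ensemble(coords=np.repeat(place(0.5)[None], 3, axis=0))
        topo = _single_spring_topology(500.0)
        result = henm_fit(
            topo, ref, SimSettings(temperature=310.0, n_steps=20_000, stride=50, seed=1),
            n_iterations=25, gamma_scale=25.0, average_window=1,
        )
        assert result.topology.spring_k[0] == pytest.approx(1.0e5)

    def test_spring_network_construction(self, dimer):
        bare = CGTopology(
            monomer_id=dimer.topology.monomer_id,
            bead_type=dimer.topology.bead_type,
            charge=dimer.topology.charge,
            mass=dimer.topology.mass,
        )
        topo = build_spring_network(bare, dimer.ensemble, r_enm=1.4)
        assert topo.spring_i.size > 0
        # springs only within monomers, rest lengths at the reference means
        assert np.all(topo.monomer_id[topo.spring_i] == topo.monomer_id[topo.spring_j])
        msd = spring_msd(dimer.ensemble, topo.spring_i, topo.spring_j)
        np.testing.assert_array_less(topo.spring_r0**2, msd + 1e-9)
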