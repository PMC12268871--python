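"""Essential-dynamics partitioning and mapping application."""

import itertools

import numpy as np
import pytest

from regcg.ensemble import Ensemble
from regcg.mapping import (
    MappingSpec,
    apply_mapping,
    edcg_partition,
    edcg_residual,
    pca_subspace,
)


def _gaussian_chain_ensemble(n_particles, n_frames, seed, cov=None):
    """Frames whose x-displacements follow a given covariance; y, z static."""
    rng = np.random.default_rng(seed)
    if cov is None:
        cov = np.eye(n_particles)
    dx = rng.multivariate_normal(np.zeros(n_particles), cov, size=n_frames)
    coords = np.zeros((n_frames, n_particles, 3))
    coords[:, :, 1] = np.arange(n_particles)  # static backbone spacing
    coords[:, :, 0] = dx
    return Ensemble(coords=coords)


class TestPCA:
    def test_identical_frames_zero_variance(self):
        ens = Ensemble(coords=np.ones((5, 4, 3)))
        sub = pca_subspace(ens, n_components=1)
        np.testing.assert_allclose(sub.variances, 0.0, atol=1e-20)

    def test_matches_analytic_eigenvalues(self):
        # two particles with correlated 1D Gaussian displacements:
        # eigenvalues s^2 (1 +- rho)
        s2, rho = 0.04, 0.6
        cov = s2 * np.array([[1.0, rho], [rho, 1.0]])
        ens = _gaussian_chain_ensemble(2, 10_000, seed=1, cov=cov)
        sub = pca_subspace(ens, n_components=2, align=False)
        np.testing.assert_allclose(
            sub.variances, [s2 * (1 + rho), s2 * (1 - rho)], rtol=0.02
        )

    def test_total_variance_is_covariance_trace(self):
        ens = _gaussian_chain_ensemble(4, 500, seed=2)
        sub = pca_subspace(ens, n_components=4, align=False)
        x = (ens.coords - ens.coords.mean(axis=0)).reshape(500, -1)
        trace = np.trace(np.cov(x.T))
        assert sub.total_variance == pytest.approx(trace, rel=1e-9)

    def test_too_many_components_rejected(self):
        ens = _gaussian_chain_ensemble(3, 4, seed=3)
        with pytest.raises(ValueError):
            pca_subspace(ens, n_components=5)


def _brute_force_partition(subspace, n_beads):
    """Exhaustive enumeration over all contiguous boundary placements."""
    n = subspace.n_particles
    best, best_chi = None, np.inf
    for bounds in itertools.combinations(range(1, n), n_beads - 1):
        spec = MappingSpec.from_boundaries(bounds, n)
        chi = edcg_residual(spec, subspace)
        if chi < best_chi - 1e-15:
            best, best_chi = bounds, chi
    return best, best_chi


class TestEDCGResidual:
    def test_singleton_beads_zero(self):
        ens = _gaussian_chain_ensemble(4, 200, seed=4)
        sub = pca_subspace(ens, n_components=3, align=False)
        spec = MappingSpec(np.arange(4))
        assert edcg_residual(spec, sub) == 0.0

    def test_two_particle_hand_value(self):
        # single bead holding both particles: chi^2 = <|d1 - d2|^2> / 3
        ens = _gaussian_chain_ensemble(2, 3000, seed=5)
        sub = pca_subspace(ens, n_components=2, align=False)
        x = ens.coords - ens.coords.mean(axis=0)
        hand = np.mean(np.sum((x[:, 0] - x[:, 1]) ** 2, axis=1)) * (3000 / 2999)
        spec = MappingSpec(np.zeros(2, dtype=int))
        assert edcg_residual(spec, sub) == pytest.approx(hand / 3.0, rel=1e-9)

    def test_splitting_never_increases(self):
        ens = _gaussian_chain_ensemble(6, 300, seed=6)
        sub = pca_subspace(ens, n_components=5, align=False)
        coarse = MappingSpec(np.array([0, 0, 0, 1, 1, 1]))
        finer = MappingSpec(np.array([0, 0, 1, 2, 2, 3]))  # splits both beads
        assert edcg_residual(finer, sub) <= edcg_residual(coarse, sub) + 1e-15


class TestEDCGPartition:
    @pytest.mark.parametrize("n_particles,n_beads", [(8, 2), (10, 3), (12, 4)])
    def test_equals_exhaustive_search(self, n_particles, n_beads):
        ens = _gaussian_chain_ensemble(n_particles, 400, seed=n_particles)
        sub = pca_subspace(ens, n_components=min(6, n_particles - 1), align=False)
        spec = edcg_partition(sub, n_beads)
        bounds, chi = _brute_force_partition(sub, n_beads)
        assert tuple(spec.boundaries) == bounds
        assert edcg_residual(spec, sub) == pytest.approx(chi, rel=1e-12)

    def test_identity_mapping_when_beads_equal_particles(self):
        ens = _gaussian_chain_ensemble(5, 100, seed=9)
        sub = pca_subspace(ens, n_components=3, align=False)
        spec = edcg_partition(sub, 5)
        np.testing.assert_array_equal(spec.bead_of, np.arange(5))
        assert edcg_residual(spec, sub) == 0.0

    def test_rigid_subchain_junction_found(self):
        # two internally rigid 4-particle blocks moving independently
        rng = np.random.default_rng(10)
        n_frames = 600
        a = rng.normal(size=(n_frames, 1, 3)) * 0.3
        b = rng.normal(size=(n_frames, 1, 3)) * 0.3
        coords = np.zeros((n_frames, 8, 3))
        coords[:, :, 1] = np.arange(8) * 0.5
        coords[:, :4] += a
        coords[:, 4:] += b
        sub = pca_subspace(Ensemble(coords=coords), n_components=6, align=False)
        spec = edcg_partition(sub, 2)
        assert tuple(spec.boundaries) == (4,)

    def test_beats_random_contiguous_partitions(self):
        rng = np.random.default_rng(11)
        ens = _gaussian_chain_ensemble(15, 300, seed=12)
        sub = pca_subspace(ens, n_components=8, align=False)
        spec = edcg_partition(sub, 4)
        chi_opt = edcg_residual(spec, sub)
        for _ in range(1000):
            bounds = np.sort(rng.choice(np.arange(1, 15), size=3, replace=False))
            chi = edcg_residual(MappingSpec.from_boundaries(bounds, 15), sub)
            assert chi_opt <= chi + 1e-12

    def test_anneal_agrees_with_exact_on_separable_data(self):
        rng = np.random.default_rng(13)
        n_frames = 400
        coords = np.zeros((n_frames, 9, 3))
        coords[:, :, 1] = np.arange(9) * 0.5
        for block, sl in enumerate([slice(0, 3), slice(3, 6), slice(6, 9)]):
            coords[:, sl] += rng.normal(size=(n_frames, 1, 3)) * 0.4
        sub = pca_subspace(Ensemble(coords=coords), n_components=6, align=False)
        exact = edcg_partition(sub, 3, method="exact")
        anneal = edcg_partition(sub, 3, method="anneal", seed=3)
        assert tuple(anneal.boundaries) == tuple(exact.boundaries) == (3, 6)

    def test_invalid_bead_counts_rejected(self):
        ens = _gaussian_chain_ensemble(4, 50, seed=14)
        sub = pca_subspace(ens, n_components=2, align=False)
        with pytest.raises(ValueError):
            edcg_partition(sub, 0)
        with pytest.raises(ValueError):
            edcg_partition(sub, 5)


class TestApplyMapping:
    def test_charge_and_mass_conserved_exactly(self):
        rng = np.random.default_rng(15)
        ens = Ensemble(coords=rng.normal(size=(10, 6, 3)))
        spec = MappingSpec(np.array([0, 0, 1, 1, 1, 2]))
        q = rng.normal(size=6)
        m = rng.uniform(1, 5, size=6)
        _, qb, mb = apply_mapping(ens, spec, q, m)
        assert qb.sum() == pytest.approx(q.sum(), abs=1e-12)
        assert mb.sum() == pytest.approx(m.sum(), abs=1e-12)

    def test_singleton_bead_keeps_coordinates(self):
        rng = np.random.default_rng(16)
        ens = Ensemble(coords=rng.normal(size=(4, 3, 3)))
        spec = MappingSpec(np.array([0, 1, 2]))
        cg, _, _ = apply_mapping(ens, spec, np.zeros(3), np.ones(3))
        np.testing.assert_array_equal(cg.coords, ens.coords)

    def test_uniform_weights_midpoint(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 1.0
        spec = MappingSpec(np.array([0, 0]), weight_scheme="uniform")
        cg, _, _ = apply_mapping(Ensemble(coords=coords), spec, np.zeros(2), np.array([1.0, 3.0]))
        np.testing.assert_allclose(cg.coords[0, 0], [0.5, 0, 0])

    def test_mass_weighting(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 1.0
        spec = MappingSpec(np.array([0, 0]), weight_scheme="mass")
        cg, _, _ = apply_mapping(Ensemble(coords=coords), spec, np.zeros(2), np.array([1.0, 3.0]))
        np.testing.assert_allclose(cg.coords[0, 0], [0.75, 0, 0])

    def test_noncontiguous_mapping_rejected(self):
        with pytest.raises(ValueError):
            MappingSpec(np.array([0, 1, 0]))
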