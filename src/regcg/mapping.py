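"""Essential-dynamics coarse-graining: choosing bead boundaries from PCA.

A fine-grained chain is partitioned into contiguous bead segments so that
particles grouped into one bead move together in the essential (principal
component) subspace of the reference trajectory.  The quality of a
partition is the residual

    chi^2 = 1/(3 N_beads) < sum_I sum_{i<j in I} |dr_i^PC - dr_j^PC|^2 >

where dr_i^PC is particle i's fluctuation vector projected onto the
retained principal components.  The ensemble average is evaluated
algebraically from the retained-subspace covariance (equivalent to
averaging projected frames, without storing them): with
P_ij = sum_k lambda_k v_k(i).v_k(j) the 3x3-block trace of the
reconstructed covariance, a segment of length L contributes
L * sum_i P_ii - sum_ij P_ij.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import Ensemble
from .geometry import align_frames


@dataclass
class MappingSpec:
    """Partition of fine particles into contiguous beads.

    ``bead_of`` gives the bead index of every fine particle; beads are
    numbered 0..n_beads-1 along the chain.  ``weight_scheme`` controls the
    bead position operator: 'mass' (center of mass, the default) or
    'uniform' (center of geometry).
    """

    bead_of: np.ndarray
    weight_scheme: str = "mass"

    def __post_init__(self):
        self.bead_of = np.asarray(self.bead_of, dtype=np.int64)
        if self.weight_scheme not in ("mass", "uniform"):
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")
        b = self.bead_of
        if b.size == 0:
            raise ValueError("empty mapping")
        if b[0] != 0 or np.any(np.diff(b) < 0) or np.any(np.diff(b) > 1):
            raise ValueError(
                "beads must be contiguous chain segments numbered consecutively from 0"
            )

    @property
    def n_particles(self) -> int:
        return self.bead_of.size

    @property
    def n_beads(self) -> int:
        return int(self.bead_of[-1]) + 1

    @property
    def boundaries(self) -> np.ndarray:
        """Start index of each bead after the first (length n_beads - 1)."""
        return np.flatnonzero(np.diff(self.bead_of)) + 1

    def members(self, bead: int) -> np.ndarray:
        return np.flatnonzero(self.bead_of == bead)

    @classmethod
    def from_boundaries(
        cls, boundaries, n_particles: int, weight_scheme: str = "mass"
    ) -> "MappingSpec":
        boundaries = np.asarray(boundaries, dtype=np.int64)
        bead_of = np.zeros(n_particles, dtype=np.int64)
        bead_of[boundaries] = 1
        return cls(np.cumsum(bead_of), weight_scheme)


@dataclass
class PCSubspace:
    """Retained principal-component subspace of an aligned fine trajectory."""

    mean: np.ndarray  # (n, 3)
    components: np.ndarray  # (n_comp, 3n), orthonormal rows
    variances: np.ndarray  # (n_comp,), nm^2, decreasing
    total_variance: float  # trace of the full coordinate covariance

    @property
    def n_particles(self) -> int:
        return self.mean.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def pair_fluctuation_matrix(self) -> np.ndarray:
        """P_ij = sum_k lambda_k v_k(i) . v_k(j), the 3x3-block traces of the
        retained covariance; <|dr_i^PC - dr_j^PC|^2> = P_ii + P_jj - 2 P_ij."""
        v = self.components.reshape(self.n_components, self.n_particles, 3)
        return np.einsum("kia,kja,k->ij", v, v, self.variances)


def pca_subspace(
    fine_ensemble: Ensemble,
    n_components: int | None = None,
    variance_fraction: float = 0.9,
    align: bool = True,
) -> PCSubspace:
    """Principal components of an ensemble's coordinate fluctuations.

    Frames are least-squares superposed onto their mean structure
    (iterated to self-consistency) before the covariance is formed
    (disable with ``align=False`` for pre-aligned data).  If
    ``n_components`` is not given, the smallest number of components
    capturing at least ``variance_fraction`` of the total variance is
    retained.
    """
    if fine_ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames for a PCA")
    frames = fine_ensemble.coords.copy()
    mean = frames.mean(axis=0)
    if align:
        for _ in range(3):
            frames = align_frames(frames, mean)
            mean = frames.mean(axis=0)

    x = (frames - mean).reshape(fine_ensemble.n_frames, -1)
    # sample covariance eigendecomposition via SVD
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    variances = s**2 / (fine_ensemble.n_frames - 1)
    total = float(variances.sum())

    if n_components is None:
        if total == 0.0:
            n_components = 1
        else:
            frac = np.cumsum(variances) / total
            n_components = int(np.searchsorted(frac, variance_fraction) + 1)
            n_components = min(n_components, variances.size)
    if n_components < 1:
        raise ValueError("n_components must be at least 1")
    if n_components > min(fine_ensemble.n_frames - 1, x.shape[1]):
        raise ValueError(
            f"cannot retain {n_components} components from "
            f"{fine_ensemble.n_frames} frames of {x.shape[1]} coordinates"
        )
    return PCSubspace(
        mean=mean,
        components=vt[:n_components],
        variances=variances[:n_components],
        total_variance=total,
    )


def _segment_cost_table(P: np.ndarray) -> np.ndarray:
    """cost[a, b] = sum_{a<=i<j<b} (P_ii + P_jj - 2 P_ij) for all segments."""
    n = P.shape[0]
    diag = np.diag(P)
    # 2D prefix sums: S[a, b] = sum_{i,j in [a, b)} P_ij
    cs = np.zeros((n + 1, n + 1))
    cs[1:, 1:] = np.cumsum(np.cumsum(P, axis=0), axis=1)
    d1 = np.concatenate(([0.0], np.cumsum(diag)))
    cost = np.full((n + 1, n + 1), np.inf)
    for a in range(n):
        for b in range(a + 1, n + 1):
            L = b - a
            s1 = d1[b] - d1[a]
            S = cs[b, b] - cs[a, b] - cs[b, a] + cs[a, a]
            cost[a, b] = L * s1 - S
    return cost


def edcg_residual(spec: MappingSpec, subspace: PCSubspace) -> float:
    """The chi^2 residual (nm^2) of a partition in the retained subspace."""
    if spec.n_particles != subspace.n_particles:
        raise ValueError("partition and subspace particle counts differ")
    P = subspace.pair_fluctuation_matrix()
    diag = np.diag(P)
    chi2 = 0.0
    for bead in range(spec.n_beads):
        idx = spec.members(bead)
        L = idx.size
        if L < 2:
            continue
        chi2 += L * diag[idx].sum() - P[np.ix_(idx, idx)].sum()
    return chi2 / (3.0 * spec.n_beads)


def edcg_partition(
    subspace: PCSubspace,
    n_beads: int,
    method: str = "auto",
    seed: int = 0,
    anneal_sweeps: int = 200,
    weight_scheme: str = "mass",
) -> MappingSpec:
    """Contiguous partition minimizing the chi^2 residual.

    ``method='exact'`` runs a dynamic program over boundary placements
    (optimal; ties resolved toward the lexicographically smallest boundary
    vector).  ``'anneal'`` runs seeded simulated annealing over boundary
    moves, for systems too large for the exact table.  ``'auto'`` picks the
    exact solver below 2000 particles.
    """
    n = subspace.n_particles
    if n_beads < 1:
        raise ValueError("n_beads must be at least 1")
    if n_beads > n:
        raise ValueError("cannot use more beads than particles")
    if method == "auto":
        method = "exact" if n <= 2000 else "anneal"
    P = subspace.pair_fluctuation_matrix()
    if method == "exact":
        bounds = _partition_exact(P, n_beads)
    elif method == "anneal":
        bounds = _partition_anneal(P, n_beads, seed, anneal_sweeps)
    else:
        raise ValueError(f"unknown method {method!r}")
    return MappingSpec.from_boundaries(bounds, n, weight_scheme)


def _partition_exact(P: np.ndarray, n_beads: int) -> tuple[int, ...]:
    n = P.shape[0]
    cost = _segment_cost_table(P)
    # dp[m] = (best cost, boundary tuple) for first m particles, current bead count
    dp = [(cost[0, m], ()) for m in range(n + 1)]
    dp[0] = (0.0, ())
    for b in range(2, n_beads + 1):
        new = [(np.inf, ())] * (n + 1)
        for m in range(b, n + 1):
            best = (np.inf, ())
            for s in range(b - 1, m):
                prev_cost, prev_bounds = dp[s]
                cand = (prev_cost + cost[s, m], prev_bounds + (s,))
                if cand[0] < best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
            new[m] = best
        dp = new
    return dp[n][1]


def _partition_anneal(
    P: np.ndarray, n_beads: int, seed: int, sweeps: int
) -> tuple[int, ...]:
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    # start from an even split
    bounds = np.array(
        [round(k * n / n_beads) for k in range(1, n_beads)], dtype=np.int64
    )

    def chi(bv) -> float:
        spec = MappingSpec.from_boundaries(bv, n)
        diag = np.diag(P)
        total = 0.0
        for bead in range(spec.n_beads):
            idx = spec.members(bead)
            total += idx.size * diag[idx].sum() - P[np.ix_(idx, idx)].sum()
        return total

    cur = chi(bounds)
    best, best_cost = bounds.copy(), cur
    scale = max(cur, 1e-12)
    for sweep in range(sweeps):
        temp = scale * 0.1 * (1.0 - sweep / sweeps) + 1e-15
        for _ in range(max(n_beads - 1, 1)):
            k = rng.integers(0, n_beads - 1) if n_beads > 1 else 0
            if n_beads == 1:
                break
            step = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
            cand = bounds.copy()
            cand[k] += step
            lo = cand[k - 1] + 1 if k > 0 else 1
            hi = cand[k + 1] - 1 if k < n_beads - 2 else n - 1
            if cand[k] < lo or cand[k] > hi:
                continue
            c = chi(cand)
            if c <= cur or rng.random() < np.exp(-(c - cur) / temp):
                bounds, cur = cand, c
                if c < best_cost:
                    best, best_cost = cand.copy(), c
    return tuple(int(b) for b in best)


def apply_mapping(
    fine_ensemble: Ensemble,
    spec: MappingSpec,
    fine_charges: np.ndarray,
    fine_masses: np.ndarray,
) -> tuple[Ensemble, np.ndarray, np.ndarray]:
    """Project a fine trajectory onto beads.

    Bead positions are the (mass- or uniformly) weighted mean of member
    particles; bead charge and mass are the sums over members, so total
    charge and mass are conserved exactly.
    """
    fine_charges = np.asarray(fine_charges, dtype=np.float64)
    fine_masses = np.asarray(fine_masses, dtype=np.float64)
    if spec.n_particles != fine_ensemble.n_beads:
        raise ValueError("mapping does not cover the fine system")
    if fine_charges.size != spec.n_particles or fine_masses.size != spec.n_particles:
        raise ValueError("charge/mass arrays do not match particle count")

    w = fine_masses if spec.weight_scheme == "mass" else np.ones(spec.n_particles)
    cg = np.empty((fine_ensemble.n_frames, spec.n_beads, 3))
    q = np.empty(spec.n_beads)
    m = np.empty(spec.n_beads)
    for bead in range(spec.n_beads):
        idx = spec.members(bead)
        wb = w[idx] / w[idx].sum()
        cg[:, bead, :] = np.einsum("fia,i->fa", fine_ensemble.coords[:, idx, :], wb)
        q[bead] = fine_charges[idx].sum()
        m[bead] = fine_masses[idx].sum()
    return (
        Ensemble(coords=cg, weights=fine_ensemble.weights, meta=dict(fine_ensemble.meta)),
        q,
        m,
    )
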