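"""Heterogeneous elastic network fitting of intra-monomer springs.

Each monomer's internal structure is held by harmonic springs whose
constants are iteratively adjusted so that the CG model reproduces the
reference mean squared pair distances: the compliance update is

    1/k_IJ(n+1) = 1/k_IJ(n) - gamma_hENM * (<R_IJ^2>_CG - <R_IJ^2>_AA)

i.e. a spring whose CG fluctuations exceed the reference is stiffened.
The map k -> <R^2> sampled by the Langevin engine is monotone decreasing,
so the update sign always drives toward the fixed point; sampling noise at
the fixed point is suppressed by averaging the compliance over a final
window of iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cgmodel import CGTopology, NonbondedParams
from .ensemble import Ensemble
from .simulate import SimSettings, run


@dataclass
class HENMState:
    """Current spring constants and reference fluctuations of a hENM fit."""

    spring_i: np.ndarray
    spring_j: np.ndarray
    k: np.ndarray  # kJ mol^-1 nm^-2
    r0: np.ndarray  # nm
    msd_aa: np.ndarray  # reference <R^2>, nm^2
    gamma: np.ndarray  # per-spring learning rate on 1/k
    k_min: float = 1.0
    k_max: float = 1.0e5
    iteration: int = 0
    clamped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self):
        if np.any(self.k <= 0):
            raise ValueError("all spring constants must be positive")
        if np.any(self.msd_aa <= 0):
            raise ValueError("reference mean squared distances must be positive")
        if self.clamped.size == 0:
            self.clamped = np.zeros(self.k.size, dtype=bool)


def spring_msd(ensemble: Ensemble, spring_i, spring_j) -> np.ndarray:
    """Weighted mean squared distance <R_IJ^2> (nm^2) per listed pair."""
    spring_i = np.asarray(spring_i, dtype=np.int64)
    spring_j = np.asarray(spring_j, dtype=np.int64)
    d = ensemble.coords[:, spring_i, :] - ensemble.coords[:, spring_j, :]
    r2 = np.sum(d * d, axis=-1)
    return ensemble.average(r2)


def henm_update(state: HENMState, msd_cg: np.ndarray) -> HENMState:
    """One compliance update from measured CG fluctuations, with clamping."""
    msd_cg = np.asarray(msd_cg, dtype=np.float64)
    if msd_cg.shape != state.k.shape:
        raise ValueError("measured MSD does not match spring count")
    inv_k = 1.0 / state.k - state.gamma * (msd_cg - state.msd_aa)
    clamped = inv_k <= 1.0 / state.k_max
    new_k = np.where(clamped, state.k_max, 1.0 / np.where(clamped, 1.0, inv_k))
    low = new_k < state.k_min
    new_k = np.where(low, state.k_min, new_k)
    return replace(
        state, k=new_k, iteration=state.iteration + 1, clamped=clamped | low
    )


def default_gamma(k: np.ndarray, msd_aa: np.ndarray) -> np.ndarray:
    """Per-spring learning rate: a 10% fluctuation mismatch moves 1/k by <= 20%."""
    return 2.0 / (np.asarray(k) * np.asarray(msd_aa))


def build_spring_network(
    topology: CGTopology,
    reference: Ensemble,
    r_enm: float = 2.0,
    k_init: float = 500.0,
) -> CGTopology:
    """Connect intra-monomer bead pairs closer (on average) than ``r_enm``.

    Rest lengths are set to the reference mean distances; every spring
    starts at ``k_init`` (a typical elastic-network scale).
    """
    mono = topology.monomer_id
    ii, jj = np.triu_indices(topology.n_beads, k=1)
    intra = mono[ii] == mono[jj]
    ii, jj = ii[intra], jj[intra]
    d = reference.coords[:, ii, :] - reference.coords[:, jj, :]
    mean_r = reference.average(np.sqrt(np.sum(d * d, axis=-1)))
    keep = mean_r < r_enm
    ii, jj, mean_r = ii[keep], jj[keep], mean_r[keep]
    return topology.with_springs(ii, jj, np.full(ii.size, k_init), mean_r)


@dataclass
class HENMFitResult:
    topology: CGTopology
    state: HENMState
    history: list[dict]
    converged: bool


def henm_fit(
    topology: CGTopology,
    reference: Ensemble,
    settings: SimSettings,
    params: NonbondedParams | None = None,
    n_iterations: int = 30,
    tolerance: float = 1.0e-3,
    gamma_scale: float = 1.0,
    average_window: int = 10,
    start_coords: np.ndarray | None = None,
) -> HENMFitResult:
    """Fit all spring constants of ``topology`` against a reference ensemble.

    Each iteration samples the current model with the Langevin engine and
    applies the compliance update.  Convergence is declared when the largest
    relative MSD mismatch drops below ``tolerance``; otherwise the best
    state is returned with ``converged=False`` and a warning.  The returned
    spring constants are the harmonic mean of k over the final
    ``average_window`` iterations (averaging the compliance, which is the
    quantity the update walks in).
    """
    if topology.spring_i.size == 0:
        raise ValueError("topology has no springs to fit")
    if params is None:
        params = NonbondedParams(pairs={})
    msd_aa = spring_msd(reference, topology.spring_i, topology.spring_j)
    if np.any(msd_aa <= 0):
        raise ValueError("zero reference fluctuation distance; frozen reference?")
    state = HENMState(
        spring_i=topology.spring_i,
        spring_j=topology.spring_j,
        k=topology.spring_k.copy(),
        r0=topology.spring_r0.copy(),
        msd_aa=msd_aa,
        gamma=gamma_scale * default_gamma(topology.spring_k, msd_aa),
    )
    if start_coords is None:
        start_coords = reference.coords.mean(axis=0)

    history: list[dict] = []
    inv_k_window: list[np.ndarray] = []
    converged = False
    for it in range(n_iterations):
        topo = topology.with_springs(state.spring_i, state.spring_j, state.k, state.r0)
        ens = run(
            topo, params, start_coords,
            replace(settings, seed=settings.seed + it),
        )
        msd_cg = spring_msd(ens, state.spring_i, state.spring_j)
        err = np.abs(msd_cg - state.msd_aa) / state.msd_aa
        history.append(
            {"iteration": it, "max_rel_msd_err": float(err.max()), "k": state.k.copy()}
        )
        inv_k_window.append(1.0 / state.k)
        if err.max() < tolerance:
            converged = True
            break
        state = henm_update(state, msd_cg)

    inv_k_avg = np.mean(inv_k_window[-average_window:], axis=0)
    k_fit = np.clip(1.0 / inv_k_avg, state.k_min, state.k_max)
    fitted = topology.with_springs(state.spring_i, state.spring_j, k_fit, state.r0)
    if not converged:
        warnings.warn(
            f"hENM fit did not reach tolerance {tolerance:g} in {n_iterations} "
            f"iterations (last max relative MSD error "
            f"{history[-1]['max_rel_msd_err']:.3g}); returning window-averaged state",
            stacklevel=2,
        )
    return HENMFitResult(
        topology=fitted, state=replace(state, k=k_fit), history=history,
        converged=converged,
    )
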