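"""Langevin-dynamics sampling of CG models, plus trajectory observables.

The sampler is the source of every CG-side ensemble average used in hENM
fitting and relative-entropy training.  It uses a BAOAB splitting of the
Langevin equation, which gives accurate configurational sampling at the
large time steps (default 15 fs) these soft bead models tolerate.  Because
the models live in open boundary conditions, an optional reflecting
spherical wall bounds the accessible volume so that dissociated binding
partners can re-encounter each other during finite runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .cgmodel import CGTopology, CompiledSystem, NonbondedParams, compile_system
from .ensemble import Ensemble
from .geometry import kabsch
from .units import FS, KB


@dataclass
class SimSettings:
    """Integrator settings.

    dt is in fs (converted internally to ps), friction in ps^-1, the wall
    radius in nm (non-positive disables the wall).  ``stride`` is the
    recording interval in steps.
    """

    dt: float = 15.0
    temperature: float = 310.0
    friction: float = 1.0
    n_steps: int = 10000
    stride: int = 100
    seed: int = 0
    wall_radius: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.stride < 1 or self.stride > self.n_steps:
            raise ValueError("stride must be in [1, n_steps]")


class SimulationUnstableError(RuntimeError):
    """Raised when the integrator produces a non-finite energy."""

    def __init__(self, frame_index: int):
        super().__init__(
            f"non-finite energy at recorded frame {frame_index}; "
            "the model or time step is unstable"
        )
        self.frame_index = frame_index


def run(
    topology: CGTopology,
    params: NonbondedParams,
    start: np.ndarray,
    settings: SimSettings,
    vbind_pair: tuple[int, int] | None = None,
    system: CompiledSystem | None = None,
    start_velocities: np.ndarray | None = None,
) -> Ensemble:
    """Sample the model with Langevin dynamics.

    Returns an :class:`Ensemble` whose frames were recorded every
    ``settings.stride`` steps, carrying per-frame V_bind and dU/dtheta
    (restricted to the designated monomer pair when ``vbind_pair`` is set)
    plus an energy table in ``meta['energies']`` with columns
    (step, U_bond, U_elec, U_rep, U_att, V_bind, E_kin).  Identical seeds
    give identical trajectories.
    """
    sys = system if system is not None else compile_system(topology, params, vbind_pair)
    start = np.asarray(start, dtype=np.float64)
    if start.shape != (topology.n_beads, 3):
        raise ValueError("start coordinates do not match topology bead count")

    kT = KB * settings.temperature
    rng = np.random.default_rng(settings.seed)
    if start_velocities is not None:
        v0 = np.asarray(start_velocities, dtype=np.float64).copy()
    elif kT > 0:
        v0 = rng.normal(size=start.shape) * np.sqrt(kT / sys.mass)[:, None]
    else:
        v0 = np.zeros_like(start)

    n_rec = settings.n_steps // settings.stride
    frames = np.empty((n_rec, topology.n_beads, 3))
    energies = np.empty((n_rec, 7))
    grads = np.empty((n_rec, max(sys.n_theta, 0)))

    bad = _kernels.integrate(
        start, v0, sys.mass,
        settings.dt * FS, settings.n_steps, settings.stride,
        kT, settings.friction, settings.seed % 2**31, settings.wall_radius,
        sys.pi, sys.pj, sys.qq, sys.A, sys.R_rep, sys.R_att, sys.b_on,
        sys.slot, sys.slot_c, sys.slot_theta, sys.vbind_mask,
        sys.sigma, sys.B, sys.kappa_D, sys.cutoff,
        sys.spring_i, sys.spring_j, sys.spring_k, sys.spring_r0,
        frames, energies, grads,
    )
    if bad >= 0:
        raise SimulationUnstableError(bad)

    return Ensemble(
        coords=frames,
        v_bind=energies[:, 5].copy(),
        du_dtheta=grads,
        meta={"energies": energies, "settings": settings},
    )


def kinetic_temperature(ensemble: Ensemble) -> np.ndarray:
    """Instantaneous kinetic temperature per recorded frame, K."""
    energies = ensemble.meta.get("energies")
    if energies is None:
        raise ValueError("ensemble carries no energy table")
    n_dof = 3 * ensemble.n_beads
    return 2.0 * energies[:, 6] / (n_dof * KB)


def rmsd(ensemble: Ensemble, reference: np.ndarray) -> np.ndarray:
    """Per-frame RMSD (nm) to ``reference`` after least-squares superposition."""
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != (ensemble.n_beads, 3):
        raise ValueError("reference does not match ensemble bead count")
    out = np.empty(ensemble.n_frames)
    for k in range(ensemble.n_frames):
        _, out[k] = kabsch(ensemble.coords[k], reference)
    return out


def count_binding_cycles(
    v_bind: np.ndarray,
    bound_threshold: float = -8.0,
    unbound_threshold: float = -1.0,
) -> int:
    """Number of completed unbind-rebind cycles in a binding-energy series.

    A hysteresis state machine: starting bound, a cycle is counted each time
    the series crosses above ``unbound_threshold`` and later returns below
    ``bound_threshold``.
    """
    v_bind = np.asarray(v_bind)
    state = "bound"
    cycles = 0
    for v in v_bind:
        if state == "bound" and v > unbound_threshold:
            state = "unbound"
        elif state == "unbound" and v < bound_threshold:
            state = "bound"
            cycles += 1
    return cycles


@dataclass
class RDFResult:
    """Distance distribution p(R) of a bead-type pair, normalized to sum(p) dR = 1."""

    bin_centers: np.ndarray
    p: np.ndarray
    bin_width: float

    @property
    def p_max(self) -> float:
        return float(self.p.max())


def rdf(
    ensemble: Ensemble,
    topology: CGTopology,
    type_i: str,
    type_j: str,
    bin_width: float = 0.02,
    r_max: float | None = None,
    inter_monomer: bool = True,
) -> RDFResult:
    """Histogram of pair distances for one type pair across frames.

    Distances are binned half-open [lo, hi); frame weights are respected.
    This is the plain distance distribution (for uniformly random points it
    grows like the R^2 shell volume), which is what the repulsion- and
    attraction-range rules of :mod:`regcg.modelbuild` consume.
    """
    types = np.array(topology.bead_type)
    mono = topology.monomer_id
    ii, jj = np.triu_indices(topology.n_beads, k=1)
    match = ((types[ii] == type_i) & (types[jj] == type_j)) | (
        (types[ii] == type_j) & (types[jj] == type_i)
    )
    if inter_monomer:
        match &= mono[ii] != mono[jj]
    ii, jj = ii[match], jj[match]
    if ii.size == 0:
        raise ValueError(f"no {'inter-monomer ' if inter_monomer else ''}pairs of types ({type_i}, {type_j})")

    d = ensemble.coords[:, ii, :] - ensemble.coords[:, jj, :]
    r = np.sqrt(np.sum(d * d, axis=-1))  # (n_frames, n_pairs)
    if r_max is None:
        # headroom keeps a sharply peaked distribution off the histogram edge
        r_max = float(r.max()) + 5 * bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    w = np.repeat(ensemble.normalized_weights(), ii.size)
    hist, _ = np.histogram(r.ravel(), bins=edges, weights=w)
    total = hist.sum()
    if total <= 0:
        raise ValueError("all pair distances fall outside the histogram range")
    p = hist / (total * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(bin_centers=centers, p=p, bin_width=bin_width)
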