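"""Synthetic reference systems with known ground truth.

Each generator builds a small CG system whose native structure, spring
constants k*, charges and Gaussian amplitudes theta* are fixed by
construction, then samples a reference ensemble from that ground-truth
model with the package's own Langevin engine.  The fixtures emulate the
three regimes a binding-regularized coarse-graining method must handle —
a strongly bound dimer, a lattice-like multimer trained through one
designated monomer pair, and a weakly bound chain pair whose terminal
"rungs" fray — at desk scale, not the geometry of any real protein or
nucleic acid.

Recovery tests consume only the trajectory and topology; the ground truth
(theta*, k*, the generating mapping) travels alongside for the final
comparison only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cgmodel import CGTopology, NonbondedParams, PairEntry, compile_system, pair_key
from .ensemble import Ensemble
from .mapping import MappingSpec
from .simulate import SimSettings, run


@dataclass
class FixtureSpec:
    """Generation settings shared by all fixture kinds."""

    kind: str = "dimer"  # 'dimer' | 'multimer' | 'duplex'
    n_frames: int = 1000
    stride: int = 100
    temperature: float | None = None  # default per kind
    seed: int = 0
    fine_factor: int = 3  # particles per bead, fine-chain fixture
    # reflecting-wall radius, nm; None picks a per-kind default emulating
    # the reference simulation's effective concentration (snug for the
    # stably bound kinds, roomy for the weak duplex so it can dissociate)
    wall_radius: float | None = None

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")


@dataclass
class Fixture:
    """A generated reference system plus its ground truth."""

    topology: CGTopology
    params: NonbondedParams  # carries theta* in the trainable C entries
    ensemble: Ensemble
    native: np.ndarray
    theta_star: np.ndarray
    theta_keys: list[tuple[str, str]]
    vbind_pair: tuple[int, int] | None
    temperature: float
    spec: FixtureSpec
    extras: dict = field(default_factory=dict)


def _spring_net(native: np.ndarray, mono: np.ndarray, r_enm: float = 1.4):
    """All intra-monomer pairs closer than r_enm in the native structure.

    Spring constants cycle through three stiffness classes so the network
    is genuinely heterogeneous.
    """
    n = native.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    keep = mono[ii] == mono[jj]
    ii, jj = ii[keep], jj[keep]
    d = np.linalg.norm(native[ii] - native[jj], axis=1)
    close = d < r_enm
    ii, jj, d = ii[close], jj[close], d[close]
    k = 500.0 + 250.0 * ((ii + jj) % 3)
    return ii, jj, k, d


def _contact_params(
    native: np.ndarray,
    topology: CGTopology,
    c_star: dict[tuple[str, str], float],
    c_fixed: dict[tuple[str, str], float] | None = None,
    contact_cut: float = 1.3,
    sigma: float = 0.2,
    cutoff: float = 2.5,
    rep_frac: float = 0.72,
) -> NonbondedParams:
    """Pair table from the native structure.

    Type pairs listed in ``c_star`` become trainable Gaussian wells centered
    at the native distance of their closest inter-monomer bead pair; pairs
    in ``c_fixed`` get wells of fixed (non-trainable) amplitude; everything
    else is repulsion-only.  A follows the charge rule (like-sign
    10 kcal/mol tier).  Every pair's repulsive shoulder starts at
    ``rep_frac`` times its native distance; values close to 1 emulate a
    snugly complementary (sterically caged) interface.
    """
    c_fixed = c_fixed or {}
    from .modelbuild import assign_A

    types = np.array(topology.bead_type)
    mono = topology.monomer_id
    ii, jj = np.triu_indices(topology.n_beads, k=1)
    inter = mono[ii] != mono[jj]
    ii, jj = ii[inter], jj[inter]
    d = np.linalg.norm(native[ii] - native[jj], axis=1)

    pairs: dict[tuple[str, str], PairEntry] = {}
    keys = sorted({pair_key(str(types[a]), str(types[b])) for a, b in zip(ii, jj)})
    charge_of = {str(t): float(topology.charge[types == t][0]) for t in np.unique(types)}
    for key in keys:
        ti, tj = key
        sel = (
            ((types[ii] == ti) & (types[jj] == tj))
            | ((types[ii] == tj) & (types[jj] == ti))
        )
        dmin = float(d[sel].min())
        a_val = assign_A(charge_of[ti], charge_of[tj])
        if key in c_star or key in c_fixed:
            if dmin > contact_cut:
                raise ValueError(f"type pair {key} has no contact within {contact_cut} nm")
            pairs[key] = PairEntry(
                A=a_val,
                R_rep=rep_frac * dmin,
                C=c_star.get(key, c_fixed.get(key, 0.0)),
                R_att=dmin,
                trainable=key in c_star,
            )
        else:
            pairs[key] = PairEntry(
                A=a_val, R_rep=rep_frac * dmin, C=0.0, R_att=1.0, trainable=False
            )
    return NonbondedParams(pairs=pairs, sigma=sigma, cutoff=cutoff)


_WALL_DEFAULT = {"dimer": 1.05, "multimer": 1.5, "duplex": 2.0, "chain": 0.0}


def wall_radius_for(spec: FixtureSpec) -> float:
    if spec.wall_radius is not None:
        return spec.wall_radius
    return _WALL_DEFAULT.get(spec.kind, 2.5)


def _sample_reference(
    topology: CGTopology,
    params: NonbondedParams,
    native: np.ndarray,
    spec: FixtureSpec,
    temperature: float,
    vbind_pair: tuple[int, int] | None,
) -> Ensemble:
    settings = SimSettings(
        dt=15.0,
        temperature=temperature,
        friction=1.0,
        n_steps=spec.n_frames * spec.stride,
        stride=spec.stride,
        seed=spec.seed,
        wall_radius=wall_radius_for(spec),
    )
    ens = run(topology, params, native, settings, vbind_pair)
    ens.meta["native"] = native
    return ens


# ---------------------------------------------------------------------------
# bound dimer (strong-binding analog)
# ---------------------------------------------------------------------------

# monomer template: a central bead with four arms in the y-z plane, so the
# binding interface has contacts spread in both transverse directions
_DIMER_TEMPLATE = np.array(
    [
        [0.10, -0.60, 0.00],
        [0.10, 0.00, -0.60],
        [0.00, 0.00, 0.00],
        [0.10, 0.00, 0.60],
        [0.10, 0.60, 0.00],
    ]
)
# heterodimer with complementary rung charges
_DIMER_CHARGES_A = {"P1": 1.0, "P2": -1.0, "P3": 1.5, "P4": -1.0, "P5": 1.0}
_DIMER_CHARGES_B = {"Q1": -1.0, "Q2": 1.0, "Q3": -1.5, "Q4": 1.0, "Q5": -1.0}
# trainable ground-truth amplitudes, kJ mol^-1 nm (five rung wells)
_DIMER_CSTAR = {
    ("P1", "Q1"): -1.55,
    ("P2", "Q2"): -1.85,
    ("P3", "Q3"): -2.1,
    ("P4", "Q4"): -1.85,
    ("P5", "Q5"): -1.55,
}
# fixed (non-trainable) cross wells between each arm and the partner's
# center; they lock the binding registry against sliding and twisting and
# belong to the fixed part of the force field, like A_IJ and the charges
_DIMER_CROSS = -0.55
_DIMER_CFIXED = {
    ("P1", "Q3"): _DIMER_CROSS, ("P3", "Q1"): _DIMER_CROSS,
    ("P2", "Q3"): _DIMER_CROSS, ("P3", "Q2"): _DIMER_CROSS,
    ("P4", "Q3"): _DIMER_CROSS, ("P3", "Q4"): _DIMER_CROSS,
    ("P5", "Q3"): _DIMER_CROSS, ("P3", "Q5"): _DIMER_CROSS,
}
_DIMER_GAP = 0.45  # half-separation of the two monomers along x, nm


def make_dimer_reference(spec: FixtureSpec | None = None) -> Fixture:
    """Two 5-bead monomers bound rung-by-rung through five Gaussian wells.

    The reference is sampled from the ground-truth model at 310 K and is
    expected to remain bound throughout (it stands in for a reference
    trajectory of a stable complex); a warning is raised otherwise.
    """
    spec = spec or FixtureSpec(kind="dimer")
    T = spec.temperature or 310.0
    names_a = list(_DIMER_CHARGES_A)
    names_b = list(_DIMER_CHARGES_B)
    native = np.vstack(
        [
            _DIMER_TEMPLATE * np.array([-1.0, 1.0, 1.0]) - np.array([_DIMER_GAP, 0, 0]),
            _DIMER_TEMPLATE + np.array([_DIMER_GAP, 0, 0]),
        ]
    )
    mono = np.repeat([0, 1], 5)
    topology = CGTopology(
        monomer_id=mono,
        bead_type=names_a + names_b,
        charge=np.array(
            [_DIMER_CHARGES_A[t] for t in names_a]
            + [_DIMER_CHARGES_B[t] for t in names_b]
        ),
        mass=np.full(10, 350.0),
    )
    si, sj, k, r0 = _spring_net(native, mono)
    topology = topology.with_springs(si, sj, k, r0)
    params = _contact_params(native, topology, _DIMER_CSTAR, _DIMER_CFIXED,
                             contact_cut=1.5, rep_frac=0.93)
    ens = _sample_reference(topology, params, native, spec, T, None)
    _warn_if_unbound(ens, "dimer")
    return Fixture(
        topology=topology,
        params=params,
        ensemble=ens,
        native=native,
        theta_star=params.get_theta(),
        theta_keys=params.theta_keys(),
        vbind_pair=None,
        temperature=T,
        spec=spec,
    )


def _warn_if_unbound(ens: Ensemble, kind: str, threshold: float = -1.0) -> None:
    frac = float(np.mean(ens.v_bind > threshold))
    if frac > 0.01:
        warnings.warn(
            f"{kind} reference is unbound in {frac:.1%} of frames; "
            "recovery and overfitting demonstrations assume a bound reference",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# trimer lattice (multimer analog)
# ---------------------------------------------------------------------------

_TRIMER_OFFSETS = np.array(
    [
        [0.40, 0.00, 0.06],
        [0.00, 0.40, -0.06],
        [-0.40, 0.00, 0.06],
        [0.00, -0.40, -0.06],
    ]
)
_TRIMER_CHARGES = {"T1": 0.5, "T2": -0.5, "T3": 0.5, "T4": -0.5}
_TRIMER_CSTAR = {("T3", "T3"): -8.5, ("T2", "T3"): -4.2, ("T3", "T4"): -3.3}
_TRIMER_RADIUS = 0.95  # monomer center distance from the symmetry axis, nm


def make_multimer_reference(spec: FixtureSpec | None = None) -> Fixture:
    """Three identical 4-bead monomers on a C3-symmetric ring.

    All monomers share one type-pair parameter table; training acts on the
    designated pair (0, 1), emulating the lattice training mode in which
    gradients and the regularizer are computed from two monomers and the
    updated parameters are used by all.
    """
    spec = spec or FixtureSpec(kind="multimer")
    T = spec.temperature or 310.0
    names = list(_TRIMER_CHARGES)
    coords = []
    for m in range(3):
        phi = np.pi / 2.0 + 2.0 * np.pi * m / 3.0
        c, s = np.cos(phi), np.sin(phi)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        center = np.array([_TRIMER_RADIUS * c, _TRIMER_RADIUS * s, 0.0])
        coords.append(_TRIMER_OFFSETS @ rot.T + center)
    native = np.vstack(coords)
    mono = np.repeat([0, 1, 2], 4)
    topology = CGTopology(
        monomer_id=mono,
        bead_type=names * 3,
        charge=np.array([_TRIMER_CHARGES[t] for t in names] * 3),
        mass=np.full(12, 350.0),
    )
    si, sj, k, r0 = _spring_net(native, mono)
    topology = topology.with_springs(si, sj, k, r0)
    params = _contact_params(native, topology, _TRIMER_CSTAR, rep_frac=0.9)
    ens = _sample_reference(topology, params, native, spec, T, (0, 1))
    _warn_if_unbound(ens, "multimer", threshold=-1.0)
    return Fixture(
        topology=topology,
        params=params,
        ensemble=ens,
        native=native,
        theta_star=params.get_theta(),
        theta_keys=params.theta_keys(),
        vbind_pair=(0, 1),
        temperature=T,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# weak duplex (chain-pair analog with terminal fraying)
# ---------------------------------------------------------------------------

_DUPLEX_CHARGES = {"R1": -0.25, "R2": -0.25, "R3": -0.25, "R4": -0.25}
# terminal rungs (R1, R4) are shallower than central ones -> fraying
_DUPLEX_CSTAR = {
    ("R1", "R1"): -2.0,
    ("R2", "R2"): -4.0,
    ("R3", "R3"): -4.0,
    ("R4", "R4"): -2.0,
}
_DUPLEX_RISE = 0.5  # rung spacing along the chain, nm
_DUPLEX_SEP = 0.45  # half-separation of the strands, nm


def make_weak_duplex(spec: FixtureSpec | None = None) -> Fixture:
    """Two 4-bead chains paired rung by rung, weakly bound.

    Each rung is one bead per strand; the terminal wells are half as deep
    as the central ones, so long bound-state runs show larger terminal
    rung distances (fraying) and elevated-temperature runs show unbind /
    rebind cycles within the confining wall.
    """
    spec = spec or FixtureSpec(kind="duplex")
    T = spec.temperature or 300.0
    names = list(_DUPLEX_CHARGES)
    ys = (np.arange(4) - 1.5) * _DUPLEX_RISE
    strand_a = np.stack([-np.full(4, _DUPLEX_SEP), ys, 0.05 * (-1.0) ** np.arange(4)], axis=1)
    strand_b = np.stack([np.full(4, _DUPLEX_SEP), ys, 0.05 * (-1.0) ** np.arange(4)], axis=1)
    native = np.vstack([strand_a, strand_b])
    mono = np.repeat([0, 1], 4)
    topology = CGTopology(
        monomer_id=mono,
        bead_type=names + names,
        charge=np.array([_DUPLEX_CHARGES[t] for t in names] * 2),
        mass=np.full(8, 300.0),
    )
    si, sj, k, r0 = _spring_net(native, mono, r_enm=1.2)
    topology = topology.with_springs(si, sj, k, r0)
    params = _contact_params(native, topology, _DUPLEX_CSTAR)
    ens = _sample_reference(topology, params, native, spec, T, None)
    return Fixture(
        topology=topology,
        params=params,
        ensemble=ens,
        native=native,
        theta_star=params.get_theta(),
        theta_keys=params.theta_keys(),
        vbind_pair=None,
        temperature=T,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# fine-resolution chain (mapping / hENM ground truth)
# ---------------------------------------------------------------------------

@dataclass
class FineChain:
    """A pseudo-atomistic trajectory with its generating mapping."""

    fine_ensemble: Ensemble
    true_mapping: MappingSpec
    fine_charges: np.ndarray
    fine_masses: np.ndarray
    bead_topology: CGTopology
    bead_ensemble: Ensemble
    true_k: np.ndarray


def make_fine_chain(
    spec: FixtureSpec | None = None,
    n_beads: int = 4,
    cluster_size: float = 0.05,
) -> FineChain:
    """Chain of beads, each realized as a tight cluster of fine particles.

    A bead-level chain with heterogeneous springs is sampled first; every
    bead is then expanded into ``spec.fine_factor`` particles at fixed
    small offsets plus Gaussian jitter of scale ``cluster_size`` (well
    below the inter-bead motion, so essential-dynamics partitioning should
    recover the generating cluster boundaries).  Bead charges are split
    equally among member particles; masses likewise.
    """
    spec = spec or FixtureSpec(kind="chain")
    if spec.fine_factor < 1:
        raise ValueError("fine_factor must be at least 1")
    T = spec.temperature or 310.0
    rng = np.random.default_rng(spec.seed)

    native = np.stack(
        [np.zeros(n_beads), (np.arange(n_beads) - (n_beads - 1) / 2.0) * 0.5,
         0.08 * (-1.0) ** np.arange(n_beads)],
        axis=1,
    )
    mono = np.zeros(n_beads, dtype=np.int64)
    charges = np.round(rng.uniform(-1.0, 1.0, n_beads) * 4) / 4.0
    topology = CGTopology(
        monomer_id=mono,
        bead_type=[f"B{i+1}" for i in range(n_beads)],
        charge=charges,
        mass=np.full(n_beads, 300.0),
    )
    si, sj, k, r0 = _spring_net(native, mono, r_enm=1.1)
    topology = topology.with_springs(si, sj, k, r0)
    params = NonbondedParams(pairs={})

    settings = SimSettings(
        dt=15.0, temperature=T, friction=1.0,
        n_steps=spec.n_frames * spec.stride, stride=spec.stride,
        seed=spec.seed, wall_radius=0.0,
    )
    bead_ens = run(topology, params, native, settings)

    f = spec.fine_factor
    if f == 1:
        fine = bead_ens.coords.copy()
        offsets = np.zeros((n_beads, 1, 3))
    else:
        # fixed offsets on a small ring around each bead center (mean zero)
        ang = 2.0 * np.pi * np.arange(f) / f
        ring = cluster_size * np.stack([np.cos(ang), np.sin(ang), np.zeros(f)], axis=1)
        offsets = np.tile(ring, (n_beads, 1, 1))
        jitter = rng.normal(scale=0.2 * cluster_size,
                            size=(bead_ens.n_frames, n_beads, f, 3))
        fine = (bead_ens.coords[:, :, None, :] + offsets[None] + jitter).reshape(
            bead_ens.n_frames, n_beads * f, 3
        )
    bead_of = np.repeat(np.arange(n_beads), f)
    mapping = MappingSpec(bead_of, weight_scheme="mass")
    fine_charges = np.repeat(charges / f, f)
    fine_masses = np.repeat(topology.mass / f, f)
    return FineChain(
        fine_ensemble=Ensemble(coords=fine),
        true_mapping=mapping,
        fine_charges=fine_charges,
        fine_masses=fine_masses,
        bead_topology=topology,
        bead_ensemble=bead_ens,
        true_k=topology.spring_k.copy(),
    )


def make_reference(spec: FixtureSpec) -> Fixture:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "dimer":
        return make_dimer_reference(spec)
    if spec.kind == "multimer":
        return make_multimer_reference(spec)
    if spec.kind == "duplex":
        return make_weak_duplex(spec)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
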