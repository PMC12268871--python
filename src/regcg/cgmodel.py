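"""Coarse-grained topology, potential energy function, forces and parameter gradients.

The CG potential is a sum of four terms,

    U = U_bond + U_elec + U_rep + U_att

where U_bond collects intra-monomer harmonic springs (fitted by the hENM
procedure in :mod:`regcg.henm`) and the three nonbonded terms act between
beads of *different* monomers only:

* U_elec — Debye-screened Coulomb, Q_I Q_J / (4 pi eps0 eps_r R) * exp(-kappa_D R),
  representing implicit-solvent electrostatics at finite salt;
* U_rep — a soft cosine shoulder A_IJ [1 + cos(pi R / R_rep)] for R < R_rep
  plus a short-range B / R^4 barrier that keeps opposite-charge pairs from
  collapsing onto the Coulomb singularity;
* U_att — a Gaussian well C_IJ / (sigma sqrt(2 pi)) * exp(-(R - R_att)^2 / 2 sigma^2).

The Gaussian amplitudes C_IJ are the trainable parameters theta of the
relative-entropy machinery; attraction corresponds to C < 0.  All nonbonded
terms are truncated sharply at the global cutoff without energy shifting
(the training averages depend on absolute energies, and the wells are short
ranged compared to the default 2.5 nm cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import KE


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CGTopology:
    """Bead and spring description of a CG system.

    ``monomer_id`` assigns each bead to a molecule; springs may only connect
    beads of the same monomer (inter-monomer structure is the business of the
    nonbonded terms).  Charges are in elementary charges, masses in u,
    spring constants in kJ mol^-1 nm^-2 and rest lengths in nm.
    """

    monomer_id: np.ndarray
    bead_type: list[str]
    charge: np.ndarray
    mass: np.ndarray
    spring_i: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    spring_j: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    spring_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    spring_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.monomer_id = np.asarray(self.monomer_id, dtype=np.int64)
        self.charge = np.asarray(self.charge, dtype=np.float64)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        self.spring_i = np.asarray(self.spring_i, dtype=np.int64)
        self.spring_j = np.asarray(self.spring_j, dtype=np.int64)
        self.spring_k = np.asarray(self.spring_k, dtype=np.float64)
        self.spring_r0 = np.asarray(self.spring_r0, dtype=np.float64)
        n = self.n_beads
        if not (len(self.bead_type) == self.charge.size == self.mass.size == n):
            raise ValueError("bead attribute lengths disagree")
        if np.any(self.mass <= 0):
            raise ValueError("all bead masses must be positive")
        if self.spring_i.size:
            if np.any(self.spring_k <= 0):
                raise ValueError("all spring constants must be positive")
            if np.any(self.spring_i < 0) or np.any(self.spring_j >= n):
                raise ValueError("spring index out of range")
            if np.any(self.spring_i == self.spring_j):
                raise ValueError("spring connecting a bead to itself")
            same = self.monomer_id[self.spring_i] == self.monomer_id[self.spring_j]
            if not np.all(same):
                bad = int(np.flatnonzero(~same)[0])
                raise ValueError(
                    f"spring {bad} connects beads of different monomers; "
                    "bonded terms are intra-monomer only"
                )

    @property
    def n_beads(self) -> int:
        return self.monomer_id.size

    @property
    def n_monomers(self) -> int:
        return int(np.unique(self.monomer_id).size)

    @property
    def bead_id(self) -> np.ndarray:
        return np.arange(self.n_beads, dtype=np.int64)

    def with_springs(self, spring_i, spring_j, spring_k, spring_r0) -> "CGTopology":
        return CGTopology(
            monomer_id=self.monomer_id,
            bead_type=list(self.bead_type),
            charge=self.charge,
            mass=self.mass,
            spring_i=np.asarray(spring_i, dtype=np.int64),
            spring_j=np.asarray(spring_j, dtype=np.int64),
            spring_k=np.asarray(spring_k, dtype=np.float64),
            spring_r0=np.asarray(spring_r0, dtype=np.float64),
        )


def pair_key(type_i: str, type_j: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered type pair."""
    return (type_i, type_j) if type_i <= type_j else (type_j, type_i)


@dataclass
class PairEntry:
    """Nonbonded constants for one type pair."""

    A: float  # kJ/mol, cosine-shoulder amplitude
    R_rep: float  # nm, shoulder range
    C: float = 0.0  # kJ mol^-1 nm, Gaussian amplitude (signed; attraction < 0)
    R_att: float = 1.0  # nm, Gaussian center
    trainable: bool = False
    b_enabled: bool = True  # whether the B/R^4 barrier acts on this pair


@dataclass
class NonbondedParams:
    """Type-pair table plus the global nonbonded constants.

    Defaults for the globals follow the standard parametrization of this
    model family: eps_r = 17.5, kappa_D = 1.274 nm^-1, sigma = 0.2 nm,
    cutoff = 2.5 nm, and B = 6 kcal/mol A^4 (stored in kJ mol^-1 nm^4).
    """

    pairs: dict[tuple[str, str], PairEntry]
    sigma: float = 0.2
    B: float = 6.0 * 4.184 * 1.0e-4  # kcal/mol/A^4 -> kJ/mol/nm^4
    eps_r: float = 17.5
    kappa_D: float = 1.274
    cutoff: float = 2.5

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for key, entry in self.pairs.items():
            if key != pair_key(*key):
                raise ValueError(f"pair key {key} not in canonical order")
            if entry.A < 0:
                raise ValueError(f"A must be non-negative for pair {key}")
            if entry.R_rep <= 0:
                raise ValueError(f"R_rep must be positive for pair {key}")

    def entry(self, type_i: str, type_j: str) -> PairEntry:
        return self.pairs[pair_key(type_i, type_j)]

    # --- the trainable parameter vector -----------------------------------

    def theta_keys(self) -> list[tuple[str, str]]:
        """Trainable type pairs in deterministic (sorted) order."""
        return sorted(k for k, e in self.pairs.items() if e.trainable)

    def get_theta(self) -> np.ndarray:
        return np.array([self.pairs[k].C for k in self.theta_keys()])

    def set_theta(self, theta: np.ndarray) -> None:
        keys = self.theta_keys()
        theta = np.asarray(theta, dtype=np.float64)
        if theta.shape != (len(keys),):
            raise ValueError(f"theta must have length {len(keys)}")
        for k, c in zip(keys, theta):
            self.pairs[k].C = float(c)

    def copy(self) -> "NonbondedParams":
        return NonbondedParams(
            pairs={k: replace(e) for k, e in self.pairs.items()},
            sigma=self.sigma,
            B=self.B,
            eps_r=self.eps_r,
            kappa_D=self.kappa_D,
            cutoff=self.cutoff,
        )


@dataclass
class EnergyBreakdown:
    """Energy components of one configuration, kJ/mol.

    ``U_total`` is always the sum of the four components; ``V_bind`` is the
    inter-monomer nonbonded energy (optionally restricted to one designated
    monomer pair) and never contains bonded contributions.
    """

    U_bond: float
    U_elec: float
    U_rep: float
    U_att: float
    V_bind: float

    @property
    def U_total(self) -> float:
        return self.U_bond + self.U_elec + self.U_rep + self.U_att


# ---------------------------------------------------------------------------
# pair potentials (scalar / array forms)
# ---------------------------------------------------------------------------

def u_elec(R, Q_I: float, Q_J: float, params: NonbondedParams):
    """Debye-screened Coulomb pair energy, kJ/mol; zero beyond the cutoff."""
    R = np.asarray(R, dtype=np.float64)
    if np.any(R <= 0):
        raise ValueError("pair distance must be positive")
    u = KE * Q_I * Q_J / (params.eps_r * R) * np.exp(-params.kappa_D * R)
    u = np.where(R > params.cutoff, 0.0, u)
    return u if u.ndim else float(u)


def u_rep(R, A: float, R_rep: float, B: float):
    """Cosine-shoulder plus B/R^4 repulsion, kJ/mol.

    The shoulder A[1 + cos(pi R/R_rep)] acts only for R < R_rep (Heaviside
    factor, with H(0) = 1 by convention — immaterial since the bracket
    vanishes there); the B/R^4 barrier is always on.  The cutoff is applied
    by the caller.
    """
    R = np.asarray(R, dtype=np.float64)
    if np.any(R <= 0):
        raise ValueError("pair distance must be positive")
    shoulder = np.where(R <= R_rep, A * (1.0 + np.cos(np.pi * np.minimum(R, R_rep) / R_rep)), 0.0)
    u = shoulder + B / R**4
    return u if u.ndim else float(u)


def u_att(R, C: float, R_att: float, sigma: float):
    """Gaussian attraction well, kJ/mol (amplitude C/(sigma sqrt(2 pi)))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    R = np.asarray(R, dtype=np.float64)
    u = C / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(-((R - R_att) ** 2) / (2.0 * sigma**2))
    return u if u.ndim else float(u)


# ---------------------------------------------------------------------------
# compiled pair system
# ---------------------------------------------------------------------------

@dataclass
class CompiledSystem:
    """Flat per-pair arrays for fast energy/force evaluation.

    One entry per inter-monomer bead pair.  ``slot`` indexes the unique
    type-pair table; ``slot_theta`` maps each slot to its position in the
    trainable theta vector (-1 when fixed).  ``vbind_mask`` flags the pairs
    that contribute to V_bind (all inter-monomer pairs, or only those
    between a designated monomer pair).
    """

    pi: np.ndarray
    pj: np.ndarray
    qq: np.ndarray  # KE * Q_i * Q_j / eps_r
    A: np.ndarray
    R_rep: np.ndarray
    R_att: np.ndarray
    b_on: np.ndarray  # 1.0 / 0.0 multiplier on the B/R^4 term
    slot: np.ndarray
    vbind_mask: np.ndarray
    slot_keys: list[tuple[str, str]]
    slot_c: np.ndarray
    slot_theta: np.ndarray
    n_theta: int
    sigma: float
    B: float
    kappa_D: float
    cutoff: float
    spring_i: np.ndarray
    spring_j: np.ndarray
    spring_k: np.ndarray
    spring_r0: np.ndarray
    mass: np.ndarray

    def set_theta(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=np.float64)
        if theta.shape != (self.n_theta,):
            raise ValueError(f"theta must have length {self.n_theta}")
        for s in range(self.slot_c.size):
            t = self.slot_theta[s]
            if t >= 0:
                self.slot_c[s] = theta[t]

    def get_theta(self) -> np.ndarray:
        out = np.zeros(self.n_theta)
        for s in range(self.slot_c.size):
            t = self.slot_theta[s]
            if t >= 0:
                out[t] = self.slot_c[s]
        return out


def compile_system(
    topology: CGTopology,
    params: NonbondedParams,
    vbind_pair: tuple[int, int] | None = None,
) -> CompiledSystem:
    """Flatten topology + parameter table into per-pair arrays.

    ``vbind_pair`` designates the monomer pair whose interactions define
    V_bind; ``None`` counts every inter-monomer pair (the standard dimer
    convention).
    """
    n = topology.n_beads
    mono = topology.monomer_id
    ii, jj = np.triu_indices(n, k=1)
    inter = mono[ii] != mono[jj]
    ii, jj = ii[inter], jj[inter]

    theta_keys = params.theta_keys()
    theta_index = {k: t for t, k in enumerate(theta_keys)}

    slot_keys: list[tuple[str, str]] = []
    slot_of: dict[tuple[str, str], int] = {}
    qq = np.empty(ii.size)
    A = np.empty(ii.size)
    R_rep = np.empty(ii.size)
    R_att = np.empty(ii.size)
    b_on = np.empty(ii.size)
    slot = np.empty(ii.size, dtype=np.int64)
    for p, (i, j) in enumerate(zip(ii, jj)):
        key = pair_key(topology.bead_type[i], topology.bead_type[j])
        try:
            entry = params.pairs[key]
        except KeyError:
            raise KeyError(f"no nonbonded parameters for type pair {key}") from None
        if key not in slot_of:
            slot_of[key] = len(slot_keys)
            slot_keys.append(key)
        slot[p] = slot_of[key]
        qq[p] = KE * topology.charge[i] * topology.charge[j] / params.eps_r
        A[p] = entry.A
        R_rep[p] = entry.R_rep
        R_att[p] = entry.R_att
        b_on[p] = 1.0 if entry.b_enabled else 0.0

    slot_c = np.array([params.pairs[k].C for k in slot_keys], dtype=np.float64)
    slot_theta = np.array(
        [theta_index.get(k, -1) for k in slot_keys], dtype=np.int64
    )

    if vbind_pair is None:
        vbind_mask = np.ones(ii.size, dtype=np.bool_)
    else:
        ma, mb = vbind_pair
        vbind_mask = (
            ((mono[ii] == ma) & (mono[jj] == mb))
            | ((mono[ii] == mb) & (mono[jj] == ma))
        )

    return CompiledSystem(
        pi=ii.astype(np.int64),
        pj=jj.astype(np.int64),
        qq=qq,
        A=A,
        R_rep=R_rep,
        R_att=R_att,
        b_on=b_on,
        slot=slot,
        vbind_mask=vbind_mask,
        slot_keys=slot_keys,
        slot_c=slot_c,
        slot_theta=slot_theta,
        n_theta=len(theta_keys),
        sigma=params.sigma,
        B=params.B,
        kappa_D=params.kappa_D,
        cutoff=params.cutoff,
        spring_i=topology.spring_i,
        spring_j=topology.spring_j,
        spring_k=topology.spring_k,
        spring_r0=topology.spring_r0,
        mass=topology.mass.copy(),
    )


# ---------------------------------------------------------------------------
# energies, forces, parameter gradients
# ---------------------------------------------------------------------------

def _pair_distances(coords: np.ndarray, sys: CompiledSystem) -> tuple[np.ndarray, np.ndarray]:
    d = coords[sys.pi] - coords[sys.pj]
    r = np.sqrt(np.sum(d * d, axis=1))
    return d, r


def _check_coords(coords: np.ndarray, sys: CompiledSystem) -> np.ndarray:
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (sys.mass.size, 3):
        raise ValueError(
            f"coords shape {coords.shape} does not match bead count {sys.mass.size}"
        )
    return coords


def total_energy(
    coords: np.ndarray,
    topology: CGTopology,
    params: NonbondedParams,
    vbind_pair: tuple[int, int] | None = None,
    system: CompiledSystem | None = None,
) -> EnergyBreakdown:
    """Potential energy decomposition of one configuration.

    Bonded springs sum over the topology's intra-monomer spring list; the
    nonbonded terms run over inter-monomer bead pairs within the cutoff.
    """
    sys = system if system is not None else compile_system(topology, params, vbind_pair)
    coords = _check_coords(coords, sys)

    u_bond = 0.0
    if sys.spring_i.size:
        d = coords[sys.spring_i] - coords[sys.spring_j]
        r = np.sqrt(np.sum(d * d, axis=1))
        u_bond = float(np.sum(0.5 * sys.spring_k * (r - sys.spring_r0) ** 2))

    _, r = _pair_distances(coords, sys)
    if np.any(r <= 0):
        raise ValueError("overlapping beads (zero pair distance)")
    within = r <= sys.cutoff

    ue_pair = np.where(within, sys.qq / r * np.exp(-sys.kappa_D * r), 0.0)
    shoulder = np.where(
        r <= sys.R_rep, sys.A * (1.0 + np.cos(np.pi * np.minimum(r, sys.R_rep) / sys.R_rep)), 0.0
    )
    ur_pair = np.where(within, shoulder + sys.b_on * sys.B / r**4, 0.0)
    c = sys.slot_c[sys.slot]
    gauss = np.exp(-((r - sys.R_att) ** 2) / (2.0 * sys.sigma**2)) / (
        sys.sigma * np.sqrt(2.0 * np.pi)
    )
    ua_pair = np.where(within, c * gauss, 0.0)

    nb_pair = ue_pair + ur_pair + ua_pair
    return EnergyBreakdown(
        U_bond=u_bond,
        U_elec=float(ue_pair.sum()),
        U_rep=float(ur_pair.sum()),
        U_att=float(ua_pair.sum()),
        V_bind=float(nb_pair[sys.vbind_mask].sum()),
    )


def forces(
    coords: np.ndarray,
    topology: CGTopology,
    params: NonbondedParams,
    system: CompiledSystem | None = None,
) -> np.ndarray:
    """Per-bead forces -dU/dR, kJ mol^-1 nm^-1 (sharply truncated at the cutoff)."""
    sys = system if system is not None else compile_system(topology, params)
    coords = _check_coords(coords, sys)
    f = np.zeros_like(coords)

    if sys.spring_i.size:
        d = coords[sys.spring_i] - coords[sys.spring_j]
        r = np.sqrt(np.sum(d * d, axis=1))
        if np.any(r <= 0):
            raise ValueError("overlapping bonded beads")
        mag = -sys.spring_k * (r - sys.spring_r0) / r  # along d, on bead i
        np.add.at(f, sys.spring_i, mag[:, None] * d)
        np.add.at(f, sys.spring_j, -mag[:, None] * d)

    d, r = _pair_distances(coords, sys)
    if np.any(r <= 0):
        raise ValueError("overlapping beads (zero pair distance)")
    within = r <= sys.cutoff

    # dU/dR per pair
    dudr = sys.qq * np.exp(-sys.kappa_D * r) * (-1.0 / r**2 - sys.kappa_D / r)
    dudr = dudr + np.where(
        r <= sys.R_rep, -sys.A * np.pi / sys.R_rep * np.sin(np.pi * np.minimum(r, sys.R_rep) / sys.R_rep), 0.0
    )
    dudr = dudr - 4.0 * sys.b_on * sys.B / r**5
    c = sys.slot_c[sys.slot]
    gauss = np.exp(-((r - sys.R_att) ** 2) / (2.0 * sys.sigma**2)) / (
        sys.sigma * np.sqrt(2.0 * np.pi)
    )
    dudr = dudr + c * gauss * (-(r - sys.R_att) / sys.sigma**2)
    dudr = np.where(within, dudr, 0.0)

    mag = -dudr / r
    np.add.at(f, sys.pi, mag[:, None] * d)
    np.add.at(f, sys.pj, -mag[:, None] * d)
    return f


def dU_dtheta(
    coords: np.ndarray,
    topology: CGTopology,
    params: NonbondedParams,
    system: CompiledSystem | None = None,
    vbind_only: bool = False,
) -> np.ndarray:
    """Gradient of U with respect to the trainable Gaussian amplitudes C_IJ.

    dU/dC_IJ is the Gaussian factor summed over in-range pairs of that type
    pair; it does not depend on theta itself.  Because the trainable
    parameters are purely inter-molecular, this also equals dV_bind/dC_IJ
    when ``vbind_only`` selects the designated pairs.
    """
    sys = system if system is not None else compile_system(topology, params)
    coords = _check_coords(coords, sys)
    _, r = _pair_distances(coords, sys)
    within = r <= sys.cutoff
    if vbind_only:
        within = within & sys.vbind_mask
    gauss = np.exp(-((r - sys.R_att) ** 2) / (2.0 * sys.sigma**2)) / (
        sys.sigma * np.sqrt(2.0 * np.pi)
    )
    gauss = np.where(within, gauss, 0.0)
    out = np.zeros(sys.n_theta)
    for p in range(sys.slot.size):
        t = sys.slot_theta[sys.slot[p]]
        if t >= 0:
            out[t] += gauss[p]
    return out
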