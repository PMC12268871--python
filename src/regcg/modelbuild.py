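"""Rule-based construction of the fixed nonbonded constants.

Only the Gaussian amplitudes C_IJ are learned; everything else is set once
from the reference data:

* A_IJ (cosine-shoulder amplitude) from the bead charges, in multiples of
  10 kcal/mol — 10 for like-sign pairs, 100 for strongly opposite pairs
  (Q_I Q_J < -1 e^2), with intermediate opposite-sign products interpolated
  and rounded up to the next multiple (a documented convention; the rule
  table only anchors the two extremes).  Multimer mode uses a flat
  25 kcal/mol, a milder repulsion that stabilizes lattice training.
* R_rep (shoulder range) from the pair distance distribution: the largest
  radius still below the first peak at which p(R) <= 0.05 p_max.  Multimer
  mode instead uses half the sum of the two bead-type gyration radii.
* R_att (well center) at the first peak of the distance distribution;
  multimer mode uses the minimum over monomer pairs of the mean
  inter-monomer type-pair distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cgmodel import CGTopology, NonbondedParams, PairEntry, pair_key
from .ensemble import Ensemble
from .simulate import RDFResult, rdf
from .units import KCAL


@dataclass
class PairRuleSet:
    """Constants of the pair-construction rules (energies in kJ/mol)."""

    mode: str = "standard"  # 'standard' | 'multimer'
    a_like: float = 10.0 * KCAL
    a_strong: float = 100.0 * KCAL
    a_multimer: float = 25.0 * KCAL
    a_unit: float = 10.0 * KCAL  # rounding granularity of the interpolation
    rdf_threshold: float = 0.05
    gyration_radii: dict[str, float] = field(default_factory=dict)  # nm, multimer mode

    def __post_init__(self):
        if self.mode not in ("standard", "multimer"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.rdf_threshold < 1.0):
            raise ValueError("rdf threshold must lie in (0, 1)")
        if min(self.a_like, self.a_strong, self.a_multimer) <= 0:
            raise ValueError("A levels must be positive")


def _smooth3(p: np.ndarray) -> np.ndarray:
    """3-bin moving average with edge bins kept as partial averages."""
    out = np.copy(p)
    out[1:-1] = (p[:-2] + p[1:-1] + p[2:]) / 3.0
    out[0] = (p[0] + p[1]) / 2.0
    out[-1] = (p[-2] + p[-1]) / 2.0
    return out


def first_peak_radius(rdf_result: RDFResult, noise_floor: float = 0.1) -> float:
    """Radius of the first local maximum of the smoothed distribution.

    Maxima below ``noise_floor`` times the global maximum are ignored.
    """
    p = _smooth3(rdf_result.p)
    floor = noise_floor * p.max()
    for i in range(1, p.size - 1):
        if p[i] >= p[i - 1] and p[i] > p[i + 1] and p[i] > floor:
            # plateau (e.g. a smoothed single occupied bin): take its center
            left = i
            while left > 0 and p[left - 1] == p[i]:
                left -= 1
            return float(rdf_result.bin_centers[(left + i) // 2])
    raise ValueError("no peak detected in the distance distribution")


def determine_R_rep(rdf_result: RDFResult, ruleset: PairRuleSet | None = None,
                    pair: tuple[str, str] | None = None) -> float:
    """Largest radius below the first peak with p(R) <= threshold * p_max."""
    ruleset = ruleset or PairRuleSet()
    label = f" for pair {pair}" if pair else ""
    peak_r = first_peak_radius(rdf_result)
    p = _smooth3(rdf_result.p)
    thr = ruleset.rdf_threshold * p.max()
    below = rdf_result.bin_centers < peak_r
    ok = below & (p <= thr)
    if not np.any(ok):
        raise ValueError(
            f"no radius below the first peak satisfies the {ruleset.rdf_threshold:g} "
            f"p_max criterion{label}"
        )
    return float(rdf_result.bin_centers[np.flatnonzero(ok)[-1]])


def assign_A(Q_I: float, Q_J: float, ruleset: PairRuleSet | None = None) -> float:
    """Cosine-shoulder amplitude from the bead charges, kJ/mol (symmetric)."""
    ruleset = ruleset or PairRuleSet()
    if not (math.isfinite(Q_I) and math.isfinite(Q_J)):
        raise ValueError("charges must be finite")
    if ruleset.mode == "multimer":
        return ruleset.a_multimer
    prod = Q_I * Q_J
    if prod >= 0.0:
        # sgn(0) counts as matching either sign: weakest repulsion tier
        return ruleset.a_like
    if prod < -1.0:
        return ruleset.a_strong
    # interpolate between the two anchors by |Q_I Q_J|, round up to the grid
    a = ruleset.a_like + (ruleset.a_strong - ruleset.a_like) * (-prod)
    n = a / ruleset.a_unit
    n_up = math.ceil(n - 1e-9)
    return n_up * ruleset.a_unit


def determine_R_att(
    ensemble: Ensemble,
    topology: CGTopology,
    type_i: str,
    type_j: str,
    ruleset: PairRuleSet | None = None,
    bin_width: float = 0.02,
) -> float:
    """Gaussian well center for one type pair, nm.

    Standard mode: first peak of the inter-monomer distance distribution.
    Multimer mode: minimum over monomer pairs of the mean inter-monomer
    type-pair distance.
    """
    ruleset = ruleset or PairRuleSet()
    if ruleset.mode == "standard":
        r = rdf(ensemble, topology, type_i, type_j, bin_width=bin_width)
        return first_peak_radius(r)

    types = np.array(topology.bead_type)
    mono = topology.monomer_id
    ii, jj = np.triu_indices(topology.n_beads, k=1)
    match = (
        ((types[ii] == type_i) & (types[jj] == type_j))
        | ((types[ii] == type_j) & (types[jj] == type_i))
    ) & (mono[ii] != mono[jj])
    ii, jj = ii[match], jj[match]
    if ii.size == 0:
        raise ValueError(f"no inter-monomer pairs of types ({type_i}, {type_j})")
    d = ensemble.coords[:, ii, :] - ensemble.coords[:, jj, :]
    mean_r = ensemble.average(np.sqrt(np.sum(d * d, axis=-1)))
    pairs_mono = np.stack([mono[ii], mono[jj]], axis=1)
    best = np.inf
    for ma, mb in {tuple(sorted(pm)) for pm in pairs_mono}:
        sel = ((mono[ii] == ma) & (mono[jj] == mb)) | (
            (mono[ii] == mb) & (mono[jj] == ma)
        )
        best = min(best, float(mean_r[sel].mean()))
    return best


def build_params(
    topology: CGTopology,
    reference: Ensemble,
    ruleset: PairRuleSet | None = None,
    bin_width: float = 0.02,
    trainable: bool = True,
    **globals_kw,
) -> NonbondedParams:
    """Assemble the full nonbonded table for every inter-monomer type pair.

    Charges per type are taken from the beads of that type (which must
    agree); C starts at zero so early training is driven purely by the
    KL term.  Extra keyword arguments override the global constants
    (sigma, B, eps_r, kappa_D, cutoff).
    """
    ruleset = ruleset or PairRuleSet()
    types = np.array(topology.bead_type)
    mono = topology.monomer_id
    charge_of: dict[str, float] = {}
    for t in np.unique(types):
        qs = topology.charge[types == t]
        if np.ptp(qs) > 1e-9:
            raise ValueError(f"beads of type {t!r} carry inconsistent charges")
        charge_of[str(t)] = float(qs[0])

    ii, jj = np.triu_indices(topology.n_beads, k=1)
    inter = mono[ii] != mono[jj]
    keys = sorted({pair_key(str(types[a]), str(types[b]))
                   for a, b in zip(ii[inter], jj[inter])})
    pairs: dict[tuple[str, str], PairEntry] = {}
    for ti, tj in keys:
        if ruleset.mode == "multimer":
            try:
                r_rep = 0.5 * (ruleset.gyration_radii[ti] + ruleset.gyration_radii[tj])
            except KeyError as err:
                raise KeyError(
                    f"multimer mode needs a gyration radius for type {err.args[0]!r}"
                ) from None
        else:
            r = rdf(reference, topology, ti, tj, bin_width=bin_width)
            r_rep = determine_R_rep(r, ruleset, pair=(ti, tj))
        pairs[(ti, tj)] = PairEntry(
            A=assign_A(charge_of[ti], charge_of[tj], ruleset),
            R_rep=r_rep,
            C=0.0,
            R_att=determine_R_att(reference, topology, ti, tj, ruleset, bin_width),
            trainable=trainable,
        )
    return NonbondedParams(pairs=pairs, **globals_kw)
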