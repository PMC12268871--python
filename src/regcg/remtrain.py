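"""Relative-entropy minimization with a binding-affinity regularizer.

Standard REM descends the Kullback-Leibler divergence D_KL(ref || CG)
between the mapped reference ensemble and the CG model's own Boltzmann
ensemble; in the canonical ensemble its parameter gradient is

    grad L = beta <dU/dtheta>_ref - beta <dU/dtheta>_CG .

Trained on a reference in which a complex never dissociates, plain REM is
agnostic of any lower bound on the binding strength and keeps deepening the
inter-molecular wells (overfitting).  The regularized loss adds a penalty
on the mean inter-molecular binding energy,

    L = D_KL + kappa * (V0 - Vbar_bind)^2 ,

whose gradient follows from differentiating the ensemble average Vbar
under the Boltzmann measure:

    grad [kappa (V0 - Vbar)^2] = -2 kappa (V0 - Vbar) *
        [ <dVbind/dtheta> - beta <Vbind dU/dtheta> + beta <dU/dtheta><Vbind> ] .

All averages here are over the CG ensemble, so the regularizer only
requires recording the binding energy (and the theta-gradient) per sampled
frame.  With kappa = 0 the method reduces exactly to standard REM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cgmodel import (
    CGTopology,
    CompiledSystem,
    NonbondedParams,
    compile_system,
    dU_dtheta,
)
from .ensemble import Ensemble
from .simulate import SimSettings, SimulationUnstableError, rmsd, run
from .units import KCAL, beta


# ---------------------------------------------------------------------------
# configuration and records
# ---------------------------------------------------------------------------

@dataclass
class RegConfig:
    """Settings of one training run.

    ``kappa_reg`` is the regularization strength in (kJ/mol)^-2 (0 recovers
    standard REM), ``V0`` the target mean binding energy in kJ/mol,
    ``gamma`` the learning rate in (kJ mol^-1 nm)^2 per unit gradient.
    ``vbind_pair`` designates the monomer pair whose interactions define
    V_bind and the training gradients (None = all inter-monomer pairs);
    in multimer mode the updated parameters are shared by all monomers
    because they live in the type-pair table.
    """

    V0: float = -25.0
    kappa_reg: float = 0.1 / KCAL
    gamma: float = 1.0
    n_iterations: int = 200
    sim: SimSettings = field(default_factory=SimSettings)
    vbind_pair: tuple[int, int] | None = None
    max_step: float = 1.0  # largest |delta theta| per iteration, kJ mol^-1 nm
    seed: int = 0
    early_stop_tol: float | None = None
    early_stop_window: int = 20
    unbound_threshold: float = -1.0  # frames with V_bind above this count as unbound

    def __post_init__(self):
        if self.kappa_reg < 0:
            raise ValueError("kappa_reg must be non-negative")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class TrainRecord:
    """Per-iteration snapshot of the training state."""

    iteration: int
    theta: np.ndarray
    v_bind_mean: float
    rmsd_mean: float
    grad_kl: np.ndarray
    grad_reg: np.ndarray
    unbound_fraction: float


@dataclass
class TrainResult:
    records: list[TrainRecord]
    params: NonbondedParams
    theta_keys: list[tuple[str, str]]
    aborted: bool = False

    def theta_history(self) -> np.ndarray:
        return np.array([r.theta for r in self.records])

    def vbind_history(self) -> np.ndarray:
        return np.array([r.v_bind_mean for r in self.records])

    def rmsd_history(self) -> np.ndarray:
        return np.array([r.rmsd_mean for r in self.records])

    def final_window_theta(self, window: int = 20) -> np.ndarray:
        """Mean theta over the final iterations (suppresses sampling noise)."""
        return self.theta_history()[-window:].mean(axis=0)

    def final_window_vbind(self, window: int = 20) -> float:
        return float(self.vbind_history()[-window:].mean())


# ---------------------------------------------------------------------------
# gradient estimators
# ---------------------------------------------------------------------------

def _mean_du_dtheta(
    ensemble: Ensemble,
    topology: CGTopology,
    params: NonbondedParams,
    vbind_pair: tuple[int, int] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame and ensemble-mean dU/dtheta, computed if not recorded.

    For the Gaussian amplitudes dU/dC does not depend on theta, so values
    recorded during sampling remain valid for any current theta.
    """
    if ensemble.du_dtheta is not None:
        per_frame = ensemble.du_dtheta
    else:
        sys = compile_system(topology, params, vbind_pair)
        per_frame = np.array(
            [
                dU_dtheta(ensemble.coords[k], topology, params, system=sys, vbind_only=True)
                for k in range(ensemble.n_frames)
            ]
        )
    return per_frame, ensemble.average(per_frame)


def kl_gradient(
    aa_ensemble: Ensemble,
    cg_ensemble: Ensemble,
    topology: CGTopology,
    params: NonbondedParams,
    temperature: float,
    vbind_pair: tuple[int, int] | None = None,
) -> np.ndarray:
    """Gradient of D_KL(ref || CG) with respect to the trainable amplitudes."""
    b = beta(temperature)
    _, g_aa = _mean_du_dtheta(aa_ensemble, topology, params, vbind_pair)
    _, g_cg = _mean_du_dtheta(cg_ensemble, topology, params, vbind_pair)
    return b * (g_aa - g_cg)


def grad_mean_vbind(cg_ensemble: Ensemble, temperature: float) -> np.ndarray:
    """Covariance-form estimator of d<V_bind>/dtheta over the CG ensemble.

    Requires per-frame V_bind and dU/dtheta records (the sampler provides
    both).  Because the trainable parameters are purely inter-molecular,
    <dV_bind/dtheta> coincides with the recorded <dU/dtheta>.
    """
    if cg_ensemble.v_bind is None or cg_ensemble.du_dtheta is None:
        raise ValueError("ensemble lacks per-frame V_bind / dU_dtheta records")
    b = beta(temperature)
    g = cg_ensemble.du_dtheta
    v = cg_ensemble.v_bind
    g_mean = cg_ensemble.average(g)
    v_mean = float(cg_ensemble.average(v))
    vg_mean = cg_ensemble.average(v[:, None] * g)
    return g_mean - b * vg_mean + b * g_mean * v_mean


def regrem_gradient(
    aa_ensemble: Ensemble,
    cg_ensemble: Ensemble,
    topology: CGTopology,
    params: NonbondedParams,
    config: RegConfig,
    temperature: float | None = None,
) -> np.ndarray:
    """Full regularized gradient; identical to ``kl_gradient`` at kappa_reg = 0."""
    T = config.sim.temperature if temperature is None else temperature
    kl = kl_gradient(
        aa_ensemble, cg_ensemble, topology, params, T, config.vbind_pair
    )
    if config.kappa_reg == 0.0:
        return kl
    v_mean = float(cg_ensemble.average(cg_ensemble.v_bind))
    gmv = grad_mean_vbind(cg_ensemble, T)
    return kl - 2.0 * config.kappa_reg * (config.V0 - v_mean) * gmv


def kappa_heuristic(mean_grad_vbind: float, temperature: float) -> float:
    """Rule-of-thumb regularization strength, (kJ/mol)^-2.

    Balances a D_KL gradient of 0.5 beta nm^-1 against the regularization
    gradient produced by a 1 kcal/mol error in the mean binding energy:
    0.5 beta = 2 kappa * (1 kcal/mol) * <dV_bind/dtheta>, i.e.
    kappa = 0.25 beta / (4.184 * <dV_bind/dtheta>).
    """
    if mean_grad_vbind <= 0:
        raise ValueError("mean gradient scale must be positive")
    return 0.25 * beta(temperature) / (KCAL * mean_grad_vbind)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(
    topology: CGTopology,
    params: NonbondedParams,
    aa_ensemble: Ensemble,
    config: RegConfig,
    native: np.ndarray | None = None,
    callback=None,
) -> TrainResult:
    """Iterative (reg-)REM training of the Gaussian amplitudes.

    Each iteration samples a fresh CG trajectory from the native reference
    structure, estimates the gradient from the recorded observables, and
    takes a plain gradient-descent step (the update vector is rescaled when
    its largest component exceeds ``config.max_step``).  Returns the full
    per-iteration history; if a simulation blows up the learning rate is
    halved and the iteration retried once, after which the run aborts with
    the history collected so far.
    """
    params = params.copy()
    T = config.sim.temperature
    sys = compile_system(topology, params, config.vbind_pair)
    if sys.n_theta == 0:
        raise ValueError("no trainable parameters (set trainable=True on type pairs)")
    if native is None:
        native = aa_ensemble.coords[0]

    # dU/dC is theta-independent, so the reference-side average is fixed
    _, g_aa = _mean_du_dtheta(aa_ensemble, topology, params, config.vbind_pair)

    b = beta(T)
    theta = sys.get_theta()
    gamma = config.gamma
    records: list[TrainRecord] = []
    aborted = False
    streak = 0

    for it in range(config.n_iterations):
        sys.set_theta(theta)
        sim = replace(config.sim, seed=(config.seed + 7919 * it) % 2**31)
        try:
            ens = run(topology, params, native, sim, config.vbind_pair, system=sys)
        except SimulationUnstableError:
            gamma *= 0.5
            try:
                ens = run(topology, params, native, sim, config.vbind_pair, system=sys)
            except SimulationUnstableError:
                aborted = True
                break

        g_cg = ens.average(ens.du_dtheta)
        kl = b * (g_aa - g_cg)
        v_mean = float(ens.average(ens.v_bind))
        if config.kappa_reg > 0.0:
            gmv = grad_mean_vbind(ens, T)
            greg = -2.0 * config.kappa_reg * (config.V0 - v_mean) * gmv
        else:
            greg = np.zeros_like(kl)
        grad = kl + greg

        rec = TrainRecord(
            iteration=it,
            theta=theta.copy(),
            v_bind_mean=v_mean,
            rmsd_mean=float(rmsd(ens, native).mean()),
            grad_kl=kl,
            grad_reg=greg,
            unbound_fraction=float(
                np.mean(ens.v_bind > config.unbound_threshold)
            ),
        )
        records.append(rec)
        if callback is not None:
            callback(rec)

        step = -gamma * grad
        biggest = np.abs(step).max()
        if biggest > config.max_step:
            step *= config.max_step / biggest
        theta = theta + step

        if config.early_stop_tol is not None:
            streak = streak + 1 if abs(v_mean - config.V0) < config.early_stop_tol else 0
            if streak >= config.early_stop_window:
                break

    # leave params at the last sampled theta
    final_theta = records[-1].theta if records else theta
    params.set_theta(final_theta)
    return TrainResult(
        records=records,
        params=params,
        theta_keys=params.theta_keys(),
        aborted=aborted,
    )
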