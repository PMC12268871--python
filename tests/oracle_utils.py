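"""Independent quadrature oracles for the two-bead gradient checks.

The potential here is written out inline so oracle values never flow
through the package's energy code; the package only supplies the ensembles
whose estimators are being checked.
"""

import numpy as np
from scipy.integrate import simpson

from regcg.cgmodel import dU_dtheta, total_energy
from regcg.ensemble import Ensemble
from regcg.units import KB, KE

T = 310.0
BETA = 1.0 / (KB * T)
R_LO, R_HI, N_GRID = 0.2, 5.0, 2400
C_STAR = -8.0  # generating amplitude (reference side)
C_CUR = -5.0  # current model amplitude (evaluation point)


def oracle_u(R, C):
    """Inline pair potential: screened Coulomb + cosine shoulder + B/R^4 + well."""
    R = np.asarray(R, dtype=float)
    qq = KE * (1.0 * -1.0) / 17.5
    u = qq / R * np.exp(-1.274 * R)
    u = u + np.where(
        R <= 0.7, 41.84 * (1 + np.cos(np.pi * np.minimum(R, 0.7) / 0.7)), 0.0
    )
    u = u + 0.0025104 / R**4
    u = u + C / (0.2 * np.sqrt(2 * np.pi)) * np.exp(-((R - 1.0) ** 2) / (2 * 0.2**2))
    return u


def measure(R, dims):
    return np.ones_like(R) if dims == 1 else R**2


def oracle_mean_vbind(C, dims=1, n=12001):
    R = np.linspace(R_LO, R_HI, n)
    w = measure(R, dims) * np.exp(-BETA * oracle_u(R, C))
    return simpson(w * oracle_u(R, C), x=R) / simpson(w, x=R)


def oracle_dkl(C_aa, C_cg, dims=1, n=12001):
    R = np.linspace(R_LO, R_HI, n)
    wa = measure(R, dims) * np.exp(-BETA * oracle_u(R, C_aa))
    wc = measure(R, dims) * np.exp(-BETA * oracle_u(R, C_cg))
    pa = wa / simpson(wa, x=R)
    pc = wc / simpson(wc, x=R)
    return simpson(pa * np.log(pa / pc), x=R)


def grid_ensemble(C, topo, params, dims=1):
    """Dense weighted ensemble standing in for perfectly sampled frames."""
    R = np.linspace(R_LO, R_HI, N_GRID)
    coords = np.zeros((N_GRID, 2, 3))
    coords[:, 1, 0] = R
    w = measure(R, dims) * np.exp(-BETA * oracle_u(R, C))
    v = np.empty(N_GRID)
    g = np.empty((N_GRID, 1))
    for k in range(N_GRID):
        v[k] = total_energy(coords[k], topo, params).V_bind
        g[k] = dU_dtheta(coords[k], topo, params)
    return Ensemble(coords=coords, weights=w, v_bind=v, du_dtheta=g)


def make_oracle_system(dims=1):
    """Two-bead toy + reference/current grid ensembles."""
    from conftest import two_bead_system

    topo, params_cg = two_bead_system(C=C_CUR, R_rep=0.7, R_att=1.0)
    params_cg.cutoff = 5.0
    params_aa = params_cg.copy()
    params_aa.set_theta(np.array([C_STAR]))
    aa = grid_ensemble(C_STAR, topo, params_aa, dims)
    cg = grid_ensemble(C_CUR, topo, params_cg, dims)
    return topo, params_cg, aa, cg
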