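"""Numba-compiled inner loops for energy/force evaluation and Langevin dynamics.

These kernels duplicate the pair math of :mod:`regcg.cgmodel` in flat-array
form for speed; an internal consistency test pins them against the numpy
reference implementation.  Systems here are small (tens of beads), so the
pair loop runs over a precomputed all-pairs list; no neighbor list is built.
"""

import numba
import numpy as np

SQRT2PI = np.sqrt(2.0 * np.pi)


@numba.njit(cache=True)
def pair_forces_energy(
    x,
    pi, pj, qq, A, R_rep, R_att, b_on, slot, slot_c, slot_theta, vmask,
    sigma, B, kappa, cutoff,
    si, sj, sk, sr0,
    f, g,
):
    """Fill forces ``f`` and masked parameter gradient ``g``; return energy terms.

    Returns (U_bond, U_elec, U_rep, U_att, V_bind).  ``g`` accumulates the
    Gaussian factor dU/dC per trainable slot over pairs flagged by ``vmask``.
    """
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    for t in range(g.shape[0]):
        g[t] = 0.0

    u_bond = 0.0
    for s in range(si.shape[0]):
        a = si[s]
        b = sj[s]
        dx = x[a, 0] - x[b, 0]
        dy = x[a, 1] - x[b, 1]
        dz = x[a, 2] - x[b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u_bond += 0.5 * sk[s] * (r - sr0[s]) ** 2
        mag = -sk[s] * (r - sr0[s]) / r
        f[a, 0] += mag * dx
        f[a, 1] += mag * dy
        f[a, 2] += mag * dz
        f[b, 0] -= mag * dx
        f[b, 1] -= mag * dy
        f[b, 2] -= mag * dz

    u_elec = 0.0
    u_rep = 0.0
    u_att = 0.0
    v_bind = 0.0
    inv_s2 = 1.0 / (sigma * sigma)
    gnorm = 1.0 / (sigma * SQRT2PI)
    for p in range(pi.shape[0]):
        a = pi[p]
        b = pj[p]
        dx = x[a, 0] - x[b, 0]
        dy = x[a, 1] - x[b, 1]
        dz = x[a, 2] - x[b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > cutoff:
            continue
        ue = qq[p] / r * np.exp(-kappa * r)
        dudr = qq[p] * np.exp(-kappa * r) * (-1.0 / (r * r) - kappa / r)
        ur = b_on[p] * B / r**4
        dudr += -4.0 * b_on[p] * B / r**5
        if r <= R_rep[p]:
            ur += A[p] * (1.0 + np.cos(np.pi * r / R_rep[p]))
            dudr += -A[p] * np.pi / R_rep[p] * np.sin(np.pi * r / R_rep[p])
        dr = r - R_att[p]
        gauss = gnorm * np.exp(-0.5 * dr * dr * inv_s2)
        c = slot_c[slot[p]]
        ua = c * gauss
        dudr += -c * gauss * dr * inv_s2
        u_elec += ue
        u_rep += ur
        u_att += ua
        if vmask[p]:
            v_bind += ue + ur + ua
            t = slot_theta[slot[p]]
            if t >= 0:
                g[t] += gauss
        mag = -dudr / r
        f[a, 0] += mag * dx
        f[a, 1] += mag * dy
        f[a, 2] += mag * dz
        f[b, 0] -= mag * dx
        f[b, 1] -= mag * dy
        f[b, 2] -= mag * dz

    return u_bond, u_elec, u_rep, u_att, v_bind


@numba.njit(cache=True)
def integrate(
    x0, v0, mass,
    dt, n_steps, stride, kT, friction, seed, wall_radius,
    pi, pj, qq, A, R_rep, R_att, b_on, slot, slot_c, slot_theta, vmask,
    sigma, B, kappa, cutoff,
    si, sj, sk, sr0,
    frames, energies, grads,
):
    """BAOAB Langevin integration with periodic recording.

    ``frames`` (n_rec, n, 3) receives coordinates every ``stride`` steps;
    ``energies`` (n_rec, 7) the columns (step, U_bond, U_elec, U_rep, U_att,
    V_bind, E_kin); ``grads`` (n_rec, n_theta) the masked dU/dC.  A
    reflecting spherical wall of radius ``wall_radius`` about the origin is
    applied when the radius is positive.  Returns the index of the first
    frame with a non-finite energy, or -1 on success.
    """
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    v = v0.copy()
    f = np.zeros((n, 3))
    n_theta = grads.shape[1]
    gbuf = np.zeros(n_theta if n_theta > 0 else 1)

    c1 = np.exp(-friction * dt)
    # per-bead OU noise amplitude
    noise = np.empty(n)
    for i in range(n):
        noise[i] = np.sqrt(kT / mass[i] * (1.0 - c1 * c1))

    eb = pair_forces_energy(
        x, pi, pj, qq, A, R_rep, R_att, b_on, slot, slot_c, slot_theta, vmask,
        sigma, B, kappa, cutoff, si, sj, sk, sr0, f, gbuf,
    )

    half = 0.5 * dt
    rec = 0
    for step in range(1, n_steps + 1):
        for i in range(n):
            inv_m = 1.0 / mass[i]
            v[i, 0] += half * f[i, 0] * inv_m
            v[i, 1] += half * f[i, 1] * inv_m
            v[i, 2] += half * f[i, 2] * inv_m
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        if friction > 0.0:
            for i in range(n):
                v[i, 0] = c1 * v[i, 0] + noise[i] * np.random.normal()
                v[i, 1] = c1 * v[i, 1] + noise[i] * np.random.normal()
                v[i, 2] = c1 * v[i, 2] + noise[i] * np.random.normal()
        for i in range(n):
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        if wall_radius > 0.0:
            for i in range(n):
                rr = np.sqrt(x[i, 0] ** 2 + x[i, 1] ** 2 + x[i, 2] ** 2)
                if rr > wall_radius:
                    # fold the radius back inside and reverse the radial velocity
                    scale = (2.0 * wall_radius - rr) / rr
                    if scale < 0.1:
                        scale = 0.1
                    nx = x[i, 0] / rr
                    ny = x[i, 1] / rr
                    nz = x[i, 2] / rr
                    x[i, 0] *= scale
                    x[i, 1] *= scale
                    x[i, 2] *= scale
                    vr = v[i, 0] * nx + v[i, 1] * ny + v[i, 2] * nz
                    if vr > 0.0:
                        v[i, 0] -= 2.0 * vr * nx
                        v[i, 1] -= 2.0 * vr * ny
                        v[i, 2] -= 2.0 * vr * nz
        eb = pair_forces_energy(
            x, pi, pj, qq, A, R_rep, R_att, b_on, slot, slot_c, slot_theta, vmask,
            sigma, B, kappa, cutoff, si, sj, sk, sr0, f, gbuf,
        )
        for i in range(n):
            inv_m = 1.0 / mass[i]
            v[i, 0] += half * f[i, 0] * inv_m
            v[i, 1] += half * f[i, 1] * inv_m
            v[i, 2] += half * f[i, 2] * inv_m

        if step % stride == 0:
            ekin = 0.0
            for i in range(n):
                ekin += 0.5 * mass[i] * (
                    v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
                )
            u_total = eb[0] + eb[1] + eb[2] + eb[3]
            if not np.isfinite(u_total):
                return rec
            for i in range(n):
                frames[rec, i, 0] = x[i, 0]
                frames[rec, i, 1] = x[i, 1]
                frames[rec, i, 2] = x[i, 2]
            energies[rec, 0] = step
            energies[rec, 1] = eb[0]
            energies[rec, 2] = eb[1]
            energies[rec, 3] = eb[2]
            energies[rec, 4] = eb[3]
            energies[rec, 5] = eb[4]
            energies[rec, 6] = ekin
            for t in range(n_theta):
                grads[rec, t] = gbuf[t]
            rec += 1
    return -1
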