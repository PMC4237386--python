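"""Compiled inner loops for the two Lagrangian wavecodes.

Both kernels implement the classic staggered-grid von Neumann-Richtmyer
scheme: node velocities and positions leapfrogged against cell-centred
states, quadratic + linear artificial viscosity at compressions, and an
implicit trapezoidal internal-energy update (both gas EOS are linear in
the specific internal energy, so the update is closed-form).

Kernels return an error code instead of raising so the Python wrappers
can attach time/cell context:

* 0 — completed
* 1 — cell inversion
* 2 — non-finite state
* 3 — time-step collapse
* 4 — step budget exhausted
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# volumetric-law tags for the tissue column
VOL_LINEAR = 0  # P = K * mu
VOL_SHOCK = 1  # linear U_s-U_p Hugoniot


@njit(cache=True)
def _jwl_cold(A, B, R1, R2, omega, v):
    return A * (1.0 - omega / (R1 * v)) * math.exp(-R1 * v) + B * (
        1.0 - omega / (R2 * v)
    ) * math.exp(-R2 * v)


@njit(cache=True)
def _jwl_cold_dpdv(A, B, R1, R2, omega, v):
    t1 = A * math.exp(-R1 * v) * (omega / (R1 * v * v) - R1 * (1.0 - omega / (R1 * v)))
    t2 = B * math.exp(-R2 * v) * (omega / (R2 * v * v) - R2 * (1.0 - omega / (R2 * v)))
    return t1 + t2


@njit(cache=True)
def run_spherical(
    r,
    u,
    m,
    e,
    n_prod,
    gamma,
    p0,
    e_floor,
    A,
    B,
    R1,
    R2,
    omega,
    rho0_tnt,
    q_quad,
    q_lin,
    cfl,
    end_time,
    gauge_r,
    r_fine_end,
    max_steps,
):
    """Spherical blast kernel.  Mutates r, u, e in place.

    Returns (nsteps, times, gauge_p, max_drift, err_code, err_cell, err_t).
    """
    n = m.size
    four_pi = 4.0 * math.pi

    rho = np.empty(n)
    p = np.empty(n)
    q = np.zeros(n)
    c = np.empty(n)
    m_node = np.empty(n + 1)
    m_node[0] = 0.5 * m[0]
    m_node[n] = 0.5 * m[n - 1]
    for i in range(1, n):
        m_node[i] = 0.5 * (m[i - 1] + m[i])

    for j in range(n):
        vol = (four_pi / 3.0) * (r[j + 1] ** 3 - r[j] ** 3)
        rho[j] = m[j] / vol

    # initial pressures
    for j in range(n):
        if j < n_prod:
            v = rho0_tnt / rho[j]
            p[j] = _jwl_cold(A, B, R1, R2, omega, v) + omega * rho[j] * e[j]
        else:
            p[j] = (gamma - 1.0) * rho[j] * e[j]

    e_tot0 = 0.0
    for j in range(n):
        e_tot0 += m[j] * e[j]
    bwork = 0.0
    max_drift = 0.0

    times = np.empty(max_steps + 1)
    gauge_p = np.empty(max_steps + 1)
    times[0] = 0.0

    # gauge cell hint
    jg = 0
    while jg < n - 1 and 0.5 * (r[jg] + r[jg + 1]) < gauge_r:
        jg += 1
    gauge_p[0] = p0

    t = 0.0
    dt = 1.0e-9
    k = 0
    while t < end_time:
        if k >= max_steps:
            return k, times, gauge_p, max_drift, 4, -1, t
        # sound speed, viscosity, CFL
        dt_cfl = 1.0e30
        for j in range(n):
            if j < n_prod:
                v = rho0_tnt / rho[j]
                dfdv = _jwl_cold_dpdv(A, B, R1, R2, omega, v)
                c2 = -dfdv * rho0_tnt / (rho[j] * rho[j]) + omega * e[j] + omega * p[j] / rho[j]
            else:
                c2 = gamma * p[j] / rho[j]
            if c2 < 100.0:
                c2 = 100.0
            c[j] = math.sqrt(c2)
            du = u[j + 1] - u[j]
            if du < 0.0:
                q[j] = q_quad * rho[j] * du * du + q_lin * rho[j] * c[j] * (-du)
            else:
                q[j] = 0.0
            dr = r[j + 1] - r[j]
            denom = c[j] + 2.0 * abs(du) + 1.0e-30
            cand = dr / denom
            if cand < dt_cfl:
                dt_cfl = cand
        dt_new = cfl * dt_cfl
        if dt_new > 1.1 * dt:
            dt_new = 1.1 * dt
        if dt_new > end_time - t:
            dt_new = end_time - t
        dt = dt_new
        if dt <= 0.0 or not math.isfinite(dt):
            return k, times, gauge_p, max_drift, 3, -1, t

        # momentum
        for i in range(1, n):
            area = four_pi * r[i] * r[i]
            u[i] -= dt * area * ((p[i] + q[i]) - (p[i - 1] + q[i - 1])) / m_node[i]
        area_out = four_pi * r[n] * r[n]
        u[n] -= dt * area_out * (p0 - (p[n - 1] + q[n - 1])) / m_node[n]
        u[0] = 0.0

        # positions
        prev = 0.0
        for i in range(n + 1):
            r[i] += u[i] * dt
            if i > 0 and r[i] <= prev:
                return k, times, gauge_p, max_drift, 1, i - 1, t
            prev = r[i]

        # energy update (implicit trapezoid) and new pressure
        for j in range(n):
            vol = (four_pi / 3.0) * (r[j + 1] ** 3 - r[j] ** 3)
            rho_new = m[j] / vol
            dv = 1.0 / rho_new - 1.0 / rho[j]
            if j < n_prod:
                v = rho0_tnt / rho_new
                f_cold = _jwl_cold(A, B, R1, R2, omega, v)
                e_new = (e[j] - (0.5 * (p[j] + f_cold) + q[j]) * dv) / (
                    1.0 + 0.5 * omega * rho_new * dv
                )
                if e_new < e_floor:
                    e_new = e_floor
                p_new = f_cold + omega * rho_new * e_new
            else:
                e_new = (e[j] - (0.5 * p[j] + q[j]) * dv) / (
                    1.0 + 0.5 * (gamma - 1.0) * rho_new * dv
                )
                if e_new < e_floor:
                    e_new = e_floor
                p_new = (gamma - 1.0) * rho_new * e_new
            if not math.isfinite(p_new):
                return k, times, gauge_p, max_drift, 2, j, t
            rho[j] = rho_new
            e[j] = e_new
            p[j] = p_new

        bwork -= p0 * (four_pi * r[n] * r[n]) * u[n] * dt
        t += dt
        k += 1

        # gauge: track the bracketing cell-centre pair, linear interp
        while jg > 0 and 0.5 * (r[jg] + r[jg + 1]) > gauge_r:
            jg -= 1
        while jg < n - 2 and 0.5 * (r[jg + 1] + r[jg + 2]) < gauge_r:
            jg += 1
        rc0 = 0.5 * (r[jg] + r[jg + 1])
        rc1 = 0.5 * (r[jg + 1] + r[jg + 2]) if jg + 2 <= n else rc0
        if rc1 > rc0 and gauge_r >= rc0:
            w = (gauge_r - rc0) / (rc1 - rc0)
            if w > 1.0:
                w = 1.0
            gp = (1.0 - w) * p[jg] + w * p[jg + 1]
        else:
            gp = p[jg]
        times[k] = t
        gauge_p[k] = gp

        if k % 25 == 0:
            ke = 0.0
            for i in range(n + 1):
                ke += 0.5 * m_node[i] * u[i] * u[i]
            ie = 0.0
            for j in range(n):
                ie += m[j] * e[j]
            drift = abs(ie + ke - e_tot0 - bwork) / e_tot0
            # meaningful while the shocked region is inside the fine grid
            front = 0.0
            for j in range(n - 1, -1, -1):
                if p[j] > 1.02 * p0:
                    front = 0.5 * (r[j] + r[j + 1])
                    break
            if front < r_fine_end and drift > max_drift:
                max_drift = drift

    return k, times, gauge_p, max_drift, 0, -1, t


@njit(cache=True)
def run_column(
    x,
    u,
    m,
    vol_law,
    k_bulk,
    s_slope,
    rho0c,
    g0,
    ginf,
    beta,
    load_t,
    load_p,
    z_right,
    q_quad,
    q_lin,
    cfl,
    end_time,
    gauge_cells,
    max_steps,
):
    """Planar uniaxial-strain tissue-column kernel.  Mutates x, u in place.

    Deviatoric response: single-term viscoelastic hereditary integral in
    recursive exponential-integrator form (exact for piecewise-linear
    strain histories); elastic materials are the degenerate case
    ``G0 == Ginf``.  Returns per-step gauge pressure / von Mises records,
    a mechanical-energy history and the worst momentum-balance residual.
    """
    n = m.size
    n_g = gauge_cells.size

    rho = np.empty(n)
    p = np.empty(n)
    q = np.zeros(n)
    s_eq = np.zeros(n)  # equilibrium (long-term) deviatoric axial stress
    h = np.zeros(n)  # transient Maxwell-branch deviatoric stress
    c0 = np.empty(n)
    dx0 = np.empty(n)

    m_node = np.empty(n + 1)
    m_node[0] = 0.5 * m[0]
    m_node[n] = 0.5 * m[n - 1]
    for i in range(1, n):
        m_node[i] = 0.5 * (m[i - 1] + m[i])

    for j in range(n):
        dx0[j] = x[j + 1] - x[j]
        rho[j] = m[j] / dx0[j]
        p[j] = 0.0
        c0[j] = math.sqrt((k_bulk[j] + 4.0 * g0[j] / 3.0) / rho0c[j])

    times = np.empty(max_steps + 1)
    g_press = np.empty((max_steps + 1, n_g))
    g_vm = np.empty((max_steps + 1, n_g))
    energy = np.empty(max_steps + 1)
    times[0] = 0.0
    for g in range(n_g):
        g_press[0, g] = 0.0
        g_vm[0, g] = 0.0
    energy[0] = 0.0

    max_mom_resid = 0.0
    t = 0.0
    dt = 1.0e-9
    k = 0
    while t < end_time:
        if k >= max_steps:
            return k, times, g_press, g_vm, energy, max_mom_resid, 4, -1, t, rho, p, s_eq, h

        dt_cfl = 1.0e30
        for j in range(n):
            du = u[j + 1] - u[j]
            if du < 0.0:
                q[j] = q_quad * rho[j] * du * du + q_lin * rho[j] * c0[j] * (-du)
            else:
                q[j] = 0.0
            cand = (x[j + 1] - x[j]) / (c0[j] + 2.0 * abs(du) + 1.0e-30)
            if cand < dt_cfl:
                dt_cfl = cand
        dt_new = cfl * dt_cfl
        if dt_new > 1.1 * dt:
            dt_new = 1.1 * dt
        if dt_new > end_time - t:
            dt_new = end_time - t
        dt = dt_new
        if dt <= 0.0 or not math.isfinite(dt):
            return k, times, g_press, g_vm, energy, max_mom_resid, 3, -1, t, rho, p, s_eq, h

        # total axial stress per cell (tension positive)
        # sigma = -(P + q) + s,  s = s_eq + h
        load = np.interp(t, load_t, load_p)
        sig_left = -load  # applied traction on the loaded face
        sig_right = -z_right * u[n]  # absorbing impedance at the distal face

        mom_before = 0.0
        for i in range(n + 1):
            mom_before += m_node[i] * u[i]

        for i in range(n + 1):
            if i == 0:
                sig_m = sig_left
            else:
                sig_m = -(p[i - 1] + q[i - 1]) + s_eq[i - 1] + h[i - 1]
            if i == n:
                sig_p = sig_right
            else:
                sig_p = -(p[i] + q[i]) + s_eq[i] + h[i]
            u[i] += dt * (sig_p - sig_m) / m_node[i]

        mom_after = 0.0
        for i in range(n + 1):
            mom_after += m_node[i] * u[i]
        impulse = dt * (sig_right - sig_left)
        scale = abs(impulse) + abs(mom_after) + 1.0e-30
        resid = abs(mom_after - mom_before - impulse) / scale
        if resid > max_mom_resid:
            max_mom_resid = resid

        prev = x[0] + u[0] * dt
        x[0] = prev
        for i in range(1, n + 1):
            x[i] += u[i] * dt
            if x[i] <= prev:
                return k, times, g_press, g_vm, energy, max_mom_resid, 1, i - 1, t, rho, p, s_eq, h
            prev = x[i]

        ke = 0.0
        for i in range(n + 1):
            ke += 0.5 * m_node[i] * u[i] * u[i]
        pe = 0.0

        for j in range(n):
            dx = x[j + 1] - x[j]
            rho_new = m[j] / dx
            mu = rho_new / rho0c[j] - 1.0
            if vol_law[j] == VOL_SHOCK:
                if mu >= 0.0:
                    denom = 1.0 - (s_slope[j] - 1.0) * mu
                    if denom <= 1.0e-6:
                        return k, times, g_press, g_vm, energy, max_mom_resid, 2, j, t, rho, p, s_eq, h
                    p_new = k_bulk[j] * mu * (1.0 + mu) / (denom * denom)
                else:
                    p_new = k_bulk[j] * mu
            else:
                p_new = k_bulk[j] * mu
            # deviatoric update: axial deviatoric strain rate = (2/3) deps
            deps = (u[j + 1] - u[j]) * dt / dx
            s_eq[j] += (4.0 / 3.0) * ginf[j] * deps
            dg = g0[j] - ginf[j]
            if dg > 0.0:
                a = beta[j] * dt
                decay = math.exp(-a)
                fac = (1.0 - decay) / a if a > 1.0e-8 else 1.0 - 0.5 * a
                h[j] = decay * h[j] + (4.0 / 3.0) * dg * fac * deps
            if not math.isfinite(p_new):
                return k, times, g_press, g_vm, energy, max_mom_resid, 2, j, t, rho, p, s_eq, h
            rho[j] = rho_new
            p[j] = p_new
            # quadratic stored-energy estimate (diagnostic only)
            pe_j = 0.5 * k_bulk[j] * mu * mu
            pe_j += 3.0 * s_eq[j] * s_eq[j] / (8.0 * ginf[j])
            if dg > 0.0:
                pe_j += 3.0 * h[j] * h[j] / (8.0 * dg)
            pe += pe_j * dx0[j]

        t += dt
        k += 1
        times[k] = t
        energy[k] = ke + pe
        for g in range(n_g):
            j = gauge_cells[g]
            g_press[k, g] = p[j]
            g_vm[k, g] = 1.5 * abs(s_eq[j] + h[j])

    return k, times, g_press, g_vm, energy, max_mom_resid, 0, -1, t, rho, p, s_eq, h
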