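"""Compiled inner loop of the cable integrator.

Theta-implicit voltage update (tridiagonal Thomas solve over
compartments, theta = 0.5 giving a trapezoidal / Crank-Nicolson-style
rule) with exponential-Euler gate updates drawn from precomputed lookup
tables of x_inf(V) and exp(-dt/tau(V)).  Each step runs a predictor and
one corrector pass: the corrector re-advances the gates with the
midpoint voltage (V(t) + V_pred)/2, which restores second-order
accuracy for the stiff Na+ activation gate whose time constant is
comparable to the step size during the upstroke.

The pump current and the Na+ Nernst potential are refreshed on a
coarser cadence (they ride on the slow [Na+]_in variable), while
[Na+]_in itself is advanced every step from the instantaneous Na+
current.

Everything here is private; :mod:`axodelay.cable_sim` is the public face.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# pump modes
PUMP_NONE = 0
PUMP_DYNAMIC = 1
PUMP_CONST = 2

# kernel status codes
OK = 0
BLOWUP = 1


@njit(cache=True, fastmath=True)
def _interp_table(tab, row, v, v0, inv_dv, nv):
    """Linear interpolation of table row at voltage v (clamped to grid)."""
    x = (v - v0) * inv_dv
    if x < 0.0:
        x = 0.0
    elif x > nv - 1.000001:
        x = nv - 1.000001
    i = int(x)
    f = x - i
    return tab[row, i] * (1.0 - f) + tab[row, i + 1] * f


@njit(cache=True, fastmath=True)
def integrate_steps(
    n_steps,
    dt,
    # state (modified in place)
    v, gates, na, ena, ipump,
    # gate tables: xinf_tab[ngate, nv], decay_tab[ngate, nv]
    xinf_tab, decay_tab, tab_v0, tab_inv_dv,
    # channel metadata
    ch_gbar, ch_e, ch_p, ch_q, ch_mi, ch_hi, na_ch,
    # pump / sodium
    pump_mode, pump_imax, pump_na_half, pump_na_s, pump_const,
    na_dynamic, na_out, na_rate_den, nernst_slope,
    # cable
    cdt, gax, theta, n_pass,
    # stimulus: step indices of pulse starts/ends (sorted), density uA/cm^2
    stim_on, stim_off, stim_den, stim_comp,
    # recording
    site1, site2, rec1, rec2, rec_gtot, record_gtot,
    pump_every, rec_pump, rec_na, step0,
):
    """Advance the cable ``n_steps`` of size ``dt`` from global step ``step0``.

    Returns (status, step, comp, ina_int, ipump_int): status OK or BLOWUP
    (with the offending step and compartment); the last two are the time
    integrals of the Na+ current density and pump current density at
    site1 (uA*ms/cm^2), for charge-balance diagnostics.
    """
    n = v.shape[0]
    ngate = gates.shape[0]
    nv = xinf_tab.shape[1]
    nch = ch_gbar.shape[0]

    gsum = np.empty(n)
    ge = np.empty(n)
    gna = np.empty(n)
    gates_old = np.empty_like(gates)
    vref = np.empty(n)
    vnew = np.empty(n)
    # Thomas scratch
    cp = np.empty(n)
    dp = np.empty(n)

    ina_int = 0.0
    ipump_int = 0.0

    n_pulse = stim_on.shape[0]
    # first pulse that has not ended yet
    ip = 0
    while ip < n_pulse and stim_off[ip] <= step0:
        ip += 1

    om = 1.0 - theta
    tgax = theta * gax

    for s in range(n_steps):
        gstep = step0 + s

        # ---- pump current and E_Na on the slow cadence ------------------
        if gstep % pump_every == 0:
            if pump_mode == PUMP_DYNAMIC:
                for i in range(n):
                    ipump[i] = pump_imax / (1.0 + np.exp((pump_na_half - na[i]) / pump_na_s))
            elif pump_mode == PUMP_CONST:
                for i in range(n):
                    ipump[i] = pump_const
            if na_dynamic:
                for i in range(n):
                    ena[i] = nernst_slope * np.log10(na_out / na[i])

        # ---- stimulus ----------------------------------------------------
        stim = 0.0
        while ip < n_pulse and stim_off[ip] <= gstep:
            ip += 1
        if ip < n_pulse and stim_on[ip] <= gstep:
            stim = stim_den

        # ---- predictor / corrector passes -------------------------------
        for j in range(ngate):
            for i in range(n):
                gates_old[j, i] = gates[j, i]
        for i in range(n):
            vref[i] = v[i]

        for ps in range(n_pass):
            # gates: exponential Euler from the start-of-step values,
            # kinetics at vref (V(t) on the predictor, the midpoint
            # voltage on the corrector)
            for j in range(ngate):
                for i in range(n):
                    xi = _interp_table(xinf_tab, j, vref[i], tab_v0, tab_inv_dv, nv)
                    de = _interp_table(decay_tab, j, vref[i], tab_v0, tab_inv_dv, nv)
                    gates[j, i] = xi + (gates_old[j, i] - xi) * de

            # membrane conductances
            for i in range(n):
                gsum[i] = 0.0
                ge[i] = 0.0
                gna[i] = 0.0
            for c in range(nch):
                gb = ch_gbar[c]
                p = ch_p[c]
                q = ch_q[c]
                mi = ch_mi[c]
                hi = ch_hi[c]
                for i in range(n):
                    g = gb
                    if p > 0:
                        m = gates[mi, i]
                        gm = m
                        for _ in range(p - 1):
                            gm *= m
                        g *= gm
                    if q > 0:
                        g *= gates[hi, i]
                    gsum[i] += g
                    if c == na_ch:
                        gna[i] = g
                        ge[i] += g * ena[i]
                    else:
                        ge[i] += g * ch_e[c]

            # theta-implicit voltage solve (Thomas); theta = 1: backward
            # Euler, theta = 0.5: trapezoidal
            # (cdt + th*(gmem + gax*nn)) Vn - th*gax*(neighbors Vn)
            #   = cdt*V + (1-th)*(gax*lap(V) - gmem*V) + ge - ipump + stim
            b0 = cdt + theta * (gsum[0] + gax)
            lap = gax * (v[1] - v[0])
            r0 = cdt * v[0] + om * (lap - gsum[0] * v[0]) + ge[0] - ipump[0]
            if stim_comp == 0:
                r0 += stim
            cp[0] = -tgax / b0
            dp[0] = r0 / b0
            for i in range(1, n - 1):
                bi = cdt + theta * (gsum[i] + 2.0 * gax)
                lap = gax * (v[i - 1] - 2.0 * v[i] + v[i + 1])
                ri = cdt * v[i] + om * (lap - gsum[i] * v[i]) + ge[i] - ipump[i]
                if i == stim_comp:
                    ri += stim
                denom = bi + tgax * cp[i - 1]
                cp[i] = -tgax / denom
                dp[i] = (ri + tgax * dp[i - 1]) / denom
            bi = cdt + theta * (gsum[n - 1] + gax)
            lap = gax * (v[n - 2] - v[n - 1])
            ri = (cdt * v[n - 1] + om * (lap - gsum[n - 1] * v[n - 1])
                  + ge[n - 1] - ipump[n - 1])
            if stim_comp == n - 1:
                ri += stim
            denom = bi + tgax * cp[n - 2]
            x = (ri + tgax * dp[n - 2]) / denom
            vnew[n - 1] = x
            for i in range(n - 2, -1, -1):
                x = dp[i] - cp[i] * vnew[i + 1]
                vnew[i] = x

            if ps < n_pass - 1:
                for i in range(n):
                    vref[i] = 0.5 * (v[i] + vnew[i])

        for i in range(n):
            v[i] = vnew[i]

        # ---- sodium balance ---------------------------------------------
        if na_dynamic:
            for i in range(n):
                ina = gna[i] * (v[i] - ena[i])
                na[i] -= dt * (ina + 3.0 * ipump[i]) * na_rate_den

        # ---- diagnostics integrals at site1 ------------------------------
        if na_ch >= 0:
            ina_int += gna[site1] * (v[site1] - ena[site1]) * dt
        ipump_int += ipump[site1] * dt

        # ---- sanity + recording -----------------------------------------
        for i in range(n):
            if not (-200.0 < v[i] < 200.0):
                return BLOWUP, gstep, i, ina_int, ipump_int
        if rec1.shape[0] > 0:
            rec1[s] = v[site1]
            rec2[s] = v[site2]
            if record_gtot:
                rec_gtot[s] = gsum[site1]
        if rec_pump.shape[0] > 0 and gstep % pump_every == 0:
            k = gstep // pump_every - step0 // pump_every
            if k < rec_pump.shape[0]:
                rec_pump[k] = ipump[site1]
                rec_na[k] = na[site1]

    return OK, step0 + n_steps, -1, ina_int, ipump_int
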