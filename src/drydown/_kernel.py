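"""Numerical core of the dehydration simulator.

A single flat time-stepping kernel over float arrays, JIT-compiled with numba
when available (pure-Python fallback otherwise; the math is identical).  The
four plant pools (root, trunk, branch, leaf) are advanced with backward Euler
solved by damped Newton on the full 4-node system — the Jacobian is
tridiagonal (chain topology) and each iteration is one Thomas solve.  Soil
water content, cavitation state and shed fraction are updated explicitly
after each converged sub-step; internal fluxes are applied antisymmetrically
so total water is conserved to rounding.

Status codes returned by :func:`simulate_core`: 0 = horizon reached,
1 = hydraulic failure (stop PLC), 2 = sub-step convergence failure.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly by every simulation
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = ["simulate_core"]


@njit(cache=True)
def _plc_sigmoid(psi: float, p50: float, a: float) -> float:
    x = a * (psi - p50)
    if x > 700.0:
        return 0.0
    return 100.0 / (1.0 + math.exp(x))


@njit(cache=True)
def simulate_core(time_h, t_air_arr, vpd_arr, par_arr,
                  pi0, eps, p50, vc_slope, gs_max, g_res25, q10a, q10b, t_p,
                  leaf_ratio, has_shed, shed_rate, shed_half,
                  w_sat, apo_cap, bark_area, k_ax, la0,
                  pot_volume, rwc_sat, rwc_res, b_ret, psi_e, k_sat,
                  dt_max, dt_min, stop_plc, theta0, patm,
                  gres_ref_t, par_thresh, psi_clip, mol_per_l):
    n_hours = time_h.shape[0]
    r_tlp = 1.0 + pi0 / eps
    a_vc = vc_slope / 25.0
    k_cond_exp = 2.0 * b_ret + 3.0

    w_soil = pot_volume * theta0 / 100.0 * mol_per_l
    soil_cap = pot_volume * mol_per_l
    w = w_sat.copy()
    apo_rel = np.zeros(4)
    plc = np.empty(4)
    plc0 = _plc_sigmoid(0.0, p50, a_vc)
    for i in range(4):
        plc[i] = plc0
    psi = np.zeros(4)
    plf_max = 0.0
    cum_loss = 0.0
    w_init_total = w_soil + w.sum() + apo_cap.sum()

    # output buffers (hourly rows; one extra for a mid-hour failure row)
    nbuf = n_hours + 1
    out_time = np.zeros(nbuf)
    out_psi_soil = np.zeros(nbuf)
    out_psi = np.zeros((nbuf, 4))
    out_gs = np.zeros(nbuf)
    out_e_sto = np.zeros(nbuf)
    out_e_res = np.zeros(nbuf)
    out_plc_leaf = np.zeros(nbuf)
    out_plc_stem = np.zeros(nbuf)
    out_theta = np.zeros(nbuf)
    out_la = np.zeros(nbuf)
    out_loss = np.zeros(nbuf)

    theta_rel = w_soil / soil_cap * 100.0
    te = (theta_rel - rwc_res) / (rwc_sat - rwc_res)
    psi_soil = psi_e * te ** (-b_ret) if te > 0.0 else psi_clip
    if psi_soil < psi_clip:
        psi_soil = psi_clip

    nrow = 0
    out_time[nrow] = time_h[0]
    out_psi_soil[nrow] = psi_soil
    out_theta[nrow] = theta_rel
    out_la[nrow] = la0
    out_plc_leaf[nrow] = plc[3]
    out_plc_stem[nrow] = plc[2]
    nrow += 1

    status = 0
    fail_time = -1.0

    wn = np.empty(4)
    psi_n = np.empty(4)
    dpsi_n = np.empty(4)
    f_res = np.empty(4)
    jd = np.empty(4)  # Jacobian diagonal
    jl = np.empty(4)  # sub-diagonal (coupling to node i-1)
    ju = np.empty(4)  # super-diagonal (coupling to node i+1)
    cp = np.empty(4)
    dp = np.empty(4)
    g_link = np.empty(4)
    sink0 = np.empty(4)

    for ih in range(n_hours - 1):
        h0 = time_h[ih]
        h1 = time_h[ih + 1]
        t = h0 * 3600.0
        t_end = h1 * 3600.0
        span = (h1 - h0) * 3600.0
        last_gs = 0.0
        last_e_sto = 0.0
        last_e_res = 0.0
        hour_failed = False

        while t < t_end - 1e-9:
            dt = dt_max
            if t + dt > t_end:
                dt = t_end - t
            while True:
                # --- forcing at the backward end of the sub-step ---------
                fr = (t + dt - h0 * 3600.0) / span
                t_air = t_air_arr[ih] + (t_air_arr[ih + 1] - t_air_arr[ih]) * fr
                vpd = vpd_arr[ih] + (vpd_arr[ih + 1] - vpd_arr[ih]) * fr
                par = par_arr[ih] + (par_arr[ih + 1] - par_arr[ih]) * fr
                light = 1.0 if par >= par_thresh else 0.0
                vpd_p = vpd / patm
                if t_air <= t_p:
                    g_res_t = g_res25 * q10a ** ((t_air - gres_ref_t) / 10.0)
                else:
                    g_res_t = (g_res25 * q10a ** ((t_p - gres_ref_t) / 10.0)
                               * q10b ** ((t_air - t_p) / 10.0))
                la_rem = la0 * (1.0 - plf_max / 100.0)
                sink_leaf_res = g_res_t * leaf_ratio * vpd_p * la_rem
                for i in range(4):
                    sink0[i] = 2.0 * g_res_t * vpd_p * bark_area[i]
                sink0[3] += sink_leaf_res
                gs_area = gs_max * light * vpd_p * la_rem

                # --- conductances frozen at sub-step start ---------------
                theta_rel = w_soil / soil_cap * 100.0
                if theta_rel > rwc_sat:
                    theta_rel = rwc_sat
                te = (theta_rel - rwc_res) / (rwc_sat - rwc_res)
                if te > 0.0:
                    psi_soil = psi_e * te ** (-b_ret)
                    if psi_soil < psi_clip:
                        psi_soil = psi_clip
                    k_soil = k_sat * (te if te < 1.0 else 1.0) ** k_cond_exp
                else:
                    psi_soil = psi_clip
                    k_soil = 0.0
                q0 = 1.0 - plc[0] / 100.0
                k_r = k_ax[0] * q0
                g_link[0] = k_soil * k_r / (k_soil + k_r) if (k_soil + k_r) > 0.0 else 0.0
                g_link[1] = k_ax[1] * 0.5 * ((1.0 - plc[0] / 100.0) + (1.0 - plc[1] / 100.0))
                g_link[2] = k_ax[2] * 0.5 * ((1.0 - plc[1] / 100.0) + (1.0 - plc[2] / 100.0))
                g_link[3] = k_ax[3] * 0.5 * ((1.0 - plc[2] / 100.0) + (1.0 - plc[3] / 100.0))

                dt_mol = dt * 1e-3

                # --- damped Newton on the 4-node implicit system ---------
                for i in range(4):
                    wn[i] = w[i]
                converged = False
                for _it in range(80):
                    maxres = 0.0
                    for i in range(4):
                        r = wn[i] / w_sat[i]
                        if r < 1e-4:
                            r = 1e-4
                        if r >= r_tlp:
                            ps = pi0 / r - pi0 - eps * (1.0 - r)
                            dps = (-pi0 / (r * r) + eps) / w_sat[i]
                        else:
                            ps = pi0 / r
                            dps = (-pi0 / (r * r)) / w_sat[i]
                        psi_n[i] = ps
                        dpsi_n[i] = dps
                    for i in range(4):
                        g_up = g_link[i]
                        psi_up = psi_soil if i == 0 else psi_n[i - 1]
                        if i < 3:
                            g_dn = g_link[i + 1]
                            psi_dn = psi_n[i + 1]
                        else:
                            g_dn = 0.0
                            psi_dn = 0.0
                        sink = sink0[i]
                        dsink = 0.0
                        if i == 3 and gs_area > 0.0:
                            r = wn[3] / w_sat[3]
                            rel_t = (-pi0 - eps * (1.0 - r)) / (-pi0)
                            if rel_t >= 1.0:
                                sink += gs_area
                            elif rel_t > 0.0:
                                sink += gs_area * rel_t
                                dsink = gs_area * (eps / (-pi0)) / w_sat[3]
                        influx = g_up * (psi_up - psi_n[i]) + g_dn * (psi_dn - psi_n[i])
                        f_res[i] = wn[i] - w[i] - dt_mol * (influx - sink)
                        jd[i] = 1.0 + dt_mol * ((g_up + g_dn) * dpsi_n[i] + dsink)
                        jl[i] = -dt_mol * g_up * (0.0 if i == 0 else dpsi_n[i - 1])
                        ju[i] = -dt_mol * (g_dn * dpsi_n[i + 1] if i < 3 else 0.0)
                        ares = abs(f_res[i]) / w_sat[i]
                        if ares > maxres:
                            maxres = ares
                    if maxres < 1e-11:
                        converged = True
                        break
                    # Thomas solve J * delta = -F
                    cp[0] = ju[0] / jd[0]
                    dp[0] = -f_res[0] / jd[0]
                    for i in range(1, 4):
                        m = jd[i] - jl[i] * cp[i - 1]
                        cp[i] = ju[i] / m if i < 3 else 0.0
                        dp[i] = (-f_res[i] - jl[i] * dp[i - 1]) / m
                    d3 = dp[3]
                    wn3 = wn[3] + (0.5 * w_sat[3] if d3 > 0.5 * w_sat[3]
                                   else (-0.5 * w_sat[3] if d3 < -0.5 * w_sat[3] else d3))
                    if wn3 < 1e-4 * w_sat[3]:
                        wn3 = 1e-4 * w_sat[3]
                    wn[3] = wn3
                    for i in range(2, -1, -1):
                        di = dp[i] - cp[i] * dp[i + 1]
                        if di > 0.5 * w_sat[i]:
                            di = 0.5 * w_sat[i]
                        elif di < -0.5 * w_sat[i]:
                            di = -0.5 * w_sat[i]
                        wi = wn[i] + di
                        if wi < 1e-4 * w_sat[i]:
                            wi = 1e-4 * w_sat[i]
                        wn[i] = wi
                if converged:
                    break
                dt *= 0.5
                if dt < dt_min:
                    status = 2
                    fail_time = t / 3600.0
                    break
            if status == 2:
                break

            # --- commit the converged sub-step ---------------------------
            flux0 = g_link[0] * (psi_soil - psi_n[0])
            w_soil -= flux0 * dt_mol
            loss = 0.0
            for i in range(4):
                f_in = flux0 if i == 0 else g_link[i] * (psi_n[i - 1] - psi_n[i])
                f_out = g_link[i + 1] * (psi_n[i] - psi_n[i + 1]) if i < 3 else 0.0
                sink = sink0[i]
                if i == 3:
                    r = wn[3] / w_sat[3]
                    rel_t = (-pi0 - eps * (1.0 - r)) / (-pi0)
                    if rel_t > 1.0:
                        rel_t = 1.0
                    elif rel_t < 0.0:
                        rel_t = 0.0
                    gs_now = gs_max * light * rel_t
                    e_sto = gs_now * vpd_p * la_rem
                    sink += e_sto
                    last_gs = gs_now
                    last_e_sto = e_sto
                    last_e_res = sink_leaf_res + sink0[1] + sink0[2]
                w[i] = w[i] + (f_in - f_out - sink) * dt_mol
                loss += sink * dt_mol
                r = w[i] / w_sat[i]
                if r < 1e-4:
                    r = 1e-4
                psi[i] = pi0 / r - pi0 - eps * (1.0 - r) if r >= r_tlp else pi0 / r
            cum_loss += loss

            # cavitation running max + apoplastic discharge
            for i in range(4):
                p_new = _plc_sigmoid(psi[i], p50, a_vc)
                if p_new > plc[i]:
                    release = (p_new - plc[i]) / 100.0 * apo_cap[i]
                    avail = apo_cap[i] - apo_rel[i]
                    if release > avail:
                        release = avail
                    headroom = w_sat[i] - w[i]
                    if headroom < 0.0:
                        headroom = 0.0
                    if release > headroom:
                        release = headroom
                    w[i] += release
                    apo_rel[i] += release
                    plc[i] = p_new
            if has_shed:
                pl = psi[3] if psi[3] < 0.0 else 0.0
                x = shed_rate * (pl - shed_half)
                plf = 0.0 if x > 700.0 else 100.0 / (1.0 + math.exp(x))
                if plf > plf_max:
                    plf_max = plf

            t += dt
            if plc[3] >= stop_plc:
                status = 1
                fail_time = t / 3600.0
                hour_failed = True
                break

        # --- hourly (or terminal) output row -----------------------------
        theta_rel = w_soil / soil_cap * 100.0
        te = (theta_rel - rwc_res) / (rwc_sat - rwc_res)
        ps_soil_out = psi_e * te ** (-b_ret) if te > 0.0 else psi_clip
        if ps_soil_out < psi_clip:
            ps_soil_out = psi_clip
        out_time[nrow] = t / 3600.0
        out_psi_soil[nrow] = ps_soil_out
        for i in range(4):
            out_psi[nrow, i] = psi[i]
        out_gs[nrow] = last_gs
        out_e_sto[nrow] = last_e_sto
        out_e_res[nrow] = last_e_res
        out_plc_leaf[nrow] = plc[3]
        out_plc_stem[nrow] = plc[2]
        out_theta[nrow] = theta_rel
        out_la[nrow] = la0 * (1.0 - plf_max / 100.0)
        out_loss[nrow] = cum_loss
        nrow += 1
        if hour_failed or status == 2:
            break

    w_final = w_soil + w.sum()
    apo_left = apo_cap.sum() - apo_rel.sum()
    return (status, fail_time, nrow, out_time, out_psi_soil, out_psi, out_gs,
            out_e_sto, out_e_res, out_plc_leaf, out_plc_stem, out_theta,
            out_la, out_loss, w_init_total, w_final + apo_left, cum_loss)
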