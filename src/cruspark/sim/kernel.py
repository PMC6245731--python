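"""Fused numba time-stepping loop for the spark simulator.

One call advances the whole operator-split system (diffusion | buffering |
SERCA | analytic RyR release | stochastic gating) at fixed dt, recording a
confocal-like fluorescence readout every ``rec_every`` steps and logging
per-RyR gating events. The numerics are identical to the reference steps in
:mod:`cruspark.sim.ops`; this loop exists to make thousands of sub-steps per
millisecond affordable.

Stop reasons: 0 = ran to n_steps, 1 = final RyR closure, 2 = detection
threshold crossed, 3 = propagation to a non-trigger cluster, 9 = numerical
abort (non-finite or negative concentration).
"""

from __future__ import annotations

import numba
import numpy as np

STOP_TMAX = 0
STOP_CLOSED = 1
STOP_DETECTED = 2
STOP_PROPAGATED = 3
STOP_ABORT = 9


@numba.njit(cache=True, fastmath=True)
def run_kernel(
    cyt_nbr, sr_nbr,
    c, b, s, q, gamma,
    alpha_c, alpha_b, alpha_s,
    kon, koff, btot, kon_q, koff_q, btot_q,
    serca_sr, serca_cyt, serca_coef, a1, a2, a3, a4, a5,
    ryr_sr, ryr_cyt, e_release,
    phi_p, n_p, kmin_p, kmax_p, phi_m, n_m, kmin_m, kmax_m,
    ryr_cluster,
    nsr_idx, s_clamp, q_clamp, clamp_nsr,
    n_out, open_boundary, c_rest, b_rest,
    dt, n_steps, rec_every,
    ix_arr, iy_arr, iz_arr, wz, wy, wx, f_extra,
    stop_on_close, stop_on_detect, detect_threshold,
    stop_on_propagation, trigger_cluster,
    seed,
    rec_t, rec_dff, rec_nopen,
    first_open, ev_t, ev_ryr, ev_state,
):
    np.random.seed(seed)
    n_cyt = c.shape[0]
    n_ryr = gamma.shape[0]
    nf = ryr_sr.shape[1]
    n_p_read = wx.shape[0]
    nx = wx.shape[1]
    ny = wy.shape[0]

    tc = np.empty(n_cyt)
    t0 = np.empty(n_cyt)
    t1 = np.empty(n_cyt)
    t3 = np.empty(n_cyt)
    ts = np.empty(s.shape[0])
    plane = np.zeros((nx, ny))
    line = np.zeros(nx)
    f_read = np.zeros(n_p_read)
    f0_read = np.zeros(n_p_read)

    n_open = 0
    for r in range(n_ryr):
        if gamma[r] == 1:
            n_open += 1

    n_rec = 0
    n_ev = 0
    stop_reason = STOP_TMAX
    peak_dff = 0.0
    ev_cap = ev_t.shape[0]
    t_end = 0.0

    for step in range(n_steps + 1):
        t = step * dt

        # ---- readout / recording ----
        if step % rec_every == 0 or step == n_steps:
            for i in range(nx):
                for jj in range(ny):
                    plane[i, jj] = 0.0
            for v in range(n_cyt):
                plane[ix_arr[v], iy_arr[v]] += b[3, v] * wz[iz_arr[v]]
            for i in range(nx):
                acc = 0.0
                for jj in range(ny):
                    acc += plane[i, jj] * wy[jj]
                line[i] = acc
            dff = 0.0
            ok = True
            for p in range(n_p_read):
                acc = f_extra[p]
                for i in range(nx):
                    acc += line[i] * wx[p, i]
                f_read[p] = acc
            if step == 0:
                for p in range(n_p_read):
                    f0_read[p] = f_read[p]
                    if f_read[p] <= 0.0:
                        ok = False
                if not ok:
                    stop_reason = STOP_ABORT
                    break
            for p in range(n_p_read):
                v = f_read[p] / f0_read[p] - 1.0
                if v > dff:
                    dff = v
            if dff > peak_dff:
                peak_dff = dff
            if n_rec < rec_t.shape[0]:
                rec_t[n_rec] = t
                rec_dff[n_rec] = dff
                rec_nopen[n_rec] = n_open
                n_rec += 1
            t_end = t
            # sanity: abort on non-finite or negative concentration
            if not np.isfinite(c[0]) or c.min() < 0.0 or s.min() < 0.0:
                stop_reason = STOP_ABORT
                break
            if stop_on_detect and dff >= detect_threshold:
                stop_reason = STOP_DETECTED
                break
        if step == n_steps:
            break

        # ---- diffusion (c + mobile buffers fused in one sweep) ----
        for v in range(n_cyt):
            cv = c[v]
            b0v = b[0, v]
            b1v = b[1, v]
            b3v = b[3, v]
            acc_c = 0.0
            acc_0 = 0.0
            acc_1 = 0.0
            acc_3 = 0.0
            for slot in range(6):
                j = cyt_nbr[v, slot]
                if j >= 0:
                    ax = slot // 2
                    acc_c += alpha_c[ax] * (c[j] - cv)
                    acc_0 += alpha_b[0, ax] * (b[0, j] - b0v)
                    acc_1 += alpha_b[1, ax] * (b[1, j] - b1v)
                    acc_3 += alpha_b[3, ax] * (b[3, j] - b3v)
            if open_boundary:
                # Dirichlet ghost cells at rest beyond the box boundary
                for ax in range(3):
                    m = n_out[v, ax]
                    if m > 0:
                        acc_c += alpha_c[ax] * m * (c_rest - cv)
                        acc_0 += alpha_b[0, ax] * m * (b_rest[0] - b0v)
                        acc_1 += alpha_b[1, ax] * m * (b_rest[1] - b1v)
                        acc_3 += alpha_b[3, ax] * m * (b_rest[3] - b3v)
            tc[v] = cv + acc_c
            t0[v] = b0v + acc_0
            t1[v] = b1v + acc_1
            t3[v] = b3v + acc_3
        for v in range(n_cyt):
            c[v] = tc[v]
            b[0, v] = t0[v]
            b[1, v] = t1[v]
            b[3, v] = t3[v]
        for v in range(s.shape[0]):
            sv = s[v]
            acc = 0.0
            for slot in range(6):
                j = sr_nbr[v, slot]
                if j >= 0:
                    acc += alpha_s[slot // 2] * (s[j] - sv)
            ts[v] = sv + acc
        for v in range(s.shape[0]):
            s[v] = ts[v]

        # ---- buffering reactions ----
        for v in range(n_cyt):
            cv = c[v]
            for k in range(4):
                r = kon[k] * cv * (btot[k] - b[k, v]) - koff[k] * b[k, v]
                cv -= dt * r
                b[k, v] += dt * r
            c[v] = cv
        for v in range(s.shape[0]):
            r = kon_q * s[v] * (btot_q - q[v]) - koff_q * q[v]
            s[v] -= dt * r
            q[v] += dt * r

        # ---- SERCA ----
        for fidx in range(serca_sr.shape[0]):
            iv = serca_sr[fidx]
            jv = serca_cyt[fidx]
            cc = c[jv]
            ss = s[iv]
            flux = (a1 * cc * cc - a2 * ss * ss) / (a3 * cc * cc + a4 * ss * ss + a5)
            amt = flux * serca_coef[fidx]
            c[jv] -= amt
            s[iv] += amt

        # ---- analytic RyR release (open channels only) ----
        for r in range(n_ryr):
            if gamma[r] == 1:
                for f in range(nf):
                    iv = ryr_sr[r, f]
                    jv = ryr_cyt[r, f]
                    x = s[iv]
                    y = c[jv]
                    m = 0.5 * (x + y)
                    s[iv] = m + (x - m) * e_release
                    c[jv] = m + (y - m) * e_release

        # ---- stochastic gating ----
        for r in range(n_ryr):
            cl = 0.0
            for f in range(nf):
                cl += c[ryr_cyt[r, f]]
            cl /= nf
            if gamma[r] == 0:
                kp = phi_p * cl**n_p
                if kp < kmin_p:
                    kp = kmin_p
                elif kp > kmax_p:
                    kp = kmax_p
                if np.random.random() < 1.0 - np.exp(-kp * dt):
                    gamma[r] = 1
                    n_open += 1
                    if first_open[r] < 0.0:
                        first_open[r] = t
                    if n_ev < ev_cap:
                        ev_t[n_ev] = t
                        ev_ryr[n_ev] = r
                        ev_state[n_ev] = 1
                        n_ev += 1
                    if stop_on_propagation and ryr_cluster[r] != trigger_cluster:
                        stop_reason = STOP_PROPAGATED
            else:
                if cl <= 0.0:
                    km = kmax_m
                else:
                    km = phi_m * cl**n_m
                    if km < kmin_m:
                        km = kmin_m
                    elif km > kmax_m:
                        km = kmax_m
                if np.random.random() < 1.0 - np.exp(-km * dt):
                    gamma[r] = 0
                    n_open -= 1
                    if n_ev < ev_cap:
                        ev_t[n_ev] = t
                        ev_ryr[n_ev] = r
                        ev_state[n_ev] = 0
                        n_ev += 1
        if stop_reason == STOP_PROPAGATED:
            t_end = t
            break

        # ---- nSR clamp ----
        if clamp_nsr:
            for k in range(nsr_idx.shape[0]):
                s[nsr_idx[k]] = s_clamp
                q[nsr_idx[k]] = q_clamp

        if stop_on_close and n_open == 0:
            stop_reason = STOP_CLOSED
            t_end = t
            break

    return n_rec, n_ev, stop_reason, peak_dff, t_end
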