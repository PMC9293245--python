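"""Fused simulation kernel.

A numba-compiled loop that advances the whole closed sensorimotor chain
(plant -> sensors -> network -> plasticity) for a block of timesteps on
flat arrays, mutating state in place.  It mirrors, operation for
operation, the per-step path composed from the module functions in
``mechanics``/``sensors``/``network``/``learning``/``apg``; the test suite
pins the two paths against each other and against a scalar straight-line
oracle.

Everything here is an implementation detail: use ``engine.Simulation``.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chunk"]


@njit(cache=True)
def run_chunk(
    n_steps, step0, stab_steps, dt,
    # plant parameters
    B, D, gain, anchor, tip_off, wall_l, wall_r, kc, stiction, limb_range,
    # network / learning parameters
    K_A, K_L, K_M, K_C, tau0, tau_dec, alpha_hp, alpha_lp,
    eta_slope, eta_max, leak_floor, leak_scale,
    # flags
    plasticity, use_phasic, record,
    # plant state: [x_l, x_r, v_l, v_r, x_body, v_body,
    #               f_lw, f_rw, f_c, f_cut_l, f_cut_r]
    mech,
    # sensor state
    ia, ii, ib, cut, cut_y, cut_s, cut_contact,
    # network state
    W, sign, learnable, P, Pp, num_y, den_y, k_leak, leak_y, Pbar,
    # learning state
    l, lp_hp, lp,
    # twitch slots
    slot_y, slot_amp, slot_gain, slot_end, slot_active, tail_cutoff,
    # twitch schedule (absolute onset/end steps, sorted by onset)
    ev_muscle, ev_start, ev_end, ev_amp, ev_gain, ev_ptr,
    # phasic drive (n_steps, 4) when use_phasic, else (0, 4)
    phasic,
    # outputs
    rec, summary,
):
    n_neurons = W.shape[0]
    n_sources = W.shape[1]
    n_ev = ev_start.shape[0]
    n_slots = slot_y.shape[1]
    span = 2.0 * limb_range
    visc = B + D
    apg = np.zeros(4)
    u_plus = np.zeros(n_sources)
    P_new = np.zeros(n_neurons)
    Pp_new = np.zeros(n_neurons)

    for t in range(n_steps):
        n = step0 + t

        # ---- muscle activations from the previous step's motoneuron output
        A0, A1, A2, A3 = Pp[0], Pp[1], Pp[2], Pp[3]

        # ---- plant -------------------------------------------------------
        x_l, x_r, x_body = mech[0], mech[1], mech[4]
        if not (np.isfinite(x_l) and np.isfinite(x_r) and np.isfinite(x_body)):
            return n
        s0 = max(0.0, x_l + anchor)
        s1 = max(0.0, anchor - x_l)
        s2 = max(0.0, anchor - x_r)
        s3 = max(0.0, x_r + anchor)
        tip_l = x_body + x_l - tip_off
        tip_r = x_body + x_r + tip_off
        ov_c = max(0.0, tip_l - tip_r)
        ov_lw = max(0.0, wall_l - tip_l)
        ov_rw = max(0.0, tip_r - wall_r)
        f_c = kc * ov_c
        f_l = -gain * A0 * s0 + gain * A1 * s1 - f_c + kc * ov_lw
        f_r = gain * A2 * s2 - gain * A3 * s3 + f_c - kc * ov_rw
        f_lw = 0.0
        f_rw = 0.0
        if ov_lw > 0.0:
            f_lw = max(0.0, gain * A0 * s0 - gain * A1 * s1)
        if ov_rw > 0.0:
            f_rw = -max(0.0, gain * A2 * s2 - gain * A3 * s3)
        x_l_new = min(max(x_l + dt * f_l / visc, -limb_range), limb_range)
        x_r_new = min(max(x_r + dt * f_r / visc, -limb_range), limb_range)
        v_l = (x_l_new - x_l) / dt
        v_r = (x_r_new - x_r) / dt
        f_net = f_lw + f_rw
        if abs(f_net) > stiction:
            v_body = f_net / visc
        else:
            v_body = 0.0
        x_body = x_body + dt * v_body
        f_cut_l = f_lw + f_c
        f_cut_r = -f_rw + f_c
        mech[0] = x_l_new
        mech[1] = x_r_new
        mech[2] = v_l
        mech[3] = v_r
        mech[4] = x_body
        mech[5] = v_body
        mech[6] = f_lw
        mech[7] = f_rw
        mech[8] = f_c
        mech[9] = f_cut_l
        mech[10] = f_cut_r

        # ---- pattern-generator drive ------------------------------------
        if use_phasic:
            for m in range(4):
                apg[m] = phasic[t, m]
        else:
            while ev_ptr[0] < n_ev and ev_start[ev_ptr[0]] <= n:
                e = ev_ptr[0]
                mu = ev_muscle[e]
                slot = -1
                for s in range(n_slots):
                    if not slot_active[mu, s]:
                        slot = s
                        break
                if slot < 0:
                    slot = 0
                    for s in range(1, n_slots):
                        if slot_end[mu, s] < slot_end[mu, slot]:
                            slot = s
                slot_y[mu, slot] = 0.0
                slot_amp[mu, slot] = ev_amp[e]
                slot_gain[mu, slot] = ev_gain[e]
                slot_end[mu, slot] = ev_end[e]
                slot_active[mu, slot] = True
                ev_ptr[0] += 1
            for m in range(4):
                d = 0.0
                for s in range(n_slots):
                    if not slot_active[m, s]:
                        continue
                    pulse = slot_amp[m, s] if n < slot_end[m, s] else 0.0
                    slot_y[m, s] += slot_gain[m, s] * (pulse - slot_y[m, s])
                    if pulse == 0.0 and slot_y[m, s] < tail_cutoff:
                        slot_active[m, s] = False
                        slot_y[m, s] = 0.0
                    else:
                        d += slot_y[m, s]
                apg[m] = min(d, 1.0)

        # ---- sensors -----------------------------------------------------
        L0 = (x_l_new + limb_range) / span
        L1 = (limb_range - x_l_new) / span
        L2 = (limb_range - x_r_new) / span
        L3 = (x_r_new + limb_range) / span
        V0 = v_l / span
        V1 = -v_l / span
        V2 = -v_r / span
        V3 = v_r / span
        Ls = (L0, L1, L2, L3)
        Vs = (V0, V1, V2, V3)
        As = (A0, A1, A2, A3)
        for m in range(4):
            ii[m] = ((Ls[m] - 0.2) * 1.25 + As[m]) / 2.0
            ia[m] = (1.5 + np.log10(As[m] + 0.1)) * Vs[m] + (As[m] + ii[m] * 0.2) / 2.0
            ib[m] = Ls[m] * As[m]
        f_cuts = (f_cut_l, f_cut_r)
        for limb in range(2):
            F = f_cuts[limb]
            in_contact = F > 0.0
            if (not in_contact) or (cut_contact[limb] == 0):
                cut_s[limb] = tau0
            drive = F * 0.5 * cut_s[limb]
            if in_contact:
                cut_s[limb] = 1.0 + (cut_s[limb] - 1.0) * tau_dec
            cut_contact[limb] = 1 if in_contact else 0
            cut_y[limb] = cut_y[limb] * (1.0 - K_C) + drive * K_C
            cut[limb] = cut_y[limb]

        # ---- source vector (rectified at synapse entry) ------------------
        for m in range(4):
            u_plus[m] = max(ia[m], 0.0)
            u_plus[4 + m] = max(ii[m], 0.0)
            u_plus[8 + m] = max(ib[m], 0.0)
        u_plus[12] = max(cut[0], 0.0)
        u_plus[13] = max(cut[1], 0.0)
        for j in range(n_neurons):
            u_plus[14 + j] = Pp[j]  # already rectified

        # ---- synchronous neuron update ----------------------------------
        for i in range(n_neurons):
            num = 0.0
            den = 0.0
            for j in range(n_sources):
                wu = W[i, j] * u_plus[j]
                num += wu * sign[j]
                den += wu
            if i < 4:
                num += apg[i]
                den += apg[i]
            num_y[i] += K_A * (num - num_y[i])
            den_y[i] += K_A * (den - den_y[i])
            leak_y[i] += K_M * (den - leak_y[i])
            target = max(leak_floor, leak_scale * leak_y[i])
            if n < stab_steps:
                k_leak[i] = target
            else:
                k_leak[i] = max(k_leak[i], target)
            p = num_y[i] / (k_leak[i] + den_y[i])
            p = min(max(p, -1.0), 1.0)
            P_new[i] = p
            Pp_new[i] = max(p, 0.0)

        # ---- plasticity --------------------------------------------------
        if plasticity:
            for i in range(n_neurons):
                lp_hp[i] += alpha_hp * (P_new[i] - lp_hp[i])
                hp_i = P_new[i] - lp_hp[i]
                lp[i] += alpha_lp * (P_new[i] - lp[i])
                lp_i = lp[i]
                pb = Pbar[i]
                eta_i = min(pb * eta_slope, eta_max)
                for j in range(n_sources):
                    post = (hp_i if sign[j] > 0.0 else lp_i) - pb
                    drv = u_plus[j] * W[i, j] * post
                    lv = l[i, j] + K_L * (drv - l[i, j])
                    lv = min(max(lv, -1.0), 1.0)
                    l[i, j] = lv
                    if learnable[i, j]:
                        c = (1.0 - W[i, j]) if lv >= 0.0 else W[i, j]
                        W[i, j] += lv * eta_i * c
            for i in range(n_neurons):
                Pbar[i] += K_M * (Pp_new[i] - Pbar[i])

        for i in range(n_neurons):
            P[i] = P_new[i]
            Pp[i] = Pp_new[i]

        if record:
            for i in range(n_neurons):
                rec[t, i] = Pp[i]

        # ---- kinematic summary accumulators ------------------------------
        summary[0] += x_l_new
        summary[1] += x_r_new
        summary[2] = min(summary[2], x_l_new)
        summary[3] = max(summary[3], x_l_new)
        summary[4] = min(summary[4], x_r_new)
        summary[5] = max(summary[5], x_r_new)
        av = max(abs(v_l), abs(v_r))
        summary[6] = max(summary[6], av)
        summary[7] = max(summary[7], max(f_lw, -f_rw))
        if v_body != 0.0:
            summary[8] += 1.0

    return -1
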