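"""Independent scalar oracles used by the test suite.

Everything here is deliberately written straight-line, on python scalars
and explicit loops, without reusing the package's vectorized code paths:
the recurrences of the sensor filter, neuron activation and learning rule,
a full closed-loop step sequence driven by a prescribed pattern-generator
drive, and a covariance-eigendecomposition PCA.
"""
from __future__ import annotations

import math

import numpy as np


def kalman_seq(y0, xs, K):
    """Hand iteration of the 1-D Kalman filter."""
    y = y0
    out = []
    for x in xs:
        y = y * (1.0 - K) + x * K
        out.append(y)
    return out


def learning_rule_scalar(seq, w0, *, K_L=0.001, eta_slope=0.04, eta_max=0.001,
                         K_M=4.0e-5, alpha_hp=None, alpha_lp=None,
                         excitatory=True, dt=0.01):
    """Straight-line recurrence of the plasticity chain for one synapse.

    ``seq`` is an iterable of (presynaptic P+, postsynaptic P) pairs.
    Returns the trajectories of (l, w, P_bar).
    """
    if alpha_hp is None:
        alpha_hp = 1.0 - math.exp(-2.0 * math.pi * 0.05 * dt)
    if alpha_lp is None:
        alpha_lp = 1.0 - math.exp(-2.0 * math.pi * 0.2 * dt)
    l = 0.0
    w = w0
    pbar = 0.0
    lp_hp = 0.0
    lp = 0.0
    ls, ws, pbars = [], [], []
    for pre, post in seq:
        lp_hp = lp_hp + alpha_hp * (post - lp_hp)
        lp = lp + alpha_lp * (post - lp)
        phi = (post - lp_hp) if excitatory else lp
        drive = pre * w * (phi - pbar)
        l = l + K_L * (drive - l)
        l = min(max(l, -1.0), 1.0)
        c = (1.0 - w) if l >= 0.0 else w
        eta = min(pbar * eta_slope, eta_max)
        w = w + l * eta * c
        pbar = pbar + K_M * (max(post, 0.0) - pbar)
        ls.append(l)
        ws.append(w)
        pbars.append(pbar)
    return ls, ws, pbars


def pca_ratios_eig(X):
    """Explained-variance ratios via covariance eigendecomposition."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    vals = np.linalg.eigvalsh(C)[::-1]
    vals = np.clip(vals, 0.0, None)
    return vals / vals.sum()


def trajectory_length(coords):
    """Scalar-loop distance traveled along a sequence of coordinates."""
    total = 0.0
    for a, b in zip(coords[:-1], coords[1:]):
        total += math.sqrt(sum((float(x) - float(y)) ** 2
                               for x, y in zip(a, b)))
    return total


def oracle_closed_loop(sim, n_steps, drive_rows, plasticity=True):
    """Straight-line scalar re-implementation of the full loop.

    Starts from (a copy of) a ``Simulation``'s current state and advances
    ``n_steps`` with the prescribed per-step pattern-generator drive
    (``drive_rows[t][m]``), returning a dict of final state arrays.  The
    loop is written with explicit per-neuron/per-synapse scalar arithmetic.
    """
    cfg = sim.cfg
    mc, nc = cfg.mech, cfg.network
    dt = cfg.dt
    anchor = mc.limb_range_max + mc.anchor_overshoot
    visc = mc.viscosity_B + mc.damping_D
    span = 2.0 * mc.limb_range_max
    alpha_hp = 1.0 - math.exp(-2.0 * math.pi * nc.f_highpass * dt)
    alpha_lp = 1.0 - math.exp(-2.0 * math.pi * nc.f_lowpass * dt)

    W = [[float(x) for x in row] for row in sim.W]
    sign = [float(x) for x in sim.topology.sign]
    learn = [[bool(x) for x in row] for row in sim.topology.learnable]
    P = [float(x) for x in sim.neurons.P]
    Pp = [float(x) for x in sim.neurons.P_plus]
    num_y = [float(x) for x in sim.neurons.num_y]
    den_y = [float(x) for x in sim.neurons.den_y]
    k = [float(x) for x in sim.neurons.k]
    leak_y = [float(x) for x in sim.neurons.leak_y]
    pbar = [float(x) for x in sim.neurons.P_bar]
    l = [[float(x) for x in row] for row in sim.learning.l]
    lp_hp = [float(x) for x in sim.learning.lp_hp]
    lp = [float(x) for x in sim.learning.lp]
    m = sim.mech
    x_l, x_r, x_body = m.x_l, m.x_r, m.x_body
    cut_y = [float(x) for x in sim.sensors.cut_y]
    cut_s = [float(x) for x in sim.sensors.cut_s]
    cut_c = [bool(x) for x in sim.sensors.cut_contact]

    for t in range(n_steps):
        n = sim.step_index + t
        A = [Pp[0], Pp[1], Pp[2], Pp[3]]
        # plant
        s0 = max(0.0, x_l + anchor)
        s1 = max(0.0, anchor - x_l)
        s2 = max(0.0, anchor - x_r)
        s3 = max(0.0, x_r + anchor)
        tip_l = x_body + x_l - mc.limb_tip_offset
        tip_r = x_body + x_r + mc.limb_tip_offset
        ov_c = max(0.0, tip_l - tip_r)
        ov_lw = max(0.0, mc.wall_positions[0] - tip_l)
        ov_rw = max(0.0, tip_r - mc.wall_positions[1])
        f_c = mc.contact_stiffness * ov_c
        g = mc.muscle_gain
        f_l = -g * A[0] * s0 + g * A[1] * s1 - f_c + mc.contact_stiffness * ov_lw
        f_r = g * A[2] * s2 - g * A[3] * s3 + f_c - mc.contact_stiffness * ov_rw
        f_lw = max(0.0, g * A[0] * s0 - g * A[1] * s1) if ov_lw > 0 else 0.0
        f_rw = -max(0.0, g * A[2] * s2 - g * A[3] * s3) if ov_rw > 0 else 0.0
        xl2 = min(max(x_l + dt * f_l / visc, -mc.limb_range_max), mc.limb_range_max)
        xr2 = min(max(x_r + dt * f_r / visc, -mc.limb_range_max), mc.limb_range_max)
        v_l = (xl2 - x_l) / dt
        v_r = (xr2 - x_r) / dt
        x_l, x_r = xl2, xr2
        f_net = f_lw + f_rw
        x_body += dt * (f_net / visc if abs(f_net) > mc.stiction_threshold else 0.0)
        f_cut = [f_lw + f_c, -f_rw + f_c]
        # sensors
        L = [(x_l + mc.limb_range_max) / span, (mc.limb_range_max - x_l) / span,
             (mc.limb_range_max - x_r) / span, (x_r + mc.limb_range_max) / span]
        V = [v_l / span, -v_l / span, -v_r / span, v_r / span]
        ii = [0.0] * 4
        ia = [0.0] * 4
        ib = [0.0] * 4
        for mu in range(4):
            ii[mu] = ((L[mu] - 0.2) * 1.25 + A[mu]) / 2.0
            ia[mu] = (1.5 + math.log10(A[mu] + 0.1)) * V[mu] + (A[mu] + ii[mu] * 0.2) / 2.0
            ib[mu] = L[mu] * A[mu]
        cut = [0.0, 0.0]
        for limb in range(2):
            F = f_cut[limb]
            contact = F > 0.0
            if (not contact) or (not cut_c[limb]):
                cut_s[limb] = nc.tau_initial
            drv = F * 0.5 * cut_s[limb]
            if contact:
                cut_s[limb] = 1.0 + (cut_s[limb] - 1.0) * nc.tau_decay
            cut_c[limb] = contact
            cut_y[limb] = cut_y[limb] * (1.0 - nc.gain_cutaneous) + drv * nc.gain_cutaneous
            cut[limb] = cut_y[limb]
        u = ([max(v, 0.0) for v in ia] + [max(v, 0.0) for v in ii]
             + [max(v, 0.0) for v in ib] + [max(v, 0.0) for v in cut] + list(Pp))
        apg = [float(drive_rows[t][mu]) for mu in range(4)]
        # neurons
        P_new = [0.0] * 36
        Pp_new = [0.0] * 36
        for i in range(36):
            num = 0.0
            den = 0.0
            for j in range(50):
                wu = W[i][j] * u[j]
                num += wu * sign[j]
                den += wu
            if i < 4:
                num += apg[i]
                den += apg[i]
            num_y[i] += nc.gain_activity * (num - num_y[i])
            den_y[i] += nc.gain_activity * (den - den_y[i])
            leak_y[i] += nc.gain_mean * (den - leak_y[i])
            target = max(nc.leak_floor, nc.leak_scale * leak_y[i])
            if n < cfg.stabilization_steps:
                k[i] = target
            else:
                k[i] = max(k[i], target)
            p = num_y[i] / (k[i] + den_y[i])
            p = min(max(p, -1.0), 1.0)
            P_new[i] = p
            Pp_new[i] = max(p, 0.0)
        if plasticity:
            for i in range(36):
                lp_hp[i] += alpha_hp * (P_new[i] - lp_hp[i])
                hp_i = P_new[i] - lp_hp[i]
                lp[i] += alpha_lp * (P_new[i] - lp[i])
                eta_i = min(pbar[i] * nc.eta_slope, nc.eta_max)
                for j in range(50):
                    post = (hp_i if sign[j] > 0 else lp[i]) - pbar[i]
                    drv = u[j] * W[i][j] * post
                    lv = l[i][j] + nc.gain_learning * (drv - l[i][j])
                    lv = min(max(lv, -1.0), 1.0)
                    l[i][j] = lv
                    if learn[i][j]:
                        c = (1.0 - W[i][j]) if lv >= 0.0 else W[i][j]
                        W[i][j] += lv * eta_i * c
            for i in range(36):
                pbar[i] += nc.gain_mean * (Pp_new[i] - pbar[i])
        P = P_new
        Pp = Pp_new

    return dict(W=np.array(W), P=np.array(P), Pp=np.array(Pp),
                num_y=np.array(num_y), den_y=np.array(den_y),
                k=np.array(k), leak_y=np.array(leak_y), pbar=np.array(pbar),
                l=np.array(l), x_l=x_l, x_r=x_r, x_body=x_body,
                cut_y=np.array(cut_y))
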