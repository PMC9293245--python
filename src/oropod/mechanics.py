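"""One-dimensional musculoskeletal plant: body, two limbs, four muscles.

Each limb is driven by an antagonistic pair of spring-like muscles that can
pull but not push: the instantaneous muscle force is ``gain * A * stretch``
where ``A`` is the neural activation (0-1) and the stretch is the distance
from the limb to the muscle anchor.  Limb dynamics are first order
(viscosity-dominated): ``B * xdot = F - xdot * D``, integrated with a 10-ms
step.  The body moves only when the net force it exerts on the walls exceeds
a stiction threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import MechConfig

__all__ = [
    "MechState",
    "MuscleKinematics",
    "muscle_stretches",
    "compute_limb_forces",
    "wall_forces",
    "contact_overlap",
    "step",
    "muscle_kinematics",
]


@dataclass
class MechState:
    """The physical world at one timestep.

    Limb positions are body-relative, each centered on its own travel
    (negative = outward for the left limb, positive = outward for the right
    limb).  ``f_lw >= 0`` and ``f_rw <= 0`` are the wall reaction forces as
    applied to the body; ``f_cut_*`` are the net contact forces pressing on
    each limb (wall plus limb-limb), which drive the cutaneous sensors.
    """

    x_l: float = 0.0
    x_r: float = 0.0
    v_l: float = 0.0
    v_r: float = 0.0
    x_body: float = 0.0
    v_body: float = 0.0
    f_lw: float = 0.0
    f_rw: float = 0.0
    f_c: float = 0.0       # limb-limb contact force magnitude
    f_cut_l: float = 0.0
    f_cut_r: float = 0.0

    def copy(self) -> "MechState":
        return replace(self)


@dataclass
class MuscleKinematics:
    """Normalized muscle lengths, lengthening velocities and activations."""

    L: np.ndarray  # (4,), each in [0, 1] over the limb's range
    V: np.ndarray  # (4,), 1/s, signed lengthening velocity
    A: np.ndarray  # (4,), activations in [0, 1]


def muscle_stretches(cfg: MechConfig, x_l: float, x_r: float) -> np.ndarray:
    """Distance from each limb to its muscle anchor, order (LE, LF, RE, RF).

    Positive throughout the anatomical range by construction; clamped at
    zero so a slack muscle can never push.
    """
    x_ll, x_lr, x_rl, x_rr = cfg.anchor_positions
    s = np.array([x_l - x_ll, x_lr - x_l, x_rr - x_r, x_r - x_rl])
    return np.maximum(s, 0.0)


def contact_overlap(cfg: MechConfig, state: MechState) -> tuple[float, float, float]:
    """(limb-limb, left-wall, right-wall) penetration depths, all >= 0."""
    tip_l = state.x_body + state.x_l - cfg.limb_tip_offset
    tip_r = state.x_body + state.x_r + cfg.limb_tip_offset
    wall_l, wall_r = cfg.wall_positions
    return (
        max(0.0, tip_l - tip_r),
        max(0.0, wall_l - tip_l),
        max(0.0, tip_r - wall_r),
    )


def wall_forces(cfg: MechConfig, state: MechState, A: np.ndarray) -> tuple[float, float]:
    """Wall reaction forces (F_LW, F_RW) as applied to the body.

    A limb in contact with its wall transmits the surplus of its extensor
    pull over its flexor pull; the formula is clamped to zero when the
    flexor dominates (the reaction is only valid pressing into the wall).
    Returns F_LW >= 0 (pushes the body rightward) and F_RW <= 0.
    """
    ov_c, ov_lw, ov_rw = contact_overlap(cfg, state)
    s = muscle_stretches(cfg, state.x_l, state.x_r)
    g = cfg.muscle_gain
    f_lw = 0.0
    f_rw = 0.0
    if ov_lw > 0.0:
        f_lw = max(0.0, g * A[0] * s[0] - g * A[1] * s[1])
    if ov_rw > 0.0:
        f_rw = -max(0.0, g * A[2] * s[2] - g * A[3] * s[3])
    return f_lw, f_rw


def compute_limb_forces(cfg: MechConfig, state: MechState, A: np.ndarray) -> tuple[float, float]:
    """Net non-viscous force on each limb (springs plus contact penalties).

    The viscous term is handled implicitly in :func:`step` (the first-order
    dynamics are solved for the velocity), so it is not included here.
    """
    s = muscle_stretches(cfg, state.x_l, state.x_r)
    g = cfg.muscle_gain
    ov_c, ov_lw, ov_rw = contact_overlap(cfg, state)
    f_c = cfg.contact_stiffness * ov_c
    f_l = -g * A[0] * s[0] + g * A[1] * s[1] - f_c + cfg.contact_stiffness * ov_lw
    f_r = g * A[2] * s[2] - g * A[3] * s[3] + f_c - cfg.contact_stiffness * ov_rw
    return f_l, f_r


def step(cfg: MechConfig, state: MechState, A: np.ndarray, dt: float) -> MechState:
    """Advance the plant by one timestep.

    Velocities solve ``v = F / (B + D)`` (viscosity plus damping), positions
    are clamped to the anatomical range, and the body moves only when the
    net wall force exceeds the stiction threshold.  Raises ``FloatingPointError``
    on non-finite state.
    """
    if not (np.isfinite(state.x_l) and np.isfinite(state.x_r)
            and np.isfinite(state.x_body)):
        raise FloatingPointError("non-finite mechanical state")

    visc = cfg.viscosity_B + cfg.damping_D
    rng = cfg.limb_range_max

    f_l, f_r = compute_limb_forces(cfg, state, A)
    f_lw, f_rw = wall_forces(cfg, state, A)
    ov_c, ov_lw, ov_rw = contact_overlap(cfg, state)
    f_c = cfg.contact_stiffness * ov_c

    x_l_new = min(max(state.x_l + dt * f_l / visc, -rng), rng)
    x_r_new = min(max(state.x_r + dt * f_r / visc, -rng), rng)
    v_l = (x_l_new - state.x_l) / dt
    v_r = (x_r_new - state.x_r) / dt

    f_net = f_lw + f_rw  # f_rw <= 0
    if abs(f_net) > cfg.stiction_threshold:
        v_body = f_net / visc
    else:
        v_body = 0.0
    x_body = state.x_body + dt * v_body

    return MechState(
        x_l=x_l_new, x_r=x_r_new, v_l=v_l, v_r=v_r,
        x_body=x_body, v_body=v_body,
        f_lw=f_lw, f_rw=f_rw, f_c=f_c,
        f_cut_l=f_lw + f_c, f_cut_r=-f_rw + f_c,
    )


def muscle_kinematics(cfg: MechConfig, state: MechState,
                      A: np.ndarray | None = None) -> MuscleKinematics:
    """Normalized muscle lengths and lengthening velocities.

    Lengths are a linear map of limb position spanning [0, 1] over the
    anatomical range, with the extensor and flexor of a limb complementary
    (both are 0.5 at center of travel).
    """
    span = 2.0 * cfg.limb_range_max
    L = np.array([
        (state.x_l + cfg.limb_range_max) / span,   # LE lengthens as limb flexes
        (cfg.limb_range_max - state.x_l) / span,   # LF
        (cfg.limb_range_max - state.x_r) / span,   # RE
        (state.x_r + cfg.limb_range_max) / span,   # RF
    ])
    V = np.array([state.v_l, -state.v_l, -state.v_r, state.v_r]) / span
    if A is None:
        A = np.zeros(4)
    return MuscleKinematics(L=L, V=V, A=np.asarray(A, dtype=float))
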