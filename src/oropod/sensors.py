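"""Proprioceptive and cutaneous receptor models.

Four muscles each carry a group Ia spindle afferent (length + velocity, with
dynamic fusimotor modulation by the motoneuron activation), a group II
spindle afferent (static length) and a Golgi tendon organ (Ib, active
force).  Each limb carries one nondirectional cutaneous receptor responding
to net contact force with a phasic onset (3x the tonic drive) that decays
multiplicatively toward a plateau at half the sustained force, like a
slowly adapting type I receptor.

All filtering shares the one-dimensional Kalman filter
``y_t = y_{t-1} (1 - K) + x_t K``.

Sensor outputs are signed (Ia can go negative during rapid shortening);
rectification happens downstream at the synapses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "kalman",
    "KalmanFilter1D",
    "spindle_ia",
    "spindle_ii",
    "spindle_ib",
    "SensorFrame",
    "cutaneous_step",
    "sense",
]


def kalman(y: float, x: float, K: float) -> float:
    """One step of the shared 1-D Kalman filter (unit DC gain)."""
    return y * (1.0 - K) + x * K


@dataclass
class KalmanFilter1D:
    """Stateful convenience wrapper around :func:`kalman`."""

    K: float
    y: float = 0.0

    def step(self, x: float) -> float:
        self.y = kalman(self.y, x, self.K)
        return self.y


def spindle_ii(L, A):
    """Group II spindle: static length component with fusimotor offset."""
    return ((np.asarray(L) - 0.2) * 1.25 + np.asarray(A)) / 2.0


def spindle_ia(A, V, II):
    """Group Ia spindle: velocity term with fusimotor-scaled dynamic gain
    plus a static component built on the group II signal."""
    A = np.asarray(A)
    return (1.5 + np.log10(A + 0.1)) * np.asarray(V) + (A + np.asarray(II) * 0.2) / 2.0


def spindle_ib(L, A):
    """Golgi tendon organ: proxy for active muscle force."""
    return np.asarray(L) * np.asarray(A)


@dataclass
class SensorFrame:
    """The 14 primary-afferent values plus the cutaneous filter memories.

    ``cut_s`` is the onset-decay scalar (starts at ``tau_initial`` on
    contact onset and decays toward 1), ``cut_y`` the Kalman memory of each
    cutaneous channel, ``cut_contact`` the previous-step contact flag.
    """

    ia: np.ndarray = field(default_factory=lambda: np.zeros(4))
    ii: np.ndarray = field(default_factory=lambda: np.zeros(4))
    ib: np.ndarray = field(default_factory=lambda: np.zeros(4))
    cutaneous: np.ndarray = field(default_factory=lambda: np.zeros(2))
    cut_y: np.ndarray = field(default_factory=lambda: np.zeros(2))
    cut_s: np.ndarray = field(default_factory=lambda: np.full(2, 3.0))
    cut_contact: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=bool))

    def copy(self) -> "SensorFrame":
        return SensorFrame(
            ia=self.ia.copy(), ii=self.ii.copy(), ib=self.ib.copy(),
            cutaneous=self.cutaneous.copy(), cut_y=self.cut_y.copy(),
            cut_s=self.cut_s.copy(), cut_contact=self.cut_contact.copy(),
        )

    def afferent_vector(self) -> np.ndarray:
        """The 14 values in canonical order Ia(4), II(4), Ib(4), C(2)."""
        return np.concatenate([self.ia, self.ii, self.ib, self.cutaneous])


def cutaneous_step(frame: SensorFrame, F: float, limb: int, *,
                   K_C: float = 0.054, tau_initial: float = 3.0,
                   tau_decay: float = 0.985) -> float:
    """Advance one cutaneous channel given the net contact force ``F >= 0``.

    The Kalman drive is ``F * 0.5 * s`` where the scalar ``s`` starts at
    ``tau_initial`` on contact onset and decays per step as
    ``s <- 1 + (s - 1) * tau_decay``, resetting on release.  The onset
    response therefore overshoots (1.5 F) and the plateau is exactly 0.5 F.
    """
    in_contact = F > 0.0
    if not in_contact or not frame.cut_contact[limb]:
        frame.cut_s[limb] = tau_initial  # reset on release and (re)onset
    drive = F * 0.5 * frame.cut_s[limb]
    if in_contact:  # decay toward 1 for the next step while contact holds
        frame.cut_s[limb] = 1.0 + (frame.cut_s[limb] - 1.0) * tau_decay
    frame.cut_contact[limb] = in_contact
    frame.cut_y[limb] = kalman(frame.cut_y[limb], drive, K_C)
    frame.cutaneous[limb] = frame.cut_y[limb]
    return frame.cutaneous[limb]


def sense(frame: SensorFrame, L: np.ndarray, V: np.ndarray, A: np.ndarray,
          f_cut: np.ndarray, *, K_C: float = 0.054, tau_initial: float = 3.0,
          tau_decay: float = 0.985) -> SensorFrame:
    """Update all 14 afferents in place from the current muscle kinematics
    and contact forces, and return the frame."""
    frame.ii = spindle_ii(L, A)
    frame.ia = spindle_ia(A, V, frame.ii)
    frame.ib = spindle_ib(L, A)
    for limb in (0, 1):
        cutaneous_step(frame, float(f_cut[limb]), limb, K_C=K_C,
                       tau_initial=tau_initial, tau_decay=tau_decay)
    return frame
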