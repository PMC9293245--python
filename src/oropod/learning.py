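"""Hebbian calcium-covariance plasticity with a compensation factor.

Every learnable synapse carries a slowly filtered learning signal

    l_ij = phiK(P_j+ * w_ij * (phiL(P_i) - Pbar_i), K_L)

whose sign encodes the covariance between presynaptic activity and the
deviation of the postsynaptic somatic signal from its long-term mean.  The
somatic signal is slightly high-pass filtered for excitatory sources
(faster supralinear calcium transient) and low-pass filtered for inhibitory
sources.  The weight update

    dw_ij = l_ij * eta_i * c_ij,   c_ij = 1 - w_ij if l_ij >= 0 else w_ij

is bounded so weights stay in [0, 1] without clipping, and the learning
rate eta_i = min(Pbar_i^4 * 0.01, 0.001) gates learning by the neuron's own
mean activity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig
from .network import N_NEURONS, N_SOURCES, Topology, NeuronState

__all__ = [
    "filter_alpha", "LearningState", "phi_L", "learning_signal",
    "compensation", "learning_rate", "mean_activity_update", "apply_update",
    "learning_step",
]


def filter_alpha(f_cutoff: float, dt: float) -> float:
    """Per-step coefficient of a first-order filter with the given -3 dB
    cutoff: ``alpha = 1 - exp(-2 pi f dt)``."""
    return 1.0 - float(np.exp(-2.0 * np.pi * f_cutoff * dt))


@dataclass
class LearningState:
    """Per-synapse learning signals and the per-neuron phi_L filter memories.

    ``lp_hp`` is the slow low-pass whose complement forms the high-pass
    (excitatory) variant; ``lp`` is the low-pass (inhibitory) variant.
    """

    l: np.ndarray = field(default_factory=lambda: np.zeros((N_NEURONS, N_SOURCES)))
    lp_hp: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))
    lp: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))

    def copy(self) -> "LearningState":
        return LearningState(l=self.l.copy(), lp_hp=self.lp_hp.copy(),
                             lp=self.lp.copy())


def phi_L(P: np.ndarray, state: LearningState, *, alpha_hp: float,
          alpha_lp: float) -> tuple[np.ndarray, np.ndarray]:
    """Advance both phi_L filters on the somatic potentials and return the
    (excitatory high-pass, inhibitory low-pass) outputs."""
    state.lp_hp += alpha_hp * (P - state.lp_hp)
    state.lp += alpha_lp * (P - state.lp)
    return P - state.lp_hp, state.lp.copy()


def learning_signal(l: np.ndarray, u_plus: np.ndarray, W: np.ndarray,
                    post_dev: np.ndarray, K_L: float) -> np.ndarray:
    """Kalman-filtered per-synapse covariance drive, clamped to [-1, 1].

    ``post_dev[i, j]`` is ``phiL(P_i) - Pbar_i`` with the filter variant
    chosen by the sign of source *j*.
    """
    drive = u_plus[None, :] * W * post_dev
    l = l + K_L * (drive - l)
    return np.clip(l, -1.0, 1.0)


def compensation(W: np.ndarray, l: np.ndarray) -> np.ndarray:
    """Distance to the bound being approached: 1 - w for potentiation,
    w for depression.  This alone keeps weights inside [0, 1]."""
    return np.where(l >= 0.0, 1.0 - W, W)


def learning_rate(P_bar: np.ndarray, *, slope: float = 0.04,
                  ceiling: float = 0.001) -> np.ndarray:
    """eta = mean_activity * slope, clipped to the published ceiling.

    Linear in the neuron's slow mean activity, so a silent neuron cannot
    learn, and saturating at the published maximum once the mean activity
    exceeds ``ceiling / slope`` (0.025 at the defaults).
    """
    return np.minimum(np.asarray(P_bar) * slope, ceiling)


def mean_activity_update(P_plus: np.ndarray, P_bar: np.ndarray,
                         K_M: float = 4.0e-5) -> np.ndarray:
    """Very slow running mean of the positive output (tau ~ 250 s)."""
    return P_bar + K_M * (P_plus - P_bar)


def apply_update(W: np.ndarray, l: np.ndarray, eta: np.ndarray,
                 c: np.ndarray, learnable: np.ndarray) -> np.ndarray:
    """Apply dw = l * eta * c on learnable synapses only (in place)."""
    dW = l * eta[:, None] * c
    W[learnable] += dW[learnable]
    return W


def learning_step(W: np.ndarray, topo: Topology, neurons: NeuronState,
                  state: LearningState, u_plus: np.ndarray, *,
                  cfg: NetworkConfig, dt: float) -> None:
    """One full plasticity step, applied after the activation update.

    Order: phi_L filters advance on the new potentials; the learning signal
    uses the pre-update mean activity; weights update; finally the mean
    activity advances.
    """
    hp, lp = phi_L(neurons.P, state, alpha_hp=filter_alpha(cfg.f_highpass, dt),
                   alpha_lp=filter_alpha(cfg.f_lowpass, dt))
    post = np.where(topo.sign[None, :] > 0, hp[:, None], lp[:, None])
    post_dev = post - neurons.P_bar[:, None]
    state.l = learning_signal(state.l, u_plus, W, post_dev, cfg.gain_learning)
    eta = learning_rate(neurons.P_bar, slope=cfg.eta_slope, ceiling=cfg.eta_max)
    c = compensation(W, state.l)
    apply_update(W, state.l, eta, c, topo.learnable)
    neurons.P_bar = mean_activity_update(neurons.P_plus, neurons.P_bar,
                                         cfg.gain_mean)
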