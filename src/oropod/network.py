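"""The 36-neuron spinal network: topology, seed weights and activation.

Neurons are nonspiking rate units with synaptic shunting and a dynamic
resting leak.  The membrane potential proxy of neuron *i* is

    P_i = phiK(sum_j P_j+ w_ij+ S_ij, K_A) / (k_i + phiK(sum_j P_j+ w_ij+, K_A))

where phiK is the shared 1-D Kalman filter, S the static sign matrix and
k_i the resting leak — twice a slow rolling measure of the summed synaptic
activation, floored at 0.5 and only allowed to grow once an initial
stabilization phase has passed.  The muscle activation is simply the
positive part of the corresponding motoneuron's output.

Source-column layout used throughout the package (50 columns):
0-3 Ia, 4-7 II, 8-11 Ib, 12-13 cutaneous (left, right), 14-17 motoneurons
(never presynaptic to anything, kept for row/column alignment), 18-33
excitatory interneurons, 34-49 inhibitory interneurons.  The per-motoneuron
pattern-generator synapse (fixed weight 1.0) is carried separately.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig

__all__ = [
    "N_AFFERENT", "N_NEURONS", "N_SOURCES",
    "ROW_MN", "ROW_INE", "ROW_INI",
    "COL_AFFERENT", "COL_NEURONS", "COL_IA", "COL_II", "COL_IB", "COL_CUT",
    "COL_MN", "COL_INE", "COL_INI",
    "Topology", "build_topology", "seed_weights",
    "NeuronState", "synaptic_drives", "leak_update", "activation_step",
    "motoneuron_activation", "source_labels",
]

N_AFFERENT = 14
N_NEURONS = 36
N_SOURCES = N_AFFERENT + N_NEURONS  # 50

ROW_MN = slice(0, 4)
ROW_INE = slice(4, 20)
ROW_INI = slice(20, 36)

COL_IA = slice(0, 4)
COL_II = slice(4, 8)
COL_IB = slice(8, 12)
COL_CUT = slice(12, 14)
COL_AFFERENT = slice(0, 14)
COL_NEURONS = slice(14, 50)
COL_MN = slice(14, 18)
COL_INE = slice(18, 34)
COL_INI = slice(34, 50)


def source_labels() -> list[str]:
    """Human-readable names of the 50 source columns (plus use + 'APG')."""
    muscles = ("LE", "LF", "RE", "RF")
    labels = [f"Ia-{m}" for m in muscles] + [f"II-{m}" for m in muscles]
    labels += [f"Ib-{m}" for m in muscles] + ["C-left", "C-right"]
    labels += [f"MN-{m}" for m in muscles]
    labels += [f"INe{i}" for i in range(16)] + [f"INi{i}" for i in range(16)]
    return labels


@dataclass
class Topology:
    """Static wiring of the network.

    ``adjacency[i, j]`` — synapse from source column *j* onto neuron row *i*
    exists; ``sign[j]`` — +1 for excitatory sources (afferents, INe), -1
    for inhibitory (INi); ``frozen`` — synapses exempt from learning (the
    Ia->MN block preset by the earlier critical period).  ``learnable`` is
    ``adjacency & ~frozen``.
    """

    adjacency: np.ndarray
    sign: np.ndarray
    frozen: np.ndarray
    learnable: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.learnable = self.adjacency & ~self.frozen

    def synapse_counts(self) -> np.ndarray:
        """Incoming synapses per neuron, counting the pattern-generator
        synapse of each motoneuron."""
        counts = self.adjacency.sum(axis=1)
        counts[ROW_MN] += 1
        return counts


def build_topology(cfg: NetworkConfig | None = None) -> Topology:
    """Construct the adjacency, sign and frozen masks.

    Motoneurons receive the four Ia afferents plus all 32 interneurons
    (37 synapses counting the pattern generator); interneurons receive all
    14 primary afferents plus the 31 other interneurons (45 synapses).
    """
    cfg = cfg or NetworkConfig()
    adj = np.zeros((N_NEURONS, N_SOURCES), dtype=bool)
    adj[ROW_MN, COL_IA] = True
    adj[ROW_MN, COL_INE] = True
    adj[ROW_MN, COL_INI] = True
    adj[ROW_INE, COL_AFFERENT] = True
    adj[ROW_INI, COL_AFFERENT] = True
    adj[ROW_INE, COL_INE] = True
    adj[ROW_INE, COL_INI] = True
    adj[ROW_INI, COL_INE] = True
    adj[ROW_INI, COL_INI] = True
    for i in range(32):  # no self-synapses among interneurons
        adj[4 + i, 18 + i] = False

    sign = np.ones(N_SOURCES)
    sign[COL_INI] = -1.0

    frozen = np.zeros_like(adj)
    frozen[ROW_MN, COL_IA] = True  # entire Ia->MN block preset and fixed
    return Topology(adjacency=adj, sign=sign, frozen=frozen)


def seed_weights(topo: Topology, rng: np.random.Generator,
                 cfg: NetworkConfig | None = None) -> np.ndarray:
    """Seed the weight matrix.

    Learnable weights are drawn from a positive-only normal
    (mean ``seed_mean``, SD ``seed_sd``); draws below ``seed_floor`` are
    redrawn.  Homonymous Ia->MN weights are set to 1.0 and heteronymous
    ones to the configured residual, both frozen.
    """
    cfg = cfg or NetworkConfig()
    W = np.zeros((N_NEURONS, N_SOURCES))
    n = int(topo.learnable.sum())
    draws = rng.normal(cfg.seed_mean, cfg.seed_sd, size=n)
    bad = draws < cfg.seed_floor
    while bad.any():
        draws[bad] = rng.normal(cfg.seed_mean, cfg.seed_sd, size=int(bad.sum()))
        bad = draws < cfg.seed_floor
    W[topo.learnable] = draws

    W[ROW_MN, COL_IA] = cfg.heteronymous_ia
    for m in range(4):
        W[m, m] = 1.0  # homonymous Ia
    return W


@dataclass
class NeuronState:
    """Per-neuron dynamic state (potentials, filters, leak, mean activity)."""

    P: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))
    P_plus: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))
    num_y: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))
    den_y: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))
    k: np.ndarray = field(default_factory=lambda: np.full(N_NEURONS, 0.5))
    leak_y: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))
    P_bar: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))

    def copy(self) -> "NeuronState":
        return NeuronState(**{k: v.copy() for k, v in self.__dict__.items()})


def synaptic_drives(W: np.ndarray, sign: np.ndarray, u_plus: np.ndarray,
                    apg_drive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed and unsigned summed synaptic activation per neuron.

    ``u_plus`` is the rectified 50-element source vector; the fixed-weight
    pattern-generator drive is added to the first four (motoneuron) rows of
    both sums.
    """
    num = W @ (u_plus * sign)
    den = W @ u_plus
    num[:4] += apg_drive
    den[:4] += apg_drive
    return num, den


def leak_update(state: NeuronState, den_drive: np.ndarray, step_index: int,
                stabilization_steps: int, cfg: NetworkConfig) -> None:
    """Advance the dynamic resting leak.

    The leak target is ``leak_scale`` times a slow rolling measure (Kalman
    gain ``gain_mean``) of the unsigned summed synaptic activation, floored
    at ``leak_floor``.  During the stabilization phase the leak tracks the
    target freely; afterwards it is monotone non-decreasing.
    """
    state.leak_y += cfg.gain_mean * (den_drive - state.leak_y)
    target = np.maximum(cfg.leak_floor, cfg.leak_scale * state.leak_y)
    if step_index < stabilization_steps:
        state.k = target
    else:
        state.k = np.maximum(state.k, target)


def activation_step(state: NeuronState, u_plus: np.ndarray, W: np.ndarray,
                    sign: np.ndarray, apg_drive: np.ndarray, *,
                    step_index: int, stabilization_steps: int,
                    cfg: NetworkConfig) -> NeuronState:
    """One synchronous update of all neuron potentials.

    Both the numerator (signed) and denominator (unsigned) drives pass
    through independent Kalman filters with gain ``gain_activity``; the
    leak is updated before the division.  |P| <= 1 holds because the
    filtered numerator magnitude never exceeds the filtered denominator.
    """
    num, den = synaptic_drives(W, sign, u_plus, apg_drive)
    state.num_y += cfg.gain_activity * (num - state.num_y)
    state.den_y += cfg.gain_activity * (den - state.den_y)
    leak_update(state, den, step_index, stabilization_steps, cfg)
    P = state.num_y / (state.k + state.den_y)
    state.P = np.clip(P, -1.0, 1.0)
    state.P_plus = np.maximum(state.P, 0.0)
    return state


def motoneuron_activation(state: NeuronState) -> np.ndarray:
    """Muscle activations: the positive part of the motoneuron outputs."""
    return state.P_plus[:4].copy()
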