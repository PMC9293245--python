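"""Configuration for the Oropod simulator.

All tunable constants of the model live here, grouped by subsystem, with the
published defaults.  Configurations round-trip through YAML so that an
experiment is fully described by one file plus a seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml

#: Muscle order used everywhere in the package: left extensor, left flexor,
#: right extensor, right flexor.
MUSCLES: Tuple[str, ...] = ("LE", "LF", "RE", "RF")


@dataclass
class MechConfig:
    """Geometry and dynamics of the body, limbs, muscles and walls.

    Each limb lives in its own centered coordinate, bounded by the anatomical
    range ``+-limb_range_max``.  Muscle anchors sit ``anchor_overshoot`` units
    beyond the range so the springs can still pull at the limits.  Only the
    ratio ``muscle_gain / (viscosity_B + damping_D)`` is observable in the
    first-order dynamics; the default calibrates a full-range traversal at
    full activation to roughly 2 s.
    """

    limb_range_max: float = 4.0
    anchor_overshoot: float = 1.0
    #: global x of the left and right wall; just inside the limbs' full
    #: reach so the contact zone is the outermost 0.05 units of travel
    wall_positions: Tuple[float, float] = (-7.45, 7.45)
    #: distance from a limb's local origin to its tip on the global axis
    limb_tip_offset: float = 3.5
    viscosity_B: float = 1.0
    damping_D: float = 2.0
    muscle_gain: float = 3.3
    #: minimum |net wall force| required to move the body (stiction);
    #: reachable only by sustained near-maximal extensor drive
    stiction_threshold: float = 3.0
    #: linear penalty stiffness for limb-limb and limb-wall contact
    contact_stiffness: float = 10.0

    @property
    def anchor_positions(self) -> Tuple[float, float, float, float]:
        """(x_LL, x_LR, x_RL, x_RR) muscle attachment coordinates."""
        a = self.limb_range_max + self.anchor_overshoot
        return (-a, a, -a, a)

    @property
    def L_max(self) -> float:
        """Maximal muscle stretch (span of travel plus anchor overshoot)."""
        return 2.0 * self.limb_range_max + self.anchor_overshoot


@dataclass
class NetworkConfig:
    """Population sizes, filter gains and learning constants.

    The Kalman gains are the dimensionless per-step gains of the shared
    one-dimensional filter; ``f_highpass``/``f_lowpass`` are the -3 dB
    cutoffs (Hz) of the excitatory/inhibitory learning-signal filters.
    """

    n_mn: int = 4
    n_ine: int = 16
    n_ini: int = 16

    gain_activity: float = 0.3       # K_A
    gain_learning: float = 0.001     # K_L
    gain_mean: float = 4.0e-5        # K_M
    gain_cutaneous: float = 0.054    # K_C

    tau_initial: float = 3.0         # cutaneous onset scalar
    tau_decay: float = 0.985         # multiplicative decay per step

    seed_mean: float = 0.2
    seed_sd: float = 0.16
    seed_floor: float = 0.001        # draws below this are redrawn

    eta_slope: float = 0.04          # learning rate = mean_activity * slope
    eta_max: float = 0.001           # Table range ceiling

    f_highpass: float = 0.05         # Hz, EPSP learning-signal filter
    f_lowpass: float = 0.2           # Hz, IPSP learning-signal filter

    leak_floor: float = 0.5
    leak_scale: float = 2.0          # leak = scale * rolling summed activation
    #: frozen heteronymous Ia->MN weight (residual of the earlier
    #: critical-period learning; 0 means only homonymous Ia synapses remain)
    heteronymous_ia: float = 0.0

    @property
    def n_neurons(self) -> int:
        return self.n_mn + self.n_ine + self.n_ini


@dataclass
class APGConfig:
    """Stochastic twitch generator settings (the motor-babbling drive)."""

    p_activation: float = 0.5
    amplitude_range: Tuple[float, float] = (0.0, 1.0)
    duration_range: Tuple[float, float] = (0.050, 0.500)   # seconds
    gain_range: Tuple[float, float] = (0.5, 0.8)           # Kalman rise gain
    max_overlap: int = 4       # concurrent decaying twitch tails per muscle
    tail_cutoff: float = 1e-4  # a tail below this is considered extinguished


@dataclass
class SimConfig:
    """Top-level simulation settings (time step, durations, seeds)."""

    dt: float = 0.010
    T_train: float = 400_000.0
    checkpoint_interval: float = 500.0
    stabilization_T: float = 30_000.0
    seed: int = 0
    test_timepoints: Tuple[float, ...] = tuple(
        float(t) for t in range(0, 400_001, 50_000)
    )
    mech: MechConfig = field(default_factory=MechConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    apg: APGConfig = field(default_factory=APGConfig)

    @property
    def stabilization_steps(self) -> int:
        return int(round(self.stabilization_T / self.dt))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        mech = MechConfig(**_tupled(d.pop("mech", {}), "wall_positions"))
        network = NetworkConfig(**d.pop("network", {}))
        apg = _tupled(d.pop("apg", {}), "amplitude_range", "duration_range",
                      "gain_range")
        d = _tupled(d, "test_timepoints")
        return cls(mech=mech, network=network, apg=APGConfig(**apg), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _tupled(d: dict, *keys: str) -> dict:
    d = dict(d)
    for k in keys:
        if k in d:
            d[k] = tuple(d[k])
    return d


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
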