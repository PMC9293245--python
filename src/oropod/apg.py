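"""Autonomous activity pattern generators.

Training drive is produced by a stochastic *twitch* generator emulating
fetal motor babbling: each muscle independently runs a renewal process of
epochs with uniformly sampled duration (50-500 ms); with probability
``p_activation`` an epoch carries a twitch (uniform amplitude 0-1, uniform
Kalman rise gain 0.5-0.8), otherwise the muscle rests for the epoch.  Each
twitch is an internal square pulse fed through its own 1-D Kalman filter,
so overlapping decay tails can coexist; the per-muscle drive saturates
at 1.

Testing drive comes from three deterministic *phasic* programs (in-phase,
symmetrical, right-wave): smooth alternating raised-sine pulses with a 4-s
core cycle, three cycles preceded by one initiation cycle (16 s total).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .config import APGConfig

__all__ = [
    "TwitchEvent", "TwitchScheduler", "TwitchSlots", "twitch_output",
    "PhasicProgram", "phasic_output", "build_programs", "PROGRAM_NAMES",
]


@dataclass
class TwitchEvent:
    """A single scheduled muscle twitch."""

    muscle: int          # 0..3 in (LE, LF, RE, RF) order
    onset: float         # s
    duration: float      # s
    amplitude: float     # 0..1
    rise_gain: float     # Kalman gain of the rise/decay filter


class TwitchScheduler:
    """Seed-deterministic stream of twitch events.

    Each muscle owns an independent child generator spawned from the master
    seed sequence, so the schedules of the four muscles are independent and
    insensitive to how often the other muscles are queried.
    """

    def __init__(self, cfg: APGConfig, seed_seq: np.random.SeedSequence):
        self.cfg = cfg
        self.rngs = [np.random.Generator(np.random.PCG64(s))
                     for s in seed_seq.spawn(4)]
        self.next_epoch = np.zeros(4)

    def advance(self, t_end: float) -> list[TwitchEvent]:
        """Emit all twitches with onset in [current position, t_end),
        advancing each muscle's renewal process up to ``t_end``."""
        cfg = self.cfg
        events: list[TwitchEvent] = []
        for m in range(4):
            rng = self.rngs[m]
            while self.next_epoch[m] < t_end:
                duration = rng.uniform(*cfg.duration_range)
                active = rng.random() < cfg.p_activation
                if active:
                    amplitude = rng.uniform(*cfg.amplitude_range)
                    gain = rng.uniform(*cfg.gain_range)
                    events.append(TwitchEvent(
                        muscle=m, onset=self.next_epoch[m],
                        duration=duration, amplitude=amplitude,
                        rise_gain=gain))
                self.next_epoch[m] += duration
        events.sort(key=lambda e: (e.onset, e.muscle))
        return events

    def state_dict(self) -> dict:
        return {
            "next_epoch": self.next_epoch.tolist(),
            "rng_states": [rng.bit_generator.state for rng in self.rngs],
        }

    def load_state_dict(self, d: dict) -> None:
        self.next_epoch = np.asarray(d["next_epoch"], dtype=float)
        for rng, st in zip(self.rngs, d["rng_states"]):
            rng.bit_generator.state = st


@dataclass
class TwitchSlots:
    """Active twitch filter states, a fixed number of slots per muscle.

    A slot holds one event's Kalman memory; the pulse is the amplitude
    while the event lasts and zero afterwards, and the slot frees itself
    once its decay tail is extinguished.
    """

    n_slots: int = 4
    y: np.ndarray = field(default=None)
    amplitude: np.ndarray = field(default=None)
    gain: np.ndarray = field(default=None)
    end_step: np.ndarray = field(default=None)
    active: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        shape = (4, self.n_slots)
        if self.y is None:
            self.y = np.zeros(shape)
            self.amplitude = np.zeros(shape)
            self.gain = np.zeros(shape)
            self.end_step = np.zeros(shape, dtype=np.int64)
            self.active = np.zeros(shape, dtype=bool)

    def copy(self) -> "TwitchSlots":
        out = TwitchSlots(n_slots=self.n_slots)
        for name in ("y", "amplitude", "gain", "end_step", "active"):
            setattr(out, name, getattr(self, name).copy())
        return out

    def activate(self, muscle: int, amplitude: float, gain: float,
                 end_step: int) -> None:
        """Claim a free slot (or evict the one ending soonest)."""
        free = np.flatnonzero(~self.active[muscle])
        slot = free[0] if free.size else int(np.argmin(self.end_step[muscle]))
        self.y[muscle, slot] = 0.0
        self.amplitude[muscle, slot] = amplitude
        self.gain[muscle, slot] = gain
        self.end_step[muscle, slot] = end_step
        self.active[muscle, slot] = True


def twitch_output(slots: TwitchSlots, step_index: int,
                  tail_cutoff: float = 1e-4) -> np.ndarray:
    """Advance all active slot filters one step and return the per-muscle
    drive (saturating sum of slot outputs, in [0, 1])."""
    drive = np.zeros(4)
    for m in range(4):
        for s in range(slots.n_slots):
            if not slots.active[m, s]:
                continue
            pulse = slots.amplitude[m, s] if step_index < slots.end_step[m, s] else 0.0
            slots.y[m, s] += slots.gain[m, s] * (pulse - slots.y[m, s])
            if pulse == 0.0 and slots.y[m, s] < tail_cutoff:
                slots.active[m, s] = False
                slots.y[m, s] = 0.0
            else:
                drive[m] += slots.y[m, s]
    return np.minimum(drive, 1.0)


PROGRAM_NAMES = ("in_phase", "symmetrical", "right_wave")


@dataclass
class PhasicProgram:
    """Deterministic per-muscle activation envelopes for testing.

    ``offsets`` are phase offsets in cycle fractions, ``amplitudes`` peak
    activations, both in (LE, LF, RE, RF) order.  The program runs
    ``n_cycles`` cycles of ``cycle_s`` seconds; the first cycle initiates
    the system into a steady state and is excluded from analysis.
    """

    name: str
    offsets: tuple = (0.0, 0.5, 0.0, 0.5)
    amplitudes: tuple = (1.0, 1.0, 1.0, 1.0)
    cycle_s: float = 4.0
    n_cycles: int = 4
    duty: float = 0.5

    @property
    def duration(self) -> float:
        return self.cycle_s * self.n_cycles

    def envelope(self, t: float) -> np.ndarray:
        """Per-muscle drive at time ``t`` (zero outside the program)."""
        if t < 0.0 or t >= self.duration:
            return np.zeros(4)
        phase = (t / self.cycle_s) % 1.0
        out = np.zeros(4)
        for m in range(4):
            ph = (phase - self.offsets[m]) % 1.0
            if ph < self.duty:
                out[m] = self.amplitudes[m] * np.sin(np.pi * ph / self.duty) ** 2
        return out

    def drive_array(self, dt: float) -> np.ndarray:
        """The full (n_steps, 4) drive sampled at the simulation step."""
        n = int(round(self.duration / dt))
        return np.stack([self.envelope(i * dt) for i in range(n)])


def phasic_output(program: PhasicProgram, t: float) -> np.ndarray:
    """Per-muscle phasic drive at time ``t``."""
    return program.envelope(t)


def build_programs() -> dict[str, PhasicProgram]:
    """The three predefined test-movement programs.

    * ``in_phase`` — homologous muscles of the two limbs share identical
      envelopes (extensors together, then flexors).
    * ``symmetrical`` — the left and right limb envelopes are mirror
      images (one limb's extensor with the other limb's flexor).
    * ``right_wave`` — only the right limb alternates; the left is quiet.
    """
    return {
        "in_phase": PhasicProgram("in_phase", offsets=(0.0, 0.5, 0.0, 0.5)),
        "symmetrical": PhasicProgram("symmetrical", offsets=(0.0, 0.5, 0.5, 0.0)),
        "right_wave": PhasicProgram("right_wave", offsets=(0.0, 0.0, 0.0, 0.5),
                                    amplitudes=(0.0, 0.0, 1.0, 1.0)),
    }
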