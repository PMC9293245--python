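"""The closed sensorimotor loop: plant -> sensors -> network -> muscles.

``Simulation`` bundles all state and exposes three levels of control:

* :meth:`Simulation.step` — one 10-ms iteration composed from the module
  functions (readable reference path, used step-by-step in tests);
* :meth:`Simulation.run` — a block of iterations through the fused numba
  kernel (the production path; equivalent to repeated ``step`` to
  numerical precision, which the test suite pins);
* :meth:`Simulation.run_training` / :meth:`Simulation.run_test_movements`
  — the training protocol (stochastic twitches, checkpointing every
  ``checkpoint_interval``) and the paused-training phasic test protocol
  (plasticity off, training state untouched).

Checkpoints are HDF5 files holding every array bit-exactly plus the
configuration and generator states, so a reloaded simulation reproduces
subsequent trajectories exactly.
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import apg as apg_mod
from . import learning as learning_mod
from . import mechanics as mech_mod
from . import network as net_mod
from . import sensors as sens_mod
from ._kernel import run_chunk
from .config import SimConfig

__all__ = ["Simulation", "History", "save_checkpoint", "load_checkpoint"]

_EMPTY_EVENTS = dict(muscle=np.zeros(0, np.int64), start=np.zeros(0, np.int64),
                     end=np.zeros(0, np.int64), amp=np.zeros(0), gain=np.zeros(0))


@dataclass
class History:
    """Training record: checkpoint times, weight snapshots, kinematics
    summaries and (optionally) phasic-test activity traces per timepoint."""

    times: list = field(default_factory=list)
    weights: list = field(default_factory=list)
    summaries: list = field(default_factory=list)
    test_traces: dict = field(default_factory=dict)

    def weight_change(self, learnable: np.ndarray) -> np.ndarray:
        """Mean |dw| over learnable synapses between consecutive
        checkpoints (one value per window)."""
        out = []
        for a, b in zip(self.weights[:-1], self.weights[1:]):
            out.append(float(np.abs(b - a)[learnable].mean()))
        return np.asarray(out)


class Simulation:
    """A complete Oropod: physical world, sensors, spinal network, drive."""

    def __init__(self, config: SimConfig | None = None):
        cfg = config or SimConfig()
        self.cfg = cfg
        self.topology = net_mod.build_topology(cfg.network)
        master = np.random.SeedSequence(cfg.seed)
        ss_weights, ss_twitch = master.spawn(2)
        self.W = net_mod.seed_weights(
            self.topology, np.random.Generator(np.random.PCG64(ss_weights)),
            cfg.network)
        self.W_seed = self.W.copy()
        self.mech = mech_mod.MechState()
        self.sensors = sens_mod.SensorFrame(
            cut_s=np.full(2, cfg.network.tau_initial))
        self.neurons = net_mod.NeuronState()
        self.learning = learning_mod.LearningState()
        self.scheduler = apg_mod.TwitchScheduler(cfg.apg, ss_twitch)
        self.slots = apg_mod.TwitchSlots(n_slots=cfg.apg.max_overlap)
        self.step_index = 0
        self.plasticity_on = True
        self._pending = {k: v.copy() for k, v in _EMPTY_EVENTS.items()}
        self._last_summary = self._blank_summary()

    # ------------------------------------------------------------------
    @property
    def time(self) -> float:
        return self.step_index * self.cfg.dt

    def clone(self) -> "Simulation":
        return copy.deepcopy(self)

    # ------------------------------------------------------------------
    def _events_to_arrays(self, events) -> dict:
        dt = self.cfg.dt
        mus = np.array([e.muscle for e in events], np.int64)
        start = np.array([int(np.floor(e.onset / dt + 1e-9)) for e in events],
                         np.int64)
        dur = np.array([max(1, int(round(e.duration / dt))) for e in events],
                       np.int64)
        return dict(muscle=mus, start=start, end=start + dur,
                    amp=np.array([e.amplitude for e in events]),
                    gain=np.array([e.rise_gain for e in events]))

    def _fetch_events(self, t_end: float) -> None:
        ev = self._events_to_arrays(self.scheduler.advance(t_end))
        self._pending = {k: np.concatenate([self._pending[k], ev[k]])
                         for k in ev}

    def _pop_events(self, step: int):
        """Activate pending twitches whose onset step is ``step``."""
        start = self._pending["start"]
        take = start <= step
        for m, a, g, e in zip(self._pending["muscle"][take],
                              self._pending["amp"][take],
                              self._pending["gain"][take],
                              self._pending["end"][take]):
            self.slots.activate(int(m), float(a), float(g), int(e))
        keep = ~take
        self._pending = {k: v[keep] for k, v in self._pending.items()}

    # ------------------------------------------------------------------
    def step(self, phasic_drive: np.ndarray | None = None) -> None:
        """One iteration of the loop via the module functions.

        Order within a step: plant update (with the previous step's
        motoneuron output), muscle kinematics, pattern-generator drive,
        sensors, synchronous neuron update, plasticity.
        """
        cfg = self.cfg
        n = self.step_index
        A = net_mod.motoneuron_activation(self.neurons)

        self.mech = mech_mod.step(cfg.mech, self.mech, A, cfg.dt)
        kin = mech_mod.muscle_kinematics(cfg.mech, self.mech, A)

        if phasic_drive is not None:
            drive = np.asarray(phasic_drive, dtype=float)
        else:
            self._fetch_events((n + 1) * cfg.dt)
            self._pop_events(n)
            drive = apg_mod.twitch_output(self.slots, n, cfg.apg.tail_cutoff)

        sens_mod.sense(self.sensors, kin.L, kin.V, A,
                       np.array([self.mech.f_cut_l, self.mech.f_cut_r]),
                       K_C=cfg.network.gain_cutaneous,
                       tau_initial=cfg.network.tau_initial,
                       tau_decay=cfg.network.tau_decay)

        u = np.concatenate([self.sensors.afferent_vector(),
                            self.neurons.P_plus])
        u_plus = np.maximum(u, 0.0)
        net_mod.activation_step(self.neurons, u_plus, self.W,
                                self.topology.sign, drive,
                                step_index=n,
                                stabilization_steps=cfg.stabilization_steps,
                                cfg=cfg.network)
        if self.plasticity_on:
            learning_mod.learning_step(self.W, self.topology, self.neurons,
                                       self.learning, u_plus,
                                       cfg=cfg.network, dt=cfg.dt)
        self.step_index = n + 1

    # ------------------------------------------------------------------
    def _mech_array(self) -> np.ndarray:
        m = self.mech
        return np.array([m.x_l, m.x_r, m.v_l, m.v_r, m.x_body, m.v_body,
                         m.f_lw, m.f_rw, m.f_c, m.f_cut_l, m.f_cut_r])

    def _set_mech(self, a: np.ndarray) -> None:
        self.mech = mech_mod.MechState(*[float(x) for x in a])

    def run(self, duration: float, *, record: bool = False,
            phasic: np.ndarray | None = None,
            plasticity: bool | None = None) -> np.ndarray | None:
        """Advance ``duration`` seconds through the fused kernel.

        With ``phasic`` (an (n_steps, 4) drive array) the twitch generator
        is bypassed.  With ``record`` the positive output of all 36
        neurons is returned, one row per step.  Returns the recording or
        ``None``.
        """
        cfg = self.cfg
        net = cfg.network
        n_steps = int(round(duration / cfg.dt))
        if plasticity is None:
            plasticity = self.plasticity_on
        use_phasic = phasic is not None
        if use_phasic:
            phasic = np.ascontiguousarray(phasic, dtype=float)
            if phasic.shape[0] < n_steps:
                raise ValueError("phasic drive shorter than the run")
            ev = {k: v.copy() for k, v in _EMPTY_EVENTS.items()}
        else:
            self._fetch_events((self.step_index + n_steps) * cfg.dt)
            ev = self._pending
            self._pending = {k: v.copy() for k, v in _EMPTY_EVENTS.items()}
        rec = np.zeros((n_steps if record else 0, net_mod.N_NEURONS))
        summary = self._blank_summary()
        mech = self._mech_array()
        ev_ptr = np.zeros(1, np.int64)
        bad = run_chunk(
            n_steps, self.step_index, cfg.stabilization_steps, cfg.dt,
            cfg.mech.viscosity_B, cfg.mech.damping_D, cfg.mech.muscle_gain,
            cfg.mech.limb_range_max + cfg.mech.anchor_overshoot,
            cfg.mech.limb_tip_offset, cfg.mech.wall_positions[0],
            cfg.mech.wall_positions[1], cfg.mech.contact_stiffness,
            cfg.mech.stiction_threshold, cfg.mech.limb_range_max,
            net.gain_activity, net.gain_learning, net.gain_mean,
            net.gain_cutaneous, net.tau_initial, net.tau_decay,
            learning_mod.filter_alpha(net.f_highpass, cfg.dt),
            learning_mod.filter_alpha(net.f_lowpass, cfg.dt),
            net.eta_slope, net.eta_max, net.leak_floor, net.leak_scale,
            plasticity, use_phasic, record,
            mech,
            self.sensors.ia, self.sensors.ii, self.sensors.ib,
            self.sensors.cutaneous, self.sensors.cut_y, self.sensors.cut_s,
            self.sensors.cut_contact,
            self.W, self.topology.sign, self.topology.learnable,
            self.neurons.P, self.neurons.P_plus, self.neurons.num_y,
            self.neurons.den_y, self.neurons.k, self.neurons.leak_y,
            self.neurons.P_bar,
            self.learning.l, self.learning.lp_hp, self.learning.lp,
            self.slots.y, self.slots.amplitude, self.slots.gain,
            self.slots.end_step, self.slots.active, cfg.apg.tail_cutoff,
            ev["muscle"], ev["start"], ev["end"], ev["amp"], ev["gain"],
            ev_ptr,
            phasic if use_phasic else np.zeros((0, 4)),
            rec, summary,
        )
        if bad >= 0:
            raise FloatingPointError(
                f"non-finite mechanical state at step {bad}")
        self._set_mech(mech)
        self.step_index += n_steps
        self._last_summary = summary
        return rec if record else None

    @staticmethod
    def _blank_summary() -> np.ndarray:
        s = np.zeros(9)
        s[2] = s[4] = np.inf
        s[3] = s[5] = -np.inf
        return s

    # ------------------------------------------------------------------
    def run_training(self, T: float | None = None, *,
                     test_timepoints=None, collect_tests: bool = False,
                     programs=None) -> History:
        """Run the twitch-driven training protocol.

        Checkpoints (time, weight snapshot, kinematics summary) are taken
        every ``checkpoint_interval``.  With ``collect_tests`` the phasic
        test battery runs on a throwaway clone at each test timepoint
        (rounded to the checkpoint grid), leaving training untouched.
        """
        cfg = self.cfg
        T = cfg.T_train if T is None else T
        chunk = cfg.checkpoint_interval
        n_chunks = int(round(T / chunk))
        if test_timepoints is None:
            test_timepoints = cfg.test_timepoints
        grid = {int(round(t / chunk)) for t in test_timepoints} \
            if collect_tests else set()

        hist = History()
        hist.times.append(self.time)
        hist.weights.append(self.W.copy())
        start_chunk = int(round(self.time / chunk))
        if collect_tests and start_chunk in grid:
            hist.test_traces[self.time] = self.run_test_movements(programs)
        for c in range(start_chunk, start_chunk + n_chunks):
            self.run(chunk)
            hist.times.append(self.time)
            hist.weights.append(self.W.copy())
            hist.summaries.append(self._last_summary.copy())
            if collect_tests and (c + 1) in grid:
                hist.test_traces[self.time] = self.run_test_movements(programs)
        return hist

    def run_test_movements(self, programs=None) -> dict:
        """Execute the phasic test programs on a clone with plasticity off.

        Returns ``{program name: (n_steps, 32) interneuron activity}``;
        the caller is responsible for excluding the initiation cycle from
        analysis windows.  Training state is untouched.
        """
        programs = programs or apg_mod.build_programs()
        out = {}
        for name, prog in programs.items():
            sim = self.clone()
            sim.plasticity_on = False
            rec = sim.run(prog.duration, record=True,
                          phasic=prog.drive_array(self.cfg.dt),
                          plasticity=False)
            out[name] = rec[:, 4:36]
        return out

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        save_checkpoint(self, path)

    @classmethod
    def load(cls, path) -> "Simulation":
        return load_checkpoint(path)


def save_checkpoint(sim: Simulation, path) -> None:
    """Serialize the full simulation state to HDF5 (bit-exact arrays plus
    JSON sidecar attributes for config and generator states)."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(sim.cfg.to_dict())
        f.attrs["scheduler"] = json.dumps(sim.scheduler.state_dict())
        f.attrs["step_index"] = sim.step_index
        f.attrs["plasticity_on"] = sim.plasticity_on
        f.create_dataset("mech", data=sim._mech_array())
        f.create_dataset("W", data=sim.W)
        f.create_dataset("W_seed", data=sim.W_seed)
        g = f.create_group("sensors")
        for name in ("ia", "ii", "ib", "cutaneous", "cut_y", "cut_s",
                     "cut_contact"):
            g.create_dataset(name, data=getattr(sim.sensors, name))
        g = f.create_group("neurons")
        for name in ("P", "P_plus", "num_y", "den_y", "k", "leak_y", "P_bar"):
            g.create_dataset(name, data=getattr(sim.neurons, name))
        g = f.create_group("learning")
        for name in ("l", "lp_hp", "lp"):
            g.create_dataset(name, data=getattr(sim.learning, name))
        g = f.create_group("slots")
        for name in ("y", "amplitude", "gain", "end_step", "active"):
            g.create_dataset(name, data=getattr(sim.slots, name))
        g = f.create_group("pending")
        for name, arr in sim._pending.items():
            g.create_dataset(name, data=arr)


def load_checkpoint(path) -> Simulation:
    """Rebuild a :class:`Simulation` from :func:`save_checkpoint` output."""
    with h5py.File(path, "r") as f:
        cfg = SimConfig.from_dict(json.loads(f.attrs["config"]))
        sim = Simulation(cfg)
        sim.scheduler.load_state_dict(json.loads(f.attrs["scheduler"]))
        sim.step_index = int(f.attrs["step_index"])
        sim.plasticity_on = bool(f.attrs["plasticity_on"])
        sim._set_mech(f["mech"][...])
        sim.W = f["W"][...]
        sim.W_seed = f["W_seed"][...]
        for name in ("ia", "ii", "ib", "cutaneous", "cut_y", "cut_s"):
            setattr(sim.sensors, name, f["sensors"][name][...])
        sim.sensors.cut_contact = f["sensors"]["cut_contact"][...].astype(bool)
        for name in ("P", "P_plus", "num_y", "den_y", "k", "leak_y", "P_bar"):
            setattr(sim.neurons, name, f["neurons"][name][...])
        for name in ("l", "lp_hp", "lp"):
            setattr(sim.learning, name, f["learning"][name][...])
        for name in ("y", "amplitude", "gain", "end_step"):
            setattr(sim.slots, name, f["slots"][name][...])
        sim.slots.active = f["slots"]["active"][...].astype(bool)
        sim._pending = {name: f["pending"][name][...]
                        for name in ("muscle", "start", "end", "amp", "gain")}
    return sim
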