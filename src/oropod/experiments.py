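"""Canned experiment protocols and ensemble summaries.

``run_session`` executes one complete scaled training session — twitch
training with periodic checkpoints, the phasic test battery at evenly
spaced timepoints — and computes the connectivity and cooperativity
diagnostics for that session.  ``run_ensemble`` repeats it over seeds and
aggregates the across-seed statistics that characterize the outcome of
learning (explained variance of input connectivity, 95% dimensionality,
archetype prevalence, distance traveled in activity space).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis as an
from .config import SimConfig
from .engine import Simulation

__all__ = ["SessionResult", "run_session", "run_ensemble", "ensemble_summary"]


@dataclass
class SessionResult:
    """Diagnostics of one training session."""

    seed: int
    times: np.ndarray                 # checkpoint times, s
    weight_change: np.ndarray         # mean |dw| per checkpoint window
    pca: dict                         # group -> analysis.PCAResult
    archetype_counts: dict            # class -> classified neurons
    multi_classified: int
    coop: an.CooperativityResult      # joint PCA over timepoints x programs
    coop_by_timepoint: dict           # timepoint -> mean distance traveled
    timepoints: tuple = ()

    @property
    def coop_untrained(self) -> float:
        return self.coop_by_timepoint[min(self.coop_by_timepoint)]

    @property
    def coop_trained(self) -> float:
        return self.coop_by_timepoint[max(self.coop_by_timepoint)]


def _timepoints(T: float, n: int, grid: float) -> tuple:
    pts = np.linspace(0.0, T, n)
    return tuple(float(np.round(p / grid) * grid) for p in pts)


def run_session(seed: int, T: float = 50_000.0, n_timepoints: int = 9,
                config: SimConfig | None = None) -> SessionResult:
    """One scaled training session plus its full analysis battery."""
    cfg = config or SimConfig()
    cfg.seed = int(seed)
    tps = _timepoints(T, n_timepoints, cfg.checkpoint_interval)
    sim = Simulation(cfg)
    hist = sim.run_training(T, collect_tests=True, test_timepoints=tps)

    pca = {}
    for group in ("mn", "ine", "ini"):
        pca[group] = an.connectivity_pca(
            an.group_input_matrix(sim.W, group),
            seed_X=an.group_input_matrix(sim.W_seed, group))

    cm = an.ConnectivityMatrix.from_simulation(sim)
    cls = an.classify_archetypes(an.archetype_distances(cm))

    traces = {(tp, name): tr
              for tp, by_prog in hist.test_traces.items()
              for name, tr in by_prog.items()}
    init_steps = int(round(4.0 / cfg.dt))  # initiation cycle excluded
    coop = an.cooperativity(traces, exclude_steps=init_steps)
    by_tp: dict = {}
    for (tp, _name), dist in coop.distances.items():
        by_tp.setdefault(tp, []).append(dist)
    by_tp = {tp: float(np.mean(v)) for tp, v in by_tp.items()}

    return SessionResult(
        seed=seed, times=np.asarray(hist.times),
        weight_change=hist.weight_change(sim.topology.learnable),
        pca=pca, archetype_counts=cls.counts,
        multi_classified=cls.multi_classified(), coop=coop,
        coop_by_timepoint=by_tp, timepoints=tps)


def run_ensemble(seeds, T: float = 50_000.0, n_timepoints: int = 9,
                 config: SimConfig | None = None) -> list[SessionResult]:
    return [run_session(s, T=T, n_timepoints=n_timepoints,
                        config=SimConfig() if config is None else config)
            for s in seeds]


def ensemble_summary(sessions: list[SessionResult]) -> dict:
    """Across-seed means of the headline statistics (percentages on the
    0-100 scale)."""
    def mean(fn):
        return float(np.mean([fn(s) for s in sessions]))

    return {
        "mn_pc12_variance_pct": mean(lambda s: 100 * s.pca["mn"].ratios[:2].sum()),
        "ine_pc12_variance_pct": mean(lambda s: 100 * s.pca["ine"].ratios[:2].sum()),
        "ini_pc12_variance_pct": mean(lambda s: 100 * s.pca["ini"].ratios[:2].sum()),
        "mn_ndim95": mean(lambda s: s.pca["mn"].ndim95),
        "ine_ndim95": mean(lambda s: s.pca["ine"].ndim95),
        "ini_ndim95": mean(lambda s: s.pca["ini"].ndim95),
        "coop_ndim95": mean(lambda s: s.coop.ndim95),
        "coop_pc3_variance_pct": mean(lambda s: 100 * s.coop.pc3_variance),
        "multi_archetype_count": mean(lambda s: s.multi_classified),
        "ib_inhibitory_count": mean(lambda s: s.archetype_counts["ib_inhibitory"]),
        "ia_reciprocal_count": mean(lambda s: s.archetype_counts["ia_reciprocal"]),
        "propriospinal_count": mean(lambda s: s.archetype_counts["propriospinal"]),
        "coop_trained_over_untrained": mean(
            lambda s: s.coop_trained / s.coop_untrained),
        "weight_change_final_over_peak": mean(
            lambda s: s.weight_change[-max(1, len(s.weight_change) // 10):].mean()
            / s.weight_change.max()),
    }
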