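"""Connectivity and population-activity analyses.

Implements the post-training diagnostics: classification of interneurons
against archetypical connectivity templates (Ib inhibitory, Ia reciprocal
inhibitory, propriospinal excitatory), PCA of the synaptic input patterns
per neuron group (explained variance, the number of components needed for
95% of it, seed-to-end distances), grouping of interneurons by their
strongest motoneuron target, relative primary-afferent weight profiles,
and the cooperativity metric: distance traveled by the interneuron
population in PCA activity space during phasic test movements.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import MUSCLES
from .network import (COL_INE, COL_INI, N_AFFERENT, N_NEURONS, ROW_INE,
                      ROW_INI, ROW_MN, Topology, build_topology,
                      source_labels)

__all__ = [
    "ConnectivityMatrix", "ArchetypeTemplate", "build_templates",
    "archetype_distances", "classify_archetypes", "ArchetypeClassification",
    "PCAResult", "connectivity_pca", "group_input_matrix",
    "group_by_target", "relative_pa_weights",
    "CooperativityResult", "cooperativity",
]

#: same-limb antagonist of each muscle in (LE, LF, RE, RF) order
ANTAGONIST = (1, 0, 3, 2)

ARCHETYPE_CLASSES = ("ib_inhibitory", "ia_reciprocal", "propriospinal")


@dataclass
class ConnectivityMatrix:
    """Rows-by-sources weight matrix of the full network (36 x 51).

    Columns are the 50 canonical sources plus the pattern-generator
    synapse; cells that are not synapses are flagged in ``mask``.
    """

    weights: np.ndarray
    mask: np.ndarray
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    @classmethod
    def from_weights(cls, W: np.ndarray,
                     topology: Topology | None = None) -> "ConnectivityMatrix":
        topo = topology or build_topology()
        weights = np.zeros((N_NEURONS, 51))
        weights[:, :50] = W
        weights[:4, 50] = 1.0
        mask = np.zeros((N_NEURONS, 51), dtype=bool)
        mask[:, :50] = topo.adjacency
        mask[:4, 50] = True
        labels = source_labels()
        rows = labels[14:]
        return cls(weights=weights, mask=mask, row_labels=rows,
                   col_labels=labels + ["APG"])

    @classmethod
    def from_simulation(cls, sim) -> "ConnectivityMatrix":
        return cls.from_weights(sim.W, sim.topology)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.weights, index=self.row_labels,
                          columns=self.col_labels)
        return df.mask(~self.mask)

    # -- convenience views ------------------------------------------------
    def interneuron_inputs(self) -> np.ndarray:
        """(32, 14) primary-afferent input weights, INe rows first."""
        return self.weights[4:36, :N_AFFERENT].copy()

    def interneuron_outputs(self) -> np.ndarray:
        """(32, 4) output weights onto the motoneurons."""
        return self.weights[:4, 18:50].T.copy()


@dataclass
class ArchetypeTemplate:
    """A pure input/output connectivity pattern from the literature."""

    archetype: str       # one of ARCHETYPE_CLASSES
    muscle: str          # LE / LF / RE / RF
    inputs: np.ndarray   # (14,) in {0, 1}
    outputs: np.ndarray  # (4,) in {0, 1}
    inhibitory: bool     # which interneuron population is eligible

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.inputs, self.outputs])


def build_templates() -> list[ArchetypeTemplate]:
    """The 12 reference templates (3 classes x 4 muscles).

    Ib inhibitory: Ib input of the muscle, output to its own motoneuron.
    Ia reciprocal inhibitory: Ia input, output to the same-limb antagonist.
    Propriospinal excitatory: convergent Ia and Ib input, homonymous output.
    """
    templates = []
    for m, name in enumerate(MUSCLES):
        inp = np.zeros(N_AFFERENT)
        out = np.zeros(4)
        inp[8 + m] = 1.0
        out[m] = 1.0
        templates.append(ArchetypeTemplate("ib_inhibitory", name, inp, out, True))
    for m, name in enumerate(MUSCLES):
        inp = np.zeros(N_AFFERENT)
        out = np.zeros(4)
        inp[m] = 1.0
        out[ANTAGONIST[m]] = 1.0
        templates.append(ArchetypeTemplate("ia_reciprocal", name, inp, out, True))
    for m, name in enumerate(MUSCLES):
        inp = np.zeros(N_AFFERENT)
        out = np.zeros(4)
        inp[m] = 1.0
        inp[8 + m] = 1.0
        out[m] = 1.0
        templates.append(ArchetypeTemplate("propriospinal", name, inp, out, False))
    return templates


def archetype_distances(cm: ConnectivityMatrix,
                        templates: Sequence[ArchetypeTemplate] | None = None
                        ) -> pd.DataFrame:
    """L2 distances between each interneuron's actual 18-value
    input/output vector and each sign-compatible template.

    Tidy frame with columns (neuron, neuron_type, archetype, muscle,
    distance); sign-mismatched pairings are excluded.
    """
    templates = templates if templates is not None else build_templates()
    inputs = cm.interneuron_inputs()
    outputs = cm.interneuron_outputs()
    vectors = np.hstack([inputs, outputs])  # (32, 18)
    rows = []
    for idx in range(32):
        inhibitory = idx >= 16
        ntype = "INi" if inhibitory else "INe"
        for tpl in templates:
            if tpl.inhibitory != inhibitory:
                continue
            d = float(np.linalg.norm(vectors[idx] - tpl.vector))
            rows.append((idx, ntype, tpl.archetype, tpl.muscle, d))
    return pd.DataFrame(rows, columns=["neuron", "neuron_type", "archetype",
                                       "muscle", "distance"])


@dataclass
class ArchetypeClassification:
    """Outcome of the mean-minus-one-SD classification rule."""

    labels: pd.DataFrame          # one row per (neuron, archetype) label
    thresholds: dict              # archetype -> population threshold
    counts: dict                  # archetype -> number of classified neurons

    def multi_classified(self) -> int:
        """Neurons carrying more than one archetype label."""
        per = self.labels.groupby("neuron").size()
        return int((per > 1).sum())


def classify_archetypes(distances: pd.DataFrame) -> ArchetypeClassification:
    """Label interneurons whose distance to at least one muscle template of
    a class falls below that class's population mean minus one SD.

    The threshold population pools the distances to all four muscle
    templates of the class across all sign-eligible interneurons.  A
    degenerate population (SD = 0) classifies nothing.  A neuron may carry
    several labels; there is no lower bound on weight magnitude.
    """
    labels = []
    thresholds = {}
    counts = {}
    for cls_name, grp in distances.groupby("archetype"):
        d = grp["distance"].to_numpy()
        sd = float(d.std())
        thr = float(d.mean()) - sd
        thresholds[cls_name] = thr
        n_cls = 0
        if sd > 1e-12:  # a degenerate population classifies nothing
            best = grp.loc[grp.groupby("neuron")["distance"].idxmin()]
            hits = best[best["distance"] < thr]
            n_cls = len(hits)
            for _, r in hits.iterrows():
                labels.append((int(r["neuron"]), r["neuron_type"], cls_name,
                               r["muscle"], float(r["distance"])))
        counts[cls_name] = n_cls
    frame = pd.DataFrame(labels, columns=["neuron", "neuron_type",
                                          "archetype", "muscle", "distance"])
    return ArchetypeClassification(labels=frame, thresholds=thresholds,
                                   counts=counts)


# ---------------------------------------------------------------------------
@dataclass
class PCAResult:
    """Explained-variance diagnostics of a set of weight (or activity)
    vectors, plus optional seed-to-end travel distances."""

    ratios: np.ndarray            # explained-variance ratios, ordered
    ndim95: int                   # smallest n with cumulative ratio >= 0.95
    coords: np.ndarray            # per-item coefficients (end state)
    components: np.ndarray
    seed_coords: np.ndarray | None = None
    seed_end_distance: np.ndarray | None = None


def _ndim95(ratios: np.ndarray) -> int:
    return int(np.searchsorted(np.cumsum(ratios), 0.95 - 1e-12) + 1)


def connectivity_pca(X: np.ndarray, seed_X: np.ndarray | None = None
                     ) -> PCAResult:
    """PCA of a neuron group's input-weight vectors.

    Variables are centered but not scaled.  Explained-variance ratios and
    ``ndim95`` describe the end-state vectors ``X``.  When seed vectors
    are supplied, a second PCA fitted on the pooled seed+end vectors
    yields per-neuron Euclidean seed-to-end distances within that pooled
    space truncated at its own 95% dimensionality.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two neurons in the group")
    pca = PCA(svd_solver="full").fit(X)
    ratios = pca.explained_variance_ratio_
    result = PCAResult(ratios=ratios, ndim95=_ndim95(ratios),
                       coords=pca.transform(X), components=pca.components_)
    if seed_X is not None:
        pooled = np.vstack([seed_X, X])
        p2 = PCA(svd_solver="full").fit(pooled)
        nd = _ndim95(p2.explained_variance_ratio_)
        cs = p2.transform(seed_X)[:, :nd]
        ce = p2.transform(X)[:, :nd]
        result.seed_coords = cs
        result.seed_end_distance = np.linalg.norm(ce - cs, axis=1)
    return result


def group_input_matrix(W: np.ndarray, group: str) -> np.ndarray:
    """Input-weight vectors of one neuron group.

    ``"mn"``: the 32 interneuronal inputs of each motoneuron (4 x 32).
    ``"ine"``/``"ini"``: the 14 primary-afferent plus 32 interneuronal
    inputs of each interneuron (16 x 46), with the nonexistent
    self-synapse filled with 1.0 (a neuron is fully correlated with
    itself), making all interneurons comparable in one space.
    """
    if group == "mn":
        return W[ROW_MN, 18:50].copy()
    row0 = {"ine": 4, "ini": 20}[group]
    out = np.zeros((16, N_AFFERENT + 32))
    for i in range(16):
        r = row0 + i
        out[i, :N_AFFERENT] = W[r, :N_AFFERENT]
        out[i, N_AFFERENT:] = W[r, 18:50]
        out[i, N_AFFERENT + (r - 4)] = 1.0  # self
    return out


# ---------------------------------------------------------------------------
def group_by_target(cm: ConnectivityMatrix) -> pd.DataFrame:
    """Assign each interneuron to the motoneuron receiving its strongest
    output weight and order them LE, LF, RE, RF within INe then INi.

    Ties (including the all-zero case) break toward the lowest motoneuron
    index and are flagged ``weak``.
    """
    outputs = cm.interneuron_outputs()
    rows = []
    for idx in range(32):
        w = outputs[idx]
        target = int(np.argmax(w))
        weak = bool(np.all(w == 0.0))
        rows.append((idx, "INi" if idx >= 16 else "INe",
                     MUSCLES[target], target, float(w[target]), weak))
    df = pd.DataFrame(rows, columns=["neuron", "neuron_type", "target",
                                     "target_index", "weight", "weak"])
    df = df.sort_values(["neuron_type", "target_index", "neuron"],
                        key=lambda s: s.map({"INe": 0, "INi": 1})
                        if s.name == "neuron_type" else s)
    return df.reset_index(drop=True)


def relative_pa_weights(cm: ConnectivityMatrix) -> pd.DataFrame:
    """Per-interneuron primary-afferent weights normalized to sum 1.

    Neurons with zero total afferent weight are flagged and left
    unnormalized (all-zero profile) rather than divided.
    """
    inputs = cm.interneuron_inputs()
    totals = inputs.sum(axis=1)
    profiles = np.zeros_like(inputs)
    nz = totals > 0
    profiles[nz] = inputs[nz] / totals[nz, None]
    cols = [f"{k}-{m}" for k in ("Ia", "II", "Ib") for m in MUSCLES]
    cols += ["C-left", "C-right"]
    df = pd.DataFrame(profiles, columns=cols)
    df.insert(0, "neuron", np.arange(32))
    df.insert(1, "neuron_type", ["INe"] * 16 + ["INi"] * 16)
    df["zero_total"] = ~nz
    return df


# ---------------------------------------------------------------------------
@dataclass
class CooperativityResult:
    """Distance-traveled metric in interneuron activity space."""

    ratios: np.ndarray
    ndim95: int
    pc3_variance: float               # variance captured by the first 3 PCs
    distances: dict                   # trace key -> distance traveled
    coords3: dict                     # trace key -> (n, 3) projection


def cooperativity(traces: Mapping, exclude_steps: int = 400
                  ) -> CooperativityResult:
    """Distance traveled in PCA activity space per movement trace.

    One PCA is fitted jointly on every timestep of every supplied trace
    (after dropping the first ``exclude_steps`` initiation samples of
    each).  For each trace the metric is the summed step-to-step Euclidean
    norm of the coefficients over the first ``ndim95`` components.
    """
    keys = list(traces.keys())
    clipped = {k: np.asarray(traces[k], dtype=float)[exclude_steps:]
               for k in keys}
    pooled = np.vstack([clipped[k] for k in keys])
    pca = PCA(svd_solver="full").fit(pooled)
    ratios = pca.explained_variance_ratio_
    nd = _ndim95(ratios)
    distances = {}
    coords3 = {}
    for k in keys:
        c = pca.transform(clipped[k])
        diffs = np.diff(c[:, :nd], axis=0)
        distances[k] = float(np.linalg.norm(diffs, axis=1).sum())
        coords3[k] = c[:, :3]
    return CooperativityResult(ratios=ratios, ndim95=nd,
                               pc3_variance=float(ratios[:3].sum()),
                               distances=distances, coords3=coords3)
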