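"""Archetype classification, connectivity PCA, grouping, cooperativity."""
import numpy as np
import pandas as pd
import pytest

from oropod import analysis as an
from oropod.network import build_topology, seed_weights
from ._oracle import pca_ratios_eig, trajectory_length


@pytest.fixture(scope="module")
def topo():
    return build_topology()


@pytest.fixture(scope="module")
def cm(topo):
    W = seed_weights(topo, np.random.default_rng(8))
    return an.ConnectivityMatrix.from_weights(W, topo)


class TestConnectivityMatrix:
    def test_shape_and_synapse_counts(self, cm):
        assert cm.weights.shape == (36, 51)
        counts = cm.mask.sum(axis=1)
        assert (counts[:4] == 37).all()
        assert (counts[4:] == 45).all()

    def test_views_have_canonical_shapes(self, cm):
        assert cm.interneuron_inputs().shape == (32, 14)
        assert cm.interneuron_outputs().shape == (32, 4)

    def test_frame_masks_non_synapses(self, cm):
        df = cm.to_frame()
        assert df.shape == (36, 51)
        assert df.isna().to_numpy().sum() == (36 * 51) - cm.mask.sum()


class TestTemplates:
    def test_twelve_templates_three_classes_four_muscles(self):
        templates = an.build_templates()
        assert len(templates) == 12
        by_class = {}
        for t in templates:
            by_class.setdefault(t.archetype, []).append(t.muscle)
        assert set(by_class) == set(an.ARCHETYPE_CLASSES)
        for muscles in by_class.values():
            assert sorted(muscles) == ["LE", "LF", "RE", "RF"]

    def test_ib_template_single_input_single_output(self):
        t = [x for x in an.build_templates()
             if x.archetype == "ib_inhibitory" and x.muscle == "LE"][0]
        assert t.inputs.sum() == 1 and t.inputs[8] == 1.0  # Ib of LE
        assert t.outputs.sum() == 1 and t.outputs[0] == 1.0
        assert t.inhibitory

    def test_reciprocal_template_targets_same_limb_antagonist(self):
        for t in an.build_templates():
            if t.archetype != "ia_reciprocal":
                continue
            m = ["LE", "LF", "RE", "RF"].index(t.muscle)
            assert t.inputs[m] == 1.0 and t.inputs.sum() == 1
            assert t.outputs[an.ANTAGONIST[m]] == 1.0

    def test_propriospinal_has_exactly_two_inputs(self):
        for t in an.build_templates():
            if t.archetype == "propriospinal":
                assert t.inputs.sum() == 2  # convergent Ia and Ib
                assert not t.inhibitory


class TestArchetypeDistances:
    def test_sign_classes_pair_correctly(self, cm):
        d = an.archetype_distances(cm)
        inhib = d[d["archetype"].isin(["ib_inhibitory", "ia_reciprocal"])]
        assert (inhib["neuron_type"] == "INi").all()
        exc = d[d["archetype"] == "propriospinal"]
        assert (exc["neuron_type"] == "INe").all()
        # 16 eligible neurons x 4 muscles per class
        assert d.groupby("archetype").size().eq(64).all()

    def test_perfect_match_has_zero_distance(self, topo):
        W = np.zeros((36, 50))
        # make INi#0 (row 20, source column 34) the pure Ib-LE archetype
        W[20, 8] = 1.0      # Ib of LE in
        W[0, 34] = 1.0      # out to the LE motoneuron
        cm = an.ConnectivityMatrix.from_weights(W, topo)
        d = an.archetype_distances(cm)
        row = d[(d["neuron"] == 16) & (d["archetype"] == "ib_inhibitory")
                & (d["muscle"] == "LE")]
        assert row["distance"].iloc[0] == 0.0

    def test_zero_neuron_distance_is_root_template_norm(self, topo):
        W = np.zeros((36, 50))
        cm = an.ConnectivityMatrix.from_weights(W, topo)
        d = an.archetype_distances(cm)
        assert set(np.round(d["distance"] ** 2).astype(int)) == {2, 3}

    def test_distances_match_scalar_loop_oracle(self, cm):
        d = an.archetype_distances(cm)
        vectors = np.hstack([cm.interneuron_inputs(), cm.interneuron_outputs()])
        for _, r in d.sample(20, random_state=0).iterrows():
            tpl = [t for t in an.build_templates()
                   if t.archetype == r["archetype"] and t.muscle == r["muscle"]][0]
            acc = 0.0
            for a, b in zip(vectors[r["neuron"]], tpl.vector):
                acc += (float(a) - float(b)) ** 2
            assert r["distance"] == pytest.approx(acc ** 0.5, abs=1e-12)


class TestClassification:
    def test_identical_population_classifies_nothing(self, topo):
        W = np.full((36, 50), 0.3)
        cm = an.ConnectivityMatrix.from_weights(W, topo)
        res = an.classify_archetypes(an.archetype_distances(cm))
        assert all(v == 0 for v in res.counts.values())

    def test_planted_archetype_is_the_only_one_classified(self, topo):
        # 15 interchangeable neurons plus one perfect Ib-LE archetype:
        # mean - 1 SD of the pooled distances isolates the plant
        W = np.full((36, 50), 0.25)
        W[23, :14] = 0.0
        W[23, 8] = 1.0       # Ib-LE input only (INi#3, row 23)
        W[:4, 37] = 0.0
        W[0, 37] = 1.0       # output to the LE motoneuron only
        cm = an.ConnectivityMatrix.from_weights(W, topo)
        res = an.classify_archetypes(an.archetype_distances(cm))
        ib = res.labels[res.labels["archetype"] == "ib_inhibitory"]
        assert list(ib["neuron"]) == [19]  # interneuron index 16 + 3
        assert ib["distance"].iloc[0] == 0.0

    def test_threshold_is_mean_minus_one_sd(self, cm):
        d = an.archetype_distances(cm)
        res = an.classify_archetypes(d)
        for cls_name, grp in d.groupby("archetype"):
            x = grp["distance"].to_numpy()
            assert res.thresholds[cls_name] == pytest.approx(x.mean() - x.std())

    def test_multi_label_counting(self):
        labels = pd.DataFrame({
            "neuron": [1, 1, 2], "neuron_type": ["INi"] * 3,
            "archetype": ["ib_inhibitory", "ia_reciprocal", "ib_inhibitory"],
            "muscle": ["LE", "LE", "RF"], "distance": [0.1, 0.2, 0.1]})
        res = an.ArchetypeClassification(labels=labels, thresholds={}, counts={})
        assert res.multi_classified() == 1


class TestConnectivityPCA:
    def test_ratios_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        for shape in ((16, 46), (4, 32), (50, 50)):
            X = rng.random(shape)
            res = an.connectivity_pca(X)
            expected = pca_ratios_eig(X)
            n = min(len(res.ratios), len(expected))
            np.testing.assert_allclose(res.ratios[:n], expected[:n], atol=1e-9)

    def test_one_direction_of_variation_is_rank_one(self):
        # all rows share a base pattern plus a per-row offset along one axis
        X = (np.tile(np.linspace(0, 1, 20), (6, 1))
             + np.outer(np.arange(6), np.ones(20)))
        res = an.connectivity_pca(X)
        assert res.ratios[0] == pytest.approx(1.0)
        assert res.ndim95 == 1

    def test_orthogonal_rows_need_full_centered_rank(self):
        X = np.eye(4)
        res = an.connectivity_pca(X)
        expected = pca_ratios_eig(X)
        np.testing.assert_allclose(res.ratios[:3], expected[:3], atol=1e-12)
        assert res.ndim95 == 3

    def test_seed_equal_end_gives_zero_distance(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 20))
        res = an.connectivity_pca(X, seed_X=X.copy())
        np.testing.assert_allclose(res.seed_end_distance, 0.0, atol=1e-9)

    def test_single_neuron_group_rejected(self):
        with pytest.raises(ValueError):
            an.connectivity_pca(np.ones((1, 5)))

    def test_group_matrices_have_documented_shapes(self, topo):
        W = seed_weights(topo, np.random.default_rng(1))
        assert an.group_input_matrix(W, "mn").shape == (4, 32)
        for g in ("ine", "ini"):
            X = an.group_input_matrix(W, g)
            assert X.shape == (16, 46)
        # self-synapse cells filled with 1.0
        X = an.group_input_matrix(W, "ine")
        for i in range(16):
            assert X[i, 14 + i] == 1.0


class TestGrouping:
    def test_strongest_projection_wins(self, topo):
        W = np.zeros((36, 50))
        W[:4, 18] = [0.9, 0.1, 0.0, 0.0]   # INe#0 -> LE
        W[:4, 34] = [0.0, 0.2, 0.0, 0.6]   # INi#0 -> RF
        cm = an.ConnectivityMatrix.from_weights(W, topo)
        df = an.group_by_target(cm)
        assert df[df["neuron"] == 0]["target"].iloc[0] == "LE"
        assert df[df["neuron"] == 16]["target"].iloc[0] == "RF"

    def test_all_zero_outputs_flagged_weak_and_tie_break_low_index(self, topo):
        W = np.zeros((36, 50))
        cm = an.ConnectivityMatrix.from_weights(W, topo)
        df = an.group_by_target(cm)
        assert (df["target"] == "LE").all()
        assert df["weak"].all()

    def test_ordering_is_type_then_target(self, topo):
        W = seed_weights(topo, np.random.default_rng(5))
        df = an.group_by_target(an.ConnectivityMatrix.from_weights(W, topo))
        types = df["neuron_type"].to_numpy()
        assert (types[:16] == "INe").all() and (types[16:] == "INi").all()
        for half in (df[:16], df[16:]):
            assert (np.diff(half["target_index"].to_numpy()) >= 0).all()
        # matches a brute-force argmax + sort
        outputs = an.ConnectivityMatrix.from_weights(W, topo).interneuron_outputs()
        manual = sorted(range(16), key=lambda i: (int(np.argmax(outputs[i])), i))
        assert list(df[:16]["neuron"]) == manual


class TestRelativeWeights:
    def test_profiles_sum_to_one(self, cm):
        df = an.relative_pa_weights(cm)
        sums = df.iloc[:, 2:16].to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_single_afferent_gives_unit_indicator(self, topo):
        W = np.zeros((36, 50))
        W[7, 3] = 0.42  # INe#3 hears only Ia-RF
        cm = an.ConnectivityMatrix.from_weights(W, topo)
        df = an.relative_pa_weights(cm)
        row = df[df["neuron"] == 3].iloc[0]
        assert row["Ia-RF"] == 1.0
        assert row[2:16].to_numpy(dtype=float).sum() == 1.0

    def test_zero_total_flagged_not_divided(self, topo):
        W = np.zeros((36, 50))
        cm = an.ConnectivityMatrix.from_weights(W, topo)
        df = an.relative_pa_weights(cm)
        assert df["zero_total"].all()
        assert np.nanmax(df.iloc[:, 2:16].to_numpy(dtype=float)) == 0.0


class TestCooperativity:
    def test_constant_activity_travels_nowhere(self):
        traces = {"a": np.ones((500, 32)) * 0.3,
                  "b": np.random.default_rng(0).random((500, 32))}
        res = an.cooperativity(traces, exclude_steps=0)
        assert res.distances["a"] == pytest.approx(0.0, abs=1e-9)
        assert res.distances["b"] > 0

    def test_two_sample_trace_is_a_single_segment(self):
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(1)
        tr = rng.random((2, 32))
        other = rng.random((50, 32))
        res = an.cooperativity({"x": tr, "y": other}, exclude_steps=0)
        pca = PCA(svd_solver="full").fit(np.vstack([tr, other]))
        c = pca.transform(tr)[:, :res.ndim95]
        assert res.distances["x"] == pytest.approx(
            np.linalg.norm(c[1] - c[0]), abs=1e-9)

    def test_distance_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(4)
        phases = rng.uniform(0, 2 * np.pi, 32)
        t = np.linspace(0, 6, 600)[:, None]
        tr1 = 0.5 + 0.4 * np.sin(2 * np.pi * t + phases)
        tr2 = 0.5 + 0.4 * np.sin(3 * np.pi * t + phases[::-1])
        res = an.cooperativity({"a": tr1, "b": tr2}, exclude_steps=100)
        from sklearn.decomposition import PCA
        pooled = np.vstack([tr1[100:], tr2[100:]])
        pca = PCA(svd_solver="full").fit(pooled)
        for key, tr in (("a", tr1), ("b", tr2)):
            coords = pca.transform(tr[100:])[:, :res.ndim95]
            assert res.distances[key] == pytest.approx(
                trajectory_length(coords), abs=1e-9)

    def test_distance_invariant_under_rotation_of_the_retained_space(self):
        rng = np.random.default_rng(6)
        tr = rng.random((300, 32))
        res = an.cooperativity({"a": tr}, exclude_steps=0)
        from sklearn.decomposition import PCA
        pca = PCA(svd_solver="full").fit(tr)
        coords = pca.transform(tr)[:, :res.ndim95]
        Q, _ = np.linalg.qr(rng.normal(size=(res.ndim95, res.ndim95)))
        rotated = coords @ Q
        assert trajectory_length(rotated) == pytest.approx(
            res.distances["a"], rel=1e-9)

    def test_initiation_cycle_is_excluded(self):
        quiet = np.zeros((400, 32))
        active = np.random.default_rng(2).random((1200, 32))
        tr = np.vstack([quiet, active])
        res_excl = an.cooperativity({"a": tr}, exclude_steps=400)
        res_incl = an.cooperativity({"a": tr}, exclude_steps=0)
        assert res_excl.distances["a"] != res_incl.distances["a"]
        assert res_excl.coords3["a"].shape == (1200, 3)
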