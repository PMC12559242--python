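import numpy as np
import pandas as pd
import pytest

from splicewalk.cell_similarity import SimilarityNetwork
from splicewalk.events import CountMatrix, EventDefinition, Junction, PsiMatrix
from splicewalk.scenario import (
    MODEL1_STAGE,
    MODEL2_STAGE,
    FeatureContext,
    ScenarioModel,
    ScenarioThresholds,
    classify_nd_wd,
    extract_scenario_features,
    finetune_scenario_models,
    label_pairs_from_reference,
    predict_scenario_probabilities,
    train_scenario_model,
)


def make_context(incl, excl, network_values, support=None):
    """Small aligned context: one SE-style event per exclusion column."""
    incl = np.asarray(incl, float)
    excl = np.asarray(excl, float)
    n_cells, n_events = excl.shape
    events = []
    incl_ids, excl_ids = [], []
    for i in range(n_events):
        base = 1000 * (i + 1)
        e = EventDefinition(
            f"e{i}", f"g{i}", "SE",
            [Junction("chr1", base, base + 100)],
            [Junction("chr1", base, base + 300)],
        )
        events.append(e)
        incl_ids.extend(e.inclusion_ids)
        excl_ids.extend(e.exclusion_ids)
    cells = [f"c{i}" for i in range(n_cells)]
    rc_i = CountMatrix(incl, cells, incl_ids)
    rc_e = CountMatrix(excl, cells, excl_ids)
    denom = incl + excl
    psi_values = np.divide(incl, denom, out=np.zeros_like(incl), where=denom > 0)
    psi = PsiMatrix(psi_values, cells, [e.event_id for e in events],
                    support if support is not None else denom > 0)
    net = SimilarityNetwork(np.asarray(network_values, float), cells,
                            max(n_cells - 1, 1), state="diffused")
    return FeatureContext(rc_ijc=rc_i, rc_ejc=rc_e, psi_raw=psi, events=events,
                          cell_network=net)


def uniform_net(n):
    return np.full((n, n), 1.0 / n)


class TestModel0:
    def test_intermediate_psi_is_nd(self):
        psi = PsiMatrix([[0.5, 1.0, 0.0]], ["c0"], ["e0", "e1", "e2"])
        assert list(classify_nd_wd(psi)[0]) == [1.0, 0.0, 0.0]

    def test_no_support_pairs_are_wd(self):
        ctx = make_context([[0.0]], [[0.0]], uniform_net(1))
        assert classify_nd_wd(ctx.psi_raw)[0, 0] == 0.0

    def test_library_rescaling_invariance(self, rng):
        incl = rng.integers(0, 10, (5, 3)).astype(float)
        excl = rng.integers(0, 10, (5, 3)).astype(float)
        ctx1 = make_context(incl, excl, uniform_net(5))
        scales = rng.uniform(0.5, 2.0, size=5)[:, None]
        ctx2 = make_context(incl * scales, excl * scales, uniform_net(5))
        assert np.array_equal(classify_nd_wd(ctx1.psi_raw), classify_nd_wd(ctx2.psi_raw))


class TestFeatures:
    def test_bd_signature_block(self):
        """Zero-read target with single-isoform high-depth neighbors."""
        incl = np.array([[0.0], [0.0], [0.0], [0.0]])
        excl = np.array([[0.0], [50.0], [60.0], [40.0]])
        ctx = make_context(incl, excl, uniform_net(4))
        feats = extract_scenario_features(ctx, MODEL1_STAGE,
                                          np.array([0]), np.array([0]))
        row = dict(zip(feats.feature_ids, feats.values[0]))
        assert row["total_reads"] == 0.0
        assert row["frac_neighbors_exclusion_support"] == pytest.approx(1.0)
        assert row["frac_neighbors_single_isoform"] == pytest.approx(1.0)
        assert row["neighbor_mean_psi"] == pytest.approx(0.0)

    def test_identical_pairs_identical_rows(self):
        incl = np.array([[3.0], [3.0], [5.0]])
        excl = np.array([[1.0], [1.0], [2.0]])
        ctx = make_context(incl, excl, uniform_net(3))
        feats = extract_scenario_features(ctx, MODEL1_STAGE,
                                          np.array([0, 1]), np.array([0, 0]))
        assert np.allclose(feats.values[0], feats.values[1])

    def test_unknown_pair_rejected(self):
        ctx = make_context([[1.0]], [[1.0]], uniform_net(1))
        with pytest.raises(ValueError, match="unknown"):
            extract_scenario_features(ctx, MODEL1_STAGE, np.array([5]), np.array([0]))

    def test_model2_requires_strategy2_outputs(self):
        ctx = make_context([[1.0]], [[1.0]], uniform_net(1))
        with pytest.raises(ValueError, match="strategy-2"):
            extract_scenario_features(ctx, MODEL2_STAGE)


class TestTraining:
    def separable_features(self, rng, n=200):
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 3)) + y[:, None] * 6.0
        feats_values = X
        from splicewalk.scenario import ScenarioFeatures

        feats = ScenarioFeatures(
            feats_values, ["f1", "f2", "f3"],
            np.zeros(n, int), np.zeros(n, int), ["c0"], ["e0"], MODEL1_STAGE,
        )
        return feats, y

    def test_separable_data_high_accuracy(self, rng):
        feats, y = self.separable_features(rng)
        model = train_scenario_model(feats, y, MODEL1_STAGE, seed=0)
        pred = (model.predict_proba(feats) >= 0.5).astype(int)
        assert (pred == y).mean() >= 0.99

    def test_permuted_labels_near_chance_on_heldout(self, rng):
        from splicewalk.scenario import ScenarioFeatures

        feats, y = self.separable_features(rng, n=400)
        y_perm = rng.permutation(y)
        train, test = np.arange(0, 280), np.arange(280, 400)
        f_train = ScenarioFeatures(feats.values[train], feats.feature_ids,
                                   feats.cell_index[train], feats.event_index[train],
                                   feats.cell_ids, feats.event_ids, MODEL1_STAGE)
        f_test = ScenarioFeatures(feats.values[test], feats.feature_ids,
                                  feats.cell_index[test], feats.event_index[test],
                                  feats.cell_ids, feats.event_ids, MODEL1_STAGE)
        model = train_scenario_model(f_train, y_perm[train], MODEL1_STAGE, seed=0)
        pred = (model.predict_proba(f_test) >= 0.5).astype(int)
        assert abs((pred == y_perm[test]).mean() - 0.5) < 0.15

    def test_same_seed_identical_weights(self, rng):
        feats, y = self.separable_features(rng)
        m1 = train_scenario_model(feats, y, MODEL1_STAGE, seed=3)
        m2 = train_scenario_model(feats, y, MODEL1_STAGE, seed=3)
        assert np.array_equal(m1.coef, m2.coef)

    def test_single_class_rejected(self, rng):
        feats, y = self.separable_features(rng)
        with pytest.raises(ValueError, match="single class"):
            train_scenario_model(feats, np.zeros_like(y), MODEL1_STAGE)

    def test_constant_feature_normalized_to_zero(self, rng):
        feats, y = self.separable_features(rng)
        feats.values[:, 2] = 7.0
        model = train_scenario_model(feats, y, MODEL1_STAGE, seed=0)
        Z = model._normalize(feats.values)
        assert np.all(Z[:, 2] == 0.0)

    def test_save_load_roundtrip(self, rng, tmp_path):
        feats, y = self.separable_features(rng)
        model = train_scenario_model(feats, y, MODEL1_STAGE, seed=0)
        path = tmp_path / "model.tsv"
        model.save(path)
        back = ScenarioModel.load(path)
        assert np.allclose(back.coef, model.coef)
        assert back.intercept == pytest.approx(model.intercept)
        assert back.feature_ids == model.feature_ids
        assert np.allclose(back.predict_proba(feats), model.predict_proba(feats))


class TestLabeling:
    def bd_context(self):
        """Zero-read target; neighbors exclusively exclusion-supporting."""
        incl = np.array([[0.0], [0.0], [0.0], [0.0], [0.0]])
        excl = np.array([[0.0], [30.0], [28.0], [31.0], [25.0]])
        return make_context(incl, excl, uniform_net(5))

    def test_bd_rule(self):
        labels = label_pairs_from_reference(self.bd_context(), {"e0": 0.0})
        assert labels.set_index("cell_id").loc["c0", "label"] == "BD"

    def test_td_info_rule(self):
        incl = np.array([[0.0], [3.0], [4.0], [0.0], [5.0]])
        excl = np.array([[0.0], [3.0], [4.0], [0.0], [5.0]])
        ctx = make_context(incl, excl, uniform_net(5))
        labels = label_pairs_from_reference(ctx, {"e0": 0.5})
        assert labels.set_index("cell_id").loc["c0", "label"] == "TD+Info"

    def test_td_noinfo_rule(self):
        incl = np.zeros((5, 1))
        excl = np.zeros((5, 1))
        ctx = make_context(incl, excl, uniform_net(5))
        labels = label_pairs_from_reference(ctx, {"e0": 0.5})
        assert (labels["label"] == "TD-Info").all()

    def test_labels_partition_all_pairs(self, rng):
        incl = rng.integers(0, 6, (8, 4)).astype(float)
        excl = rng.integers(0, 6, (8, 4)).astype(float)
        ctx = make_context(incl, excl, uniform_net(8))
        ref = {f"e{i}": float(rng.uniform()) for i in range(4)}
        labels = label_pairs_from_reference(ctx, ref)
        assert len(labels) == 8 * 4
        assert set(labels["label"]) <= {"ND", "BD", "TD+Info", "TD-Info"}
        assert not labels.duplicated(["cell_id", "event_id"]).any()

    def test_missing_reference_for_all_events_raises(self):
        ctx = self.bd_context()
        with pytest.raises(ValueError, match="reference"):
            label_pairs_from_reference(ctx, {"nonexistent": 0.5})


class TestPrediction:
    def test_extreme_bd_features_probability_near_one(self, rng):
        """A model trained on separated classes pushes clear cases to ~1."""
        n = 300
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X = rng.normal(scale=0.3, size=(n, 2)) + y[:, None] * 4.0
        from splicewalk.scenario import ScenarioFeatures

        feats = ScenarioFeatures(X, ["a", "b"], np.zeros(n, int), np.zeros(n, int),
                                 ["c0"], ["e0"], MODEL1_STAGE)
        model = train_scenario_model(feats, y, MODEL1_STAGE, seed=0)
        extreme = ScenarioFeatures(np.array([[4.0, 4.0]]), ["a", "b"],
                                   np.array([0]), np.array([0]), ["c0"], ["e0"], MODEL1_STAGE)
        assert model.predict_proba(extreme)[0] > 0.95

    def test_stage_mismatch_rejected(self, rng):
        from splicewalk.scenario import ScenarioFeatures

        X = rng.normal(size=(10, 2))
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        feats = ScenarioFeatures(X, ["a", "b"], np.zeros(10, int), np.zeros(10, int),
                                 ["c0"], ["e0"], MODEL1_STAGE)
        model = train_scenario_model(feats, y, MODEL1_STAGE, seed=0)
        feats.stage = MODEL2_STAGE
        with pytest.raises(ValueError, match="stage"):
            model.predict_proba(feats)

    def test_probability_matrices_filled_and_bounded(self, acceptance_run):
        p = acceptance_run.probabilities
        for arr in (p.p_bd, p.p_td_info):
            assert np.all((arr >= 0) & (arr <= 1))
        assert set(np.unique(p.p_nd)) <= {0.0, 1.0}


class TestFinetune:
    def make_models(self, rng):
        from splicewalk.scenario import ScenarioFeatures

        def fit(stage, n_feat):
            n = 100
            y = rng.integers(0, 2, n)
            X = rng.normal(size=(n, n_feat)) + y[:, None]
            feats = ScenarioFeatures(X, [f"f{i}" for i in range(n_feat)],
                                     np.zeros(n, int), np.zeros(n, int),
                                     ["c0"], ["e0"], stage)
            return train_scenario_model(feats, y, stage, seed=0)

        from splicewalk.scenario import MODEL1_FEATURES, MODEL2_FEATURES

        return (fit(MODEL1_STAGE, len(MODEL1_FEATURES)),
                fit(MODEL2_STAGE, len(MODEL2_FEATURES)))

    def test_empty_reference_returns_originals(self, rng):
        ctx = make_context([[1.0]], [[1.0]], uniform_net(1))
        models = self.make_models(rng)
        out = finetune_scenario_models(models, {}, ctx)
        assert out is models

    def test_underpopulated_classes_skip_finetuning(self, rng):
        incl = np.array([[0.0], [3.0], [4.0]])
        excl = np.array([[0.0], [3.0], [4.0]])
        ctx = make_context(incl, excl, uniform_net(3))
        models = self.make_models(rng)
        out = finetune_scenario_models(models, {"e0": 0.5}, ctx)
        assert out is models
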