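import numpy as np
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from rpistack import ensemble as ens


def blobs(n=200, sep=6.0, seed=0, d=4):
    """Two well-separated Gaussian clouds with binary labels."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, d))
    X[y == 1, 0] += sep
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestEncodeLevel0:
    def test_separable_data_high_heldout_aucs(self):
        X, y = blobs(n=200, sep=6.0, seed=1)
        state = ens.encode_level0(X, y, seed=1)
        assert (state.fold_aucs > 0.95).all()

    def test_permuted_labels_give_chance_aucs(self):
        X, y = blobs(n=200, sep=6.0, seed=2)
        rng = np.random.default_rng(2)
        y_perm = rng.permutation(y)
        state = ens.encode_level0(X, y_perm, seed=2)
        assert ((state.mean_aucs > 0.35) & (state.mean_aucs < 0.65)).all()

    def test_every_training_sample_gets_one_oof_encoding(self):
        X, y = blobs(n=100, seed=3)
        state = ens.encode_level0(X, y, n_folds=4, seed=3)
        assert state.train_encodings.shape == (100, 4)
        assert np.isfinite(state.train_encodings).all()
        covered = np.concatenate([held for _, held in state.fold_indices])
        assert sorted(covered.tolist()) == list(range(100))

    def test_no_leakage_with_memorizing_learner(self):
        # a fully-grown tree memorizes random labels perfectly in-sample;
        # out-of-fold encodings must still be uninformative
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 5))
        y = rng.integers(0, 2, size=120)
        learners = {"memorizer": DecisionTreeClassifier(random_state=0)}
        state = ens.encode_level0(X, y, learners=learners, seed=4)
        assert roc_auc_score(y, state.train_encodings[:, 0]) < 0.65

    def test_test_encoding_is_fold_average(self):
        X, y = blobs(n=80, seed=5)
        X_test = X[:10]
        state = ens.encode_level0(X, y, test_features=X_test, seed=5)
        manual = np.zeros(10)
        for model in state.fold_models[0]:
            manual += model.predict_proba(X_test)[:, 1]
        np.testing.assert_allclose(state.test_encodings[:, 0], manual / state.n_folds)

    def test_too_few_samples_rejected(self):
        X, y = blobs(n=6, seed=6)
        with pytest.raises(ValueError):
            ens.encode_level0(X, y, n_folds=4)


class TestAdaptiveWeights:
    def test_perfect_classifier_keeps_full_weight(self):
        assert ens.adaptive_weights([1.0])[0] == 1.0

    def test_half_auc_value(self):
        assert ens.adaptive_weights([0.5], n_classifiers=4)[0] == pytest.approx(0.68359375)

    def test_monotone_in_auc(self):
        grid = np.linspace(0.0, 1.0, 21)
        lam = ens.adaptive_weights(grid, n_classifiers=4)
        assert (np.diff(lam) >= 0).all()
        assert ((lam >= 0) & (lam <= 1)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ens.adaptive_weights([1.2])


class TestMeta:
    def test_perfectly_informative_column(self, rng):
        y = rng.integers(0, 2, size=80)
        enc = np.column_stack([y.astype(float), rng.random(80)])
        meta = ens.fit_meta(enc, y)
        assert (meta.predict(enc) == y).all()

    def test_constant_encodings_give_base_rate(self, rng):
        y = (rng.random(200) < 0.7).astype(int)
        enc = np.full((200, 3), 0.5)
        meta = ens.fit_meta(enc, y)
        assert meta.predict_proba(enc)[0, 1] == pytest.approx(y.mean(), abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ens.fit_meta(np.zeros((10, 2)), np.ones(10))


class TestPredictStrategy:
    def test_averaging_is_uniform_mean(self):
        out = ens.predict_strategy(np.array([[0.9, 0.8, 0.7, 0.2]]), "averaging")
        assert out[0] == pytest.approx(0.65)

    def test_majority_vote_and_reject(self):
        assert ens.predict_strategy(np.array([[0.9, 0.8, 0.7, 0.2]]), "voting")[0] == 1
        # 2-2 tie -> reject -> negative class
        assert ens.predict_strategy(np.array([[0.9, 0.8, 0.2, 0.1]]), "voting")[0] == 0

    def test_exact_threshold_votes_negative(self):
        assert ens.predict_strategy(np.array([[0.5, 0.5, 0.5, 0.9]]), "voting")[0] == 0

    def test_unknown_strategy(self):
        with pytest.raises(ValueError, match="unknown strategy"):
            ens.predict_strategy(np.zeros((1, 4)), "bagging")


@pytest.fixture(scope="module")
def separable():
    X, y = blobs(n=160, sep=8.0, seed=7)
    X_test, y_test = blobs(n=60, sep=8.0, seed=17)
    return X, y, X_test, y_test


class TestStackingEnsemble:
    def test_adaptive_equals_plain_when_lambdas_are_one(self, separable):
        X, y, X_test, _ = separable
        plain = ens.StackingEnsemble(strategy="stacking", seed=7).fit(X, y)
        adaptive = ens.StackingEnsemble(strategy="stacking_adaptive", seed=7).fit(X, y)
        # near-separable data drives every w^c (and hence lambda) to ~1
        np.testing.assert_allclose(adaptive.lambdas, 1.0, atol=1e-5)
        np.testing.assert_allclose(plain.predict_proba(X_test),
                                   adaptive.predict_proba(X_test), atol=1e-3)

    def test_stacking_at_least_matches_best_base(self, separable):
        X, y, X_test, y_test = separable
        model = ens.StackingEnsemble(strategy="stacking_adaptive", seed=7).fit(X, y)
        stacked_auc = roc_auc_score(y_test, model.predict_proba(X_test))
        base_aucs = [roc_auc_score(y_test, p) for p in model.base_probabilities(X_test).T]
        assert stacked_auc >= max(base_aucs) - 0.02

    def test_deterministic_refit(self, separable):
        X, y, X_test, _ = separable
        p1 = ens.StackingEnsemble(seed=9).fit(X, y).predict_proba(X_test)
        p2 = ens.StackingEnsemble(seed=9).fit(X, y).predict_proba(X_test)
        np.testing.assert_array_equal(p1, p2)

    def test_voting_has_no_probabilities(self, separable):
        X, y, X_test, _ = separable
        model = ens.StackingEnsemble(strategy="voting", seed=7).fit(X, y)
        with pytest.raises(RuntimeError):
            model.predict_proba(X_test)
        labels = model.predict(X_test)
        assert set(np.unique(labels)) <= {0, 1}

    def test_bundle_roundtrip(self, separable, tmp_path):
        X, y, X_test, _ = separable
        model = ens.StackingEnsemble(seed=7).fit(X, y)
        ens.save_bundle(model, tmp_path / "bundle")
        loaded, manifest = ens.load_bundle(tmp_path / "bundle")
        np.testing.assert_array_equal(model.predict_proba(X_test), loaded.predict_proba(X_test))
        assert manifest["strategy"] == "stacking_adaptive"
        assert len(manifest["lambdas"]) == 4

    def test_bundle_version_mismatch_rejected(self, separable, tmp_path):
        import json
        X, y, _, _ = separable
        model = ens.StackingEnsemble(seed=7).fit(X, y)
        ens.save_bundle(model, tmp_path / "bundle")
        manifest_file = tmp_path / "bundle" / "manifest.json"
        manifest = json.loads(manifest_file.read_text())
        manifest["version"] = "999.0"
        manifest_file.write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="version"):
            ens.load_bundle(tmp_path / "bundle")


def test_default_learner_roster():
    learners = ens.make_base_learners(seed=0)
    assert tuple(learners) == ens.ROLES
    rf = learners["random_forest"]
    assert rf.n_estimators == 25 and rf.criterion == "gini" and rf.random_state == 1
    assert learners["gradient_boosting"].max_depth == 6
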