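import numpy as np
import pytest

from varfx import ensemble as ens
from varfx import features as feat
from varfx.features import Scaler
from varfx.homology import Rotation
from varfx.io import EFFECT, NEUTRAL


class TestBalancing:
    def test_majority_downsampled(self):
        y = np.array([1] * 600 + [0] * 400)
        idx = ens.balance_training_set(y, np.random.default_rng(0))
        assert len(idx) == 800
        assert y[idx].sum() == 400

    def test_already_balanced_unchanged_size(self):
        y = np.array([1] * 50 + [0] * 50)
        assert len(ens.balance_training_set(y, np.random.default_rng(0))) == 100

    def test_deterministic_per_seed(self):
        y = np.array([1] * 30 + [0] * 70)
        a = ens.balance_training_set(y, np.random.default_rng(7))
        b = ens.balance_training_set(y, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ens.balance_training_set(np.ones(10), np.random.default_rng(0))


class TestReliabilityIndex:
    @pytest.mark.parametrize("eff,neu,ri,digit", [
        (0.5, 0.5, 0, 0),
        (1.0, 0.0, 10, 9),
        (0.9, 0.1, 8, 8),
        (0.0, 1.0, 10, 9),
        (0.55, 0.45, 1, 1),
    ])
    def test_values(self, eff, neu, ri, digit):
        assert ens.reliability_index(eff, neu) == (ri, digit)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            ens.reliability_index(1.2, 0.0)


class TestThreshold:
    def test_score_zero_is_effect_at_default(self):
        assert ens.classify(0.0) == EFFECT  # 0 > -0.05

    def test_strongly_negative_is_neutral(self):
        assert ens.classify(-0.5) == NEUTRAL

    def test_config_ranges_enforced(self):
        with pytest.raises(ValueError):
            ens.NetworkConfig(hidden_units=5)
        with pytest.raises(ValueError):
            ens.NetworkConfig(learning_rate=0.5)


def separable_data(n=400, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
    return X, y


class TestTrainNetwork:
    def test_separable_reaches_high_auc(self):
        X, y = separable_data(600, seed=1)
        Xc, yc = separable_data(200, seed=2)
        config = ens.NetworkConfig(hidden_units=10, learning_rate=0.05,
                                   momentum=0.1, seed=0, max_repetitions=60)
        model = ens.train_network(X, y, Xc, yc, config)
        assert model.best_auc >= 0.99

    def test_snapshot_is_recorded_maximum(self):
        X, y = separable_data(300, seed=3)
        Xc, yc = separable_data(150, seed=4)
        config = ens.NetworkConfig(hidden_units=10, learning_rate=0.05,
                                   momentum=0.1, seed=5, max_repetitions=40)
        model = ens.train_network(X, y, Xc, yc, config)
        assert model.best_auc == pytest.approx(max(model.history))
        assert model.history[model.best_repetition] == pytest.approx(model.best_auc)

    def test_two_output_units_bounded(self):
        X, y = separable_data(200, seed=6)
        config = ens.NetworkConfig(hidden_units=10, learning_rate=0.05,
                                   momentum=0.1, max_repetitions=15)
        model = ens.train_network(X, y, X, y, config)
        out = model.forward(X)
        assert out.shape == (200, 2)
        assert np.all((out >= 0) & (out <= 1))

    def test_deterministic_given_seed(self):
        X, y = separable_data(200, seed=7)
        config = ens.NetworkConfig(hidden_units=10, learning_rate=0.05,
                                   momentum=0.1, seed=9, max_repetitions=15)
        a = ens.train_network(X, y, X, y, config)
        b = ens.train_network(X, y, X, y, config)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)


class TestHyperparameterSearch:
    def test_singleton_grid(self):
        X, y = separable_data(200, seed=8)
        config = ens.NetworkConfig(hidden_units=10, learning_rate=0.05,
                                   momentum=0.1, max_repetitions=10)
        assert ens.hyperparameter_search(X, y, X, y, [config]) is config

    def test_duplicate_configs_tie_break(self):
        X, y = separable_data(200, seed=8)
        small = ens.NetworkConfig(hidden_units=10, learning_rate=0.05,
                                  momentum=0.1, seed=1, max_repetitions=10)
        big = ens.NetworkConfig(hidden_units=50, learning_rate=0.05,
                                momentum=0.1, seed=1, max_repetitions=10)
        # on perfectly separable data both reach AUC 1.0; tie -> fewer hidden units
        winner = ens.hyperparameter_search(X, y, X, y, [big, small])
        assert winner.hidden_units == 10

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            ens.hyperparameter_search(None, None, None, None, [])


def stub_member(out_neutral, out_effect, n_features=3):
    """Member whose network always outputs the given pair."""
    config = ens.NetworkConfig(hidden_units=10, learning_rate=0.05, momentum=0.1)
    model = ens.NetworkModel(
        W1=np.zeros((n_features, 10)), b1=np.zeros(10),
        W2=np.zeros((10, 2)),
        b2=np.array([np.log(o / (1 - o)) if 0 < o < 1 else (60.0 if o >= 1 else -60.0)
                     for o in (out_neutral, out_effect)]),
        config=config)
    scaler = Scaler(mean=np.zeros(n_features), sd=np.ones(n_features))
    return ens.EnsembleMember(model=model, scaler=scaler,
                              rotation=Rotation((2, 3, 4, 5, 6, 7, 8, 9), 1, 0))


class TestEnsembleAveraging:
    def test_unanimous_effect_scores_plus_100(self):
        members = [stub_member(0.0, 1.0) for _ in range(10)]
        ensemble = ens.EnsembleModel(members=members, descriptors=[])
        neu, eff = ensemble.predict_outputs(np.zeros((1, 3)))
        assert eff[0] == pytest.approx(1.0, abs=1e-9)
        assert neu[0] == pytest.approx(0.0, abs=1e-9)

    def test_split_outputs_average(self):
        members = [stub_member(0.5, 0.5)] * 5 + [stub_member(0.0, 1.0)] * 5
        ensemble = ens.EnsembleModel(members=members, descriptors=[])
        neu, eff = ensemble.predict_outputs(np.zeros((2, 3)))
        assert eff[0] == pytest.approx(0.75, abs=1e-9)
        assert neu[0] == pytest.approx(0.25, abs=1e-9)


class TestTrainEnsemble:
    def test_partition_property(self, trained_ensemble, synth_dataset):
        """Each variant is predicted exactly once across the ten test folds."""
        assert len(trained_ensemble.members) == 10
        all_rows = [r for rows, _ in trained_ensemble.crossval_outputs for r in rows]
        assert sorted(all_rows) == list(range(len(all_rows)))
        dataset, _ = synth_dataset
        assert len(all_rows) == len(dataset.labeled())

    def test_generalization_band(self, trained_ensemble):
        """Test AUC close to cross-train AUC on well-sampled synthetic data."""
        from sklearn.metrics import roc_auc_score
        kept = trained_ensemble._crossval_variants
        for member, (rows, outs) in zip(trained_ensemble.members,
                                        trained_ensemble.crossval_outputs):
            y = [1 if kept[r].label == EFFECT else 0 for r in rows]
            test_auc = roc_auc_score(y, outs[:, 1] - outs[:, 0])
            assert abs(test_auc - member.model.best_auc) < 0.1

    def test_serialization_roundtrip(self, trained_ensemble, synth_dataset,
                                     registry, tmp_path):
        dataset, _ = synth_dataset
        path = tmp_path / "model.json"
        ens.save_ensemble(trained_ensemble, path)
        loaded = ens.load_ensemble(path)
        some = dataset.variants[:25]
        a = ens.predict(trained_ensemble, dataset, registry, variants=some)
        b = ens.predict(loaded, dataset, registry, variants=some)
        assert [r.score for r in a] == pytest.approx([r.score for r in b])
        assert [r.ri for r in a] == [r.ri for r in b]

    def test_score_consistency(self, trained_ensemble, synth_dataset, registry):
        dataset, _ = synth_dataset
        results = ens.predict(trained_ensemble, dataset, registry,
                              variants=dataset.variants[:50])
        for r in results:
            assert r.score == pytest.approx(
                (r.avg_output_effect - r.avg_output_neutral) * 100)
            assert -100 <= r.score <= 100
            expected = EFFECT if (r.avg_output_effect - r.avg_output_neutral) > \
                trained_ensemble.threshold else NEUTRAL
            assert r.predicted_class == expected
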