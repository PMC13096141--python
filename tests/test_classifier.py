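import numpy as np
import pytest

from perturbrank.classifier import (
    ClassCoverageError,
    FNN,
    FNNConfig,
    balance_classes,
    classification_metrics,
    default_member_configs,
    predict_targets,
    train_fnn,
)
from perturbrank.features import FeatureMatrix, minmax_normalize
from perturbrank.vae import VAEConfig, train_vae


def three_blobs(n_per=80, d=10, seed=0, spread=0.02):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.2, 0.8, size=(3, d))
    X = np.vstack([c + rng.normal(0, spread, size=(n_per, d)) for c in centers])
    y = np.repeat([0, 1, -1], n_per)
    return X, y


def fnn_config(d=10, **kw):
    base = dict(input_dim=d, initial_hidden=32, n_layers=2, learning_rate=0.005,
                batch_size=64, max_epochs=30, seed=0)
    base.update(kw)
    return FNNConfig(**base)


class TestConfig:
    def test_decaying_widths(self):
        cfg = FNNConfig(input_dim=100, initial_hidden=1500, n_layers=5)
        assert cfg.widths() == [1500, 750, 375, 187, 93]

    def test_dropout_domain(self):
        with pytest.raises(ValueError):
            fnn_config(dropout=1.0).validate()

    def test_default_member_configs_reference_settings(self):
        cfgs = default_member_configs(input_dim=100)
        assert [c.batch_size for c in cfgs] == [1024, 2048, 2048]
        assert (cfgs[1].l1, cfgs[1].l2) == (0.2, 0.1)
        assert cfgs[0].l1 == cfgs[2].l1 == 0.0
        assert all(c.learning_rate == 0.005 and c.dropout == 0.0 for c in cfgs)
        assert len({c.seed for c in cfgs}) == 3


class TestBalanceClasses:
    def setup_method(self):
        F, _ = self._data()
        cfg = VAEConfig(input_dim=F.shape[1], initial_hidden=16, n_encoder_layers=2,
                        latent_dim=3, batch_size=32, max_epochs=3, seed=0)
        self.vae = train_vae(F, cfg)

    def _data(self, sizes=(30, 6, 9), seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.05, 0.95, size=(sum(sizes), 6))
        y = np.concatenate([np.full(s, c) for s, c in zip(sizes, (0, 1, -1))])
        F = FeatureMatrix([f"r{i}" for i in range(len(y))],
                          [f"f{j}" for j in range(6)], X, stage="decoded")
        return F, y

    def test_already_balanced_unchanged(self):
        F, y = self._data(sizes=(10, 10, 10))
        Xb, yb, prov = balance_classes(F, y, self.vae, seed=0)
        assert len(yb) == 30 and not prov.any()
        for c in (0, 1, -1):
            assert (yb == c).sum() == 10

    def test_mean_size_accounting(self):
        F, y = self._data(sizes=(30, 6, 9))
        Xb, yb, prov = balance_classes(F, y, self.vae, seed=0)
        assert len(yb) == 45  # 3 * T with T = mean(30, 6, 9) = 15
        for c, n_real, n_syn in ((0, 15, 0), (1, 6, 9), (-1, 9, 6)):
            mask = yb == c
            assert mask.sum() == 15
            assert (~prov[mask]).sum() == n_real
            assert prov[mask].sum() == n_syn

    def test_downsample_never_duplicates_real_rows(self):
        F, y = self._data(sizes=(30, 6, 9))
        Xb, yb, prov = balance_classes(F, y, self.vae, seed=3)
        real0 = Xb[(yb == 0) & ~prov]
        assert len(np.unique(real0, axis=0)) == len(real0)

    def test_absent_class_errors(self):
        F, y = self._data(sizes=(30, 6, 0))
        with pytest.raises(ClassCoverageError, match="-1"):
            balance_classes(F, y, self.vae, seed=0)

    def test_ambiguous_labels_rejected(self):
        F, y = self._data(sizes=(10, 10, 10))
        y = y.copy()
        y[0] = 2
        with pytest.raises(ValueError, match="ambiguous"):
            balance_classes(F, y, self.vae, seed=0)


class TestTrainFnn:
    def test_separable_blobs_high_f1(self):
        X, y = three_blobs()
        _, metrics = train_fnn(X, y, fnn_config())
        assert metrics["macro_f1"] > 0.95

    def test_same_seed_identical_predictions(self):
        X, y = three_blobs()
        m1, _ = train_fnn(X, y, fnn_config(max_epochs=5))
        m2, _ = train_fnn(X, y, fnn_config(max_epochs=5))
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_shuffled_labels_near_chance(self):
        X, y = three_blobs(n_per=100)
        y_shuf = np.random.default_rng(0).permutation(y)
        _, metrics = train_fnn(X, y_shuf, fnn_config(max_epochs=10))
        assert metrics["macro_f1"] < 0.55  # chance is ~1/3 for 3 balanced classes


class TestPredictTargets:
    def _members(self, label_rows):
        class Stub:
            def __init__(self, labels):
                self._labels = np.asarray(labels)

            def predict(self, X):
                return self._labels

        return [Stub(r) for r in label_rows]

    def _F(self, n):
        return FeatureMatrix([f"p{i}" for i in range(n)], ["f"],
                             np.zeros((n, 1)), stage="decoded")

    def test_vote_outcomes(self):
        members = self._members([[1, 0, 0], [1, 0, 1], [-1, 0, -1]])
        pred = predict_targets(members, self._F(3))
        assert pred.consensus.tolist() == [1, 0, 0]
        assert pred.vote_margin.tolist() == [2, 3, 0]

    def test_three_way_split_is_no_effect(self):
        pred = predict_targets(self._members([[0], [1], [-1]]), self._F(1))
        assert pred.consensus.tolist() == [0] and pred.vote_margin.tolist() == [0]

    def test_member_order_invariance(self):
        rows = [[1, -1, 0, 1], [1, 0, 0, -1], [0, -1, 1, -1]]
        base = predict_targets(self._members(rows), self._F(4)).consensus
        import itertools

        for perm in itertools.permutations(rows):
            assert np.array_equal(
                predict_targets(self._members(list(perm)), self._F(4)).consensus, base
            )

    def test_consensus_never_ambiguous(self):
        rng = np.random.default_rng(0)
        rows = rng.choice([0, 1, -1], size=(3, 50))
        pred = predict_targets(self._members(rows), self._F(50))
        assert set(pred.consensus.tolist()) <= {0, 1, -1}

    def test_exactly_three_members_required(self):
        with pytest.raises(ValueError):
            predict_targets(self._members([[0], [0]]), self._F(1))


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, -1, 0, 1, -1])
        m = classification_metrics(y, y)
        assert m["macro_f1"] == 1.0 and m["fpr"] == 0.0 and m["fnr"] == 0.0

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(5)
        truth = rng.choice([0, 1, -1], size=200)
        pred = rng.choice([0, 1, -1], size=200)
        m = classification_metrics(pred, truth)
        f1s, fprs, fnrs = [], [], []
        for c in (0, 1, -1):
            tp = np.sum((pred == c) & (truth == c))
            fp = np.sum((pred == c) & (truth != c))
            fn = np.sum((pred != c) & (truth == c))
            tn = np.sum((pred != c) & (truth != c))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
            fprs.append(fp / (fp + tn))
            fnrs.append(fn / (fn + tp))
        assert m["macro_f1"] == pytest.approx(np.mean(f1s))
        assert m["fpr"] == pytest.approx(np.mean(fprs))
        assert m["fnr"] == pytest.approx(np.mean(fnrs))

    def test_single_class_truth_flags_degenerate(self):
        y = np.zeros(10, dtype=int)
        m = classification_metrics(y, y)
        assert m["macro_f1"] == pytest.approx(1 / 3)
        assert set(m["degenerate_classes"]) == {1, -1}

    def test_all_one_class_prediction_on_balanced_truth(self):
        truth = np.repeat([0, 1, -1], 10)
        pred = np.zeros(30, dtype=int)
        m = classification_metrics(pred, truth)
        # class 0: precision 1/3, recall 1 -> F1 = 0.5; others 0
        assert m["macro_f1"] == pytest.approx(0.5 / 3)

    def test_empty_and_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            classification_metrics(np.array([0]), np.array([2]))


def test_ensemble_beats_degenerate_baselines():
    X, y = three_blobs(n_per=60)
    cfgs = [fnn_config(seed=s, max_epochs=15) for s in (1, 2, 3)]
    from perturbrank.classifier import train_ensemble

    members, _ = train_ensemble(X, y, cfgs)
    F = FeatureMatrix([f"r{i}" for i in range(len(y))],
                      [f"f{j}" for j in range(X.shape[1])], X, stage="decoded")
    ens = classification_metrics(predict_targets(members, F).consensus, y)
    rng = np.random.default_rng(0)
    uniform = classification_metrics(rng.choice([0, 1, -1], size=len(y)), y)
    zeros = classification_metrics(np.zeros(len(y), dtype=int), y)
    assert ens["macro_f1"] >= uniform["macro_f1"]
    assert ens["macro_f1"] >= zeros["macro_f1"]
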