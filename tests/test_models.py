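import numpy as np
import pandas as pd
import pytest

from walkrec import models as md
from walkrec.cnn import Cnn1d, build_cnn_spec, count_parameters, train_cnn


class TestCnnSpecs:
    @pytest.mark.parametrize(
        "arch,layer,params,shape",
        [
            ("a", "conv1_a", 40, (248, 10)),
            ("a", "conv2_a", 310, (246, 10)),
            ("a", "fully_con1_a", 157_568, (128,)),
            ("a", "fully_con2_a", 258, (2,)),
            ("b", "conv1_b", 20, (248, 5)),
            ("b", "conv2_b", 160, (122, 10)),
            ("b", "fully_con1_b", 625_664, (1024,)),
            ("b", "fully_con2_b", 2050, (2,)),
        ],
    )
    def test_per_layer_shapes_and_parameters(self, arch, layer, params, shape):
        spec = build_cnn_spec(arch)
        l = {x.name: x for x in spec.layers}[layer]
        assert l.param_count == params
        assert l.output_shape == shape

    @pytest.mark.parametrize("arch,total", [("a", 158_176), ("b", 627_894)])
    def test_total_parameter_count(self, arch, total):
        assert count_parameters(build_cnn_spec(arch)) == total

    def test_toy_dense_hand_formula(self):
        spec = build_cnn_spec("a", input_len=250)
        dense = [l for l in spec.layers if l.kind == "dense"][-1]
        assert dense.param_count == (128 + 1) * 2  # (in + 1) · out

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            build_cnn_spec("c")

    @pytest.mark.parametrize("arch", ["a", "b"])
    def test_model_parameters_match_spec_accounting(self, arch):
        spec = build_cnn_spec(arch)
        model = Cnn1d(spec, seed=0)
        assert model.n_parameters == count_parameters(spec)


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(0)
    t = np.arange(250) / 100.0
    X, y = [], []
    for i in range(60):
        if i % 2:
            f = rng.uniform(1.8, 2.2)
            X.append(np.sin(2 * np.pi * f * t + rng.uniform(0, 6)) * 3)
            y.append(1)
        else:
            X.append(rng.normal(0, 1.0, 250))
            y.append(0)
    return np.array(X), np.array(y)


class TestCnnTraining:
    def test_learns_separable_data_and_logs_epochs(self, separable_data):
        X, y = separable_data
        model = train_cnn(build_cnn_spec("a"), X, y, epochs=20, seed=1)
        assert len(model.history) == 20  # one loss entry per epoch
        assert np.mean(model.predict(X) == y) >= 0.95

    def test_imbalance_warning(self, separable_data):
        X, y = separable_data
        y = np.zeros_like(y)
        y[0] = 1
        with pytest.warns(UserWarning, match="minority"):
            train_cnn(build_cnn_spec("a"), X, y, epochs=1, seed=0)


class TestClassicalClassifiers:
    def test_linear_svm_separates_separable_toy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (30, 2)), rng.normal(4, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        model = md.train_classifier(X, y, algo="svm_linear", cv_folds=5)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_rf_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(80, 5)), rng.integers(0, 2, 80)
        a = md.train_classifier(X, y, algo="rf", cv_folds=3, seed=5)
        b = md.train_classifier(X, y, algo="rf", cv_folds=3, seed=5)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_1nn_memorizes_training_set(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        from sklearn.neighbors import KNeighborsClassifier

        model = KNeighborsClassifier(n_neighbors=1).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_unknown_algo_rejected(self):
        with pytest.raises(ValueError):
            md.train_classifier(np.zeros((4, 2)), [0, 0, 1, 1], algo="mystery")


class TestRebalance:
    def _data(self, n_pos, n_neg, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n_pos + n_neg, 4))
        y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
        return X, y

    def test_undersample_reproduces_published_arithmetic(self):
        # 1730 negatives → 70% = 1211 kept + 1211 positives = 2422 instances,
        # which is 30.7% of the 7886 collected patterns
        X, y = self._data(n_pos=6156, n_neg=1730)
        Xb, yb, _ = md.rebalance(X, y, mode="undersample_balanced", seed=0)
        assert len(yb) == 2422
        assert np.sum(yb == 0) == 1211 and np.sum(yb == 1) == 1211
        assert round(100 * len(yb) / len(y), 1) == 30.7

    @pytest.mark.parametrize("mode", ["undersample_balanced", "oversample_cnn"])
    def test_classes_balanced_and_seeded(self, mode):
        X, y = self._data(n_pos=300, n_neg=100)
        Xb, yb, idx = md.rebalance(X, y, mode=mode, seed=3)
        assert np.sum(yb == 0) == np.sum(yb == 1)
        Xb2, yb2, idx2 = md.rebalance(X, y, mode=mode, seed=3)
        np.testing.assert_array_equal(idx, idx2)

    def test_single_class_rejected(self):
        X, y = self._data(n_pos=10, n_neg=0)
        with pytest.raises(ValueError):
            md.rebalance(X, np.ones_like(y))


class TestEnsembles:
    def test_equal_coefficients_give_half_half(self):
        w = md.ensemble_weights(1.0, 1.0)
        assert (w.w_rf, w.w_svm) == (0.5, 0.5)

    def test_absolute_value_normalization(self):
        w = md.ensemble_weights(-3.0, 1.0)
        assert w.w_rf == pytest.approx(0.75)
        assert w.w_svm == pytest.approx(0.25)

    def test_weights_sum_to_one_for_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c1, c2 = rng.normal(size=2)
            if abs(c1) + abs(c2) == 0:
                continue
            w = md.ensemble_weights(c1, c2)
            assert w.w_rf + w.w_svm == pytest.approx(1.0, abs=1e-9)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            md.ensemble_weights(0.0, 0.0)

    def test_degenerate_weight_reduces_to_rf(self):
        w = md.ensemble_weights(1.0, 0.0)
        p = md.weighted_average_predict(0.83, 0.12, w)
        assert p == pytest.approx(0.83)

    def test_convexity_fixed_point_and_bounds(self):
        w = md.ensemble_weights(0.9721, 0.0278)  # the published blend
        assert md.weighted_average_predict(0.4, 0.4, w) == pytest.approx(0.4)
        p = md.weighted_average_predict(1.0, 0.0, w)
        assert p == pytest.approx(w.w_rf)
        assert 0.0 <= p <= 1.0

    def test_out_of_range_probability_rejected(self):
        w = md.ensemble_weights(1.0, 1.0)
        with pytest.raises(ValueError):
            md.weighted_average_predict(1.2, 0.5, w)

    def test_stacking_requires_fold_column(self):
        df = pd.DataFrame({"p_rf": [0.9, 0.1], "p_svm": [0.8, 0.2]})
        with pytest.raises(ValueError, match="fold"):
            md.stacking(df, [1, 0])

    def test_stacking_on_perfect_bottom_predictions(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        df = pd.DataFrame({
            "p_rf": y + rng.normal(0, 0.01, 100),
            "p_svm": y + rng.normal(0, 0.01, 100),
            "fold": np.arange(100) % 10,
        }).clip(0, 1)
        top = md.stacking(df, y, top_algo="svm_linear")
        assert np.mean(top.predict(df[["p_rf", "p_svm"]].to_numpy()) == y) == 1.0

    def test_stacking_recovers_known_linear_blend(self):
        rng = np.random.default_rng(1)
        p_rf = rng.uniform(0, 1, 300)
        p_svm = rng.uniform(0, 1, 300)
        y = (0.9 * p_rf + 0.1 * p_svm > 0.5).astype(int)
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression().fit(np.column_stack([p_rf, p_svm]), y)
        c_rf, c_svm = lr.coef_[0]
        assert c_rf > 0 and c_svm > 0
        assert abs(c_rf) > abs(c_svm)  # ordering of the true blend recovered
        w = md.ensemble_weights(c_rf, c_svm)
        assert w.w_rf > 0.6


class TestConfusionMetrics:
    def test_published_random_forest_row(self):
        cm = md.ConfusionMatrix(tp=4708, fp=19, tn=500, fn=237)
        assert md.confusion_metrics(cm) == (0.9521, 0.9634, 0.9531)

    def test_published_shape_svm_row(self):
        cm = md.ConfusionMatrix(tp=4724, fp=33, tn=486, fn=221)
        assert md.confusion_metrics(cm)[2] == 0.9535

    def test_perfect_classifier(self):
        cm = md.ConfusionMatrix(tp=10, fp=0, tn=5, fn=0)
        assert md.confusion_metrics(cm) == (1.0, 1.0, 1.0)

    def test_zero_denominator_flagged_as_nan(self):
        cm = md.ConfusionMatrix(tp=0, fp=0, tn=5, fn=0)
        sens, spec, acc = md.confusion_metrics(cm)
        assert np.isnan(sens) and spec == 1.0

    def test_counts_partition_evaluated_windows(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([1, 0, 0, 1, 1])
        cm = md.confusion_from_predictions(y, p)
        assert cm.total == len(y)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 1, 1, 1)
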