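"""Metrics, decoders, bootstrap, sequential pipelines, saliency."""

import itertools

import numpy as np
import pytest

from _oracles import hand_till_brute_force
from fundusprog.evaluation import (ConfusionMatrix3, accuracy,
                                   binarize_current, bootstrap_ci,
                                   confusion_matrix, decode_current_binary,
                                   decode_future_binary, hand_till_auc,
                                   saliency_map, sequential_eval)
from fundusprog.pairs import encode_label


class TestConfusionAccuracy:
    def test_identity_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm.counts, np.diag([2, 2, 2]))
        assert accuracy(cm) == 1.0

    def test_counts_are_placed_by_actual_row_predicted_column(self):
        cm = confusion_matrix([0, 0, 2], [1, 0, 0])
        assert cm.counts[0, 1] == 1 and cm.counts[0, 0] == 1 and cm.counts[2, 0] == 1
        assert cm.total == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [])

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 0])


class TestHandTillAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        assert hand_till_auc(y, np.eye(3)[y]) == 1.0

    def test_uninformative_scores(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        p = np.full((6, 3), 1 / 3)
        assert hand_till_auc(y, p) == 0.5

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 15))
        y = r.integers(0, 3, size=n)
        while len(np.unique(y)) < 2:
            y = r.integers(0, 3, size=n)
        p = r.dirichlet(np.ones(3), size=n)
        if r.random() < 0.3:  # exercise tie handling
            p = np.round(p, 1)
        assert hand_till_auc(y, p) == pytest.approx(
            hand_till_brute_force(y, p), abs=1e-12)

    def test_matches_sklearn_one_vs_one(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 3, size=60)
        p = rng.dirichlet(np.ones(3), size=60)
        assert hand_till_auc(y, p) == pytest.approx(
            roc_auc_score(y, p, multi_class="ovo"), abs=1e-10)

    def test_two_class_case_equals_binary_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=50)
        s = rng.random(50)
        p = np.stack([1 - s, s], axis=1)
        assert hand_till_auc(y, p) == pytest.approx(roc_auc_score(y, s))

    def test_absent_class_pair_skipped_with_warning(self):
        y = np.array([0, 0, 1, 1])
        p = np.eye(3)[y]
        with pytest.warns(UserWarning, match="skipped"):
            val = hand_till_auc(y, p)
        assert val == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            hand_till_auc([1, 1], np.full((2, 3), 1 / 3))


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        ci = bootstrap_ci(np.ones(50), np.mean, B=100, seed=0)
        assert ci.lo == ci.hi == ci.point == 1.0

    def test_deterministic_given_seed(self, rng):
        x = rng.random(100)
        a = bootstrap_ci(x, np.mean, B=200, seed=3)
        b = bootstrap_ci(x, np.mean, B=200, seed=3)
        assert (a.lo, a.hi) == (b.lo, b.hi)
        c = bootstrap_ci(x, np.mean, B=200, seed=4)
        assert (a.lo, a.hi) != (c.lo, c.hi)

    def test_joint_resampling_of_tuples(self, rng):
        y = rng.integers(0, 2, 80)
        p = y.copy()  # perfectly matched predictions
        ci = bootstrap_ci((y, p), lambda a, b: np.mean(a == b), B=100, seed=0)
        assert ci.point == ci.lo == ci.hi == 1.0

    def test_coverage_of_bernoulli_accuracy(self):
        # scaled-down coverage study: nominal 95% percentile intervals for
        # the mean of Bernoulli(0.8) should cover 0.8 most of the time
        outer = np.random.default_rng(12)
        covered = 0
        reps = 60
        for r in range(reps):
            x = (outer.random(300) < 0.8).astype(float)
            ci = bootstrap_ci(x, np.mean, B=200, seed=r)
            covered += ci.lo <= 0.8 <= ci.hi
        assert covered / reps >= 0.85

    def test_failing_resamples_redrawn(self):
        x = np.array([0.0] * 29 + [1.0])

        def fragile(v):
            if v.sum() == 0:
                raise ZeroDivisionError
            return v.mean()

        ci = bootstrap_ci(x, fragile, B=200, seed=0)
        assert np.isfinite(ci.point)


class TestDecoders:
    def test_current_visit_decoding(self):
        assert decode_current_binary([0, 1, 2]).tolist() == [0, 0, 1]

    def test_future_visit_decoding(self):
        assert decode_future_binary([0, 1, 2]).tolist() == [0, 1, 1]

    def test_future_decoder_consistent_with_label_encoding(self):
        # over every feasible severity pair, decoding the pair label
        # recovers exactly the second visit's advanced status
        for s1, s2 in itertools.product(range(13), repeat=2):
            if s1 >= 10 and s2 < 10:
                continue
            y = encode_label(s1, s2)
            assert decode_future_binary([y])[0] == int(s2 >= 10)
            assert decode_current_binary([y])[0] == int(s1 >= 10)


class TestBinarize:
    def test_diagonal_matrix_perfect_metrics(self):
        cm = ConfusionMatrix3(np.diag([5, 4, 3]))
        cm2, sens, spec, acc = binarize_current(cm)
        assert sens == spec == acc == 1.0
        assert cm2.total == cm.total

    def test_counts_conserved(self, rng):
        cm = ConfusionMatrix3(rng.integers(1, 50, (3, 3)))
        cm2, *_ = binarize_current(cm)
        assert cm2.total == cm.total

    def test_block_sums(self):
        c = np.arange(1, 10).reshape(3, 3)
        cm2, sens, spec, acc = binarize_current(ConfusionMatrix3(c))
        assert cm2.counts[1, 1] == c[2, 2]
        assert cm2.counts[1, 0] == c[2, 0] + c[2, 1]
        assert cm2.counts[0, 0] == c[:2, :2].sum()
        assert cm2.counts[0, 1] == c[0, 2] + c[1, 2]

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            binarize_current(ConfusionMatrix3(np.array(
                [[5, 1, 0], [1, 5, 0], [0, 0, 0]])))


class _OracleClassifier:
    """Stub that reads the true 3-class label planted in pixel (0, 0, 0)."""

    n_classes_ = 3

    def predict_proba(self, X):
        labels = np.round(np.asarray(X)[:, 0, 0, 0] * 2).astype(int)
        return np.eye(3)[labels]


class TestSequentialEval:
    @pytest.fixture
    def planted(self, rng):
        y = rng.integers(0, 3, size=30)
        X1 = rng.random((30, 8, 8, 3)) * 0.2
        X2 = rng.random((30, 8, 8, 3)) * 0.2
        X1[:, 0, 0, 0] = y / 2.0
        # plant the current-status label of the future image: 0/1 -> not adv
        X2[:, 0, 0, 0] = np.where(y == 0, 0.0, 1.0)
        return X1, X2, y

    def test_oracle_first3c_is_lossless(self, planted):
        X1, X2, y = planted
        _, acc = sequential_eval(None, _OracleClassifier(), X1, X2, y, "first3c")
        assert acc == 1.0

    def test_identity_generator_matches_second3c(self, planted):
        X1, X2, y = planted
        ident = lambda X: X
        p_gan, a_gan = sequential_eval(ident, _OracleClassifier(), X2, X2, y, "gan3c")
        p_2nd, a_2nd = sequential_eval(None, _OracleClassifier(), X1, X2, y, "second3c")
        assert a_gan == a_2nd
        assert np.array_equal(p_gan, p_2nd)

    def test_mode_classifier_mismatch_rejected(self, planted):
        X1, X2, y = planted
        with pytest.raises(ValueError, match="2-class"):
            sequential_eval(lambda X: X, _OracleClassifier(), X1, X2, y, "ganB")
        with pytest.raises(ValueError, match="unknown mode"):
            sequential_eval(None, _OracleClassifier(), X1, X2, y, "nope")

    def test_missing_generator_rejected(self, planted):
        X1, X2, y = planted
        with pytest.raises(ValueError, match="generator"):
            sequential_eval(None, _OracleClassifier(), X1, X2, y, "gan3c")


class TestSaliency:
    def test_constant_classifier_zero_map(self, rng):
        from fundusprog.models import ClassifierConfig, build_classifier

        clf = build_classifier(ClassifierConfig(input_size=32, width_scale=0.25))
        clf.head.W.data[...] = 0.0  # logits independent of the input
        clf.head.b.data[...] = 0.0
        heat = saliency_map(clf, rng.random((32, 32, 3)), 0)
        assert heat.shape == (32, 32)
        assert np.all(heat == 0.0)

    def test_shape_range_and_target_validation(self, rng):
        from fundusprog.models import ClassifierConfig, build_classifier

        clf = build_classifier(ClassifierConfig(input_size=32, width_scale=0.25))
        heat = saliency_map(clf, rng.random((32, 32, 3)), 2)
        assert heat.shape == (32, 32)
        assert heat.min() >= 0.0 and heat.max() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            saliency_map(clf, rng.random((32, 32, 3)), 5)
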