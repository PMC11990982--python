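"""Classifier correctness against independent oracles, and metric identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloomcam import kknn
from bloomcam.kknn import (
    KERNELS,
    NEGATIVE,
    POSITIVE,
    ConfusionCounts,
    KknnConfig,
    confusion,
    featureless_baseline,
    fit,
    kernel_weight,
    predict,
    rec_prec_fbeta,
)
from conftest import make_labeled_frame


def random_frame(n, n_features=3, seed=0, pos_share=0.4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    y = rng.random(n) < pos_share
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    df["class"] = np.where(y, POSITIVE, NEGATIVE)
    return df


class TestConfig:
    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            KknnConfig(k=4)

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            KknnConfig(kernel="parabolic")


class TestFit:
    def test_stores_all_training_rows(self):
        df = random_frame(100, seed=1)
        model = fit(df, KknnConfig(k=7), feature_names=["f0", "f1", "f2"])
        assert model.X.shape == (100, 3)

    def test_constant_column_scale_one_with_warning(self):
        df = random_frame(30, seed=2)
        df["f1"] = 5.0
        with pytest.warns(UserWarning, match="scale set to 1"):
            model = fit(df, KknnConfig(k=3), feature_names=["f0", "f1", "f2"])
        assert model.scale[1] == 1.0

    def test_single_class_rejected(self):
        df = random_frame(30, seed=3)
        df["class"] = NEGATIVE
        with pytest.raises(ValueError, match="both classes"):
            fit(df, KknnConfig(k=3), feature_names=["f0"])

    def test_too_few_records_rejected(self):
        df = random_frame(6, seed=4)
        with pytest.raises(ValueError, match="k\\+1"):
            fit(df, KknnConfig(k=7), feature_names=["f0"])

    def test_roundtrip_serialization(self, tmp_path):
        df = random_frame(40, seed=5)
        model = fit(df, KknnConfig(k=5, kernel="triangular"),
                    feature_names=["f0", "f1", "f2"])
        path = tmp_path / "model.json"
        model.save(str(path))
        loaded = kknn.KknnModel.load(str(path))
        q = random_frame(10, seed=6)
        np.testing.assert_array_equal(predict(model, q)[0], predict(loaded, q)[0])


class TestKernelWeights:
    def test_triangular_endpoints(self):
        assert kernel_weight("triangular", 0.0) == 1.0
        assert kernel_weight("triangular", 1.0) == 0.0

    def test_epanechnikov_vanishes_at_one(self):
        assert kernel_weight("epanechnikov", 1.0) == 0.0

    def test_gaussian_ratio_closed_form(self):
        w0 = kernel_weight("gaussian", 0.0)
        w1 = kernel_weight("gaussian", 1.0)
        assert w0 / w1 == pytest.approx(math.exp(0.5), rel=1e-12)

    def test_inv_capped_at_zero_distance(self):
        assert kernel_weight("inv", 0.0) == kknn.INV_CAP
        assert np.isfinite(kernel_weight("inv", 0.0))

    def test_unknown_kernel_errors(self):
        with pytest.raises(ValueError, match="unknown kernel"):
            kernel_weight("boxcar", 0.5)

    @pytest.mark.parametrize("kernel", ["rectangular", "triangular", "epanechnikov",
                                        "biweight", "triweight", "cos", "gaussian"])
    def test_bounded_kernels_non_increasing_on_unit_interval(self, kernel):
        d = np.linspace(0.0, 1.0, 101)
        w = kernel_weight(kernel, d)
        assert np.all(np.diff(w) <= 1e-12)
        assert np.all(w >= 0)

    def test_rank_and_optimal_decrease_with_neighbor_rank(self):
        d = np.sort(np.random.default_rng(0).random(7))
        for kernel in ("rank", "optimal"):
            w = kernel_weight(kernel, d, k=7, dim=3)
            assert w.shape == (7,)
            assert np.all(np.diff(w) <= 1e-12)


class TestPredict:
    def test_rectangular_equals_sklearn_majority_vote(self):
        """Rectangular kernel == unweighted k-NN (independent oracle)."""
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(12)
        train = random_frame(200, n_features=2, seed=12)
        queries = pd.DataFrame(rng.normal(size=(200, 2)), columns=["f0", "f1"])
        for k in (3, 5, 9):
            model = fit(train, KknnConfig(k=k, kernel="rectangular", standardize=False),
                        feature_names=["f0", "f1"])
            pred, _ = predict(model, queries)
            oracle = KNeighborsClassifier(n_neighbors=k, weights="uniform")
            oracle.fit(train[["f0", "f1"]].to_numpy(), train["class"].to_numpy())
            np.testing.assert_array_equal(pred, oracle.predict(queries.to_numpy()))

    def test_neighbor_sets_match_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(3)
        train = random_frame(60, n_features=4, seed=3)
        model = fit(train, KknnConfig(k=5, standardize=False),
                    feature_names=["f0", "f1", "f2", "f3"])
        q = rng.normal(size=(20, 4))
        from scipy.spatial.distance import cdist
        D = cdist(q, train[["f0", "f1", "f2", "f3"]].to_numpy())
        for i in range(q.shape[0]):
            oracle_d = np.sort(D[i])[:5]
            mine = np.sort(D[i][np.argsort(D[i], kind="stable")[:5]])
            np.testing.assert_allclose(mine, oracle_d)

    def test_query_on_training_point_with_positive_neighborhood(self):
        train = make_labeled_frame(n_pos=10, n_neg=10, seed=8)
        model = fit(train, KknnConfig(k=3))
        pos_row = train.loc[train["class"] == POSITIVE].iloc[[0]]
        pred, score = predict(model, pos_row)
        assert pred[0] == POSITIVE and score[0] > 0.5

    def test_exact_weighted_tie_returns_non_flowering(self):
        # symmetric configuration: one positive and one negative at equal
        # distance, k=3 with the third neighbor at the normalization radius
        # (zero triangular weight) -> exact tie
        train = pd.DataFrame({
            "f0": [-1.0, 1.0, 3.0, 100.0, -100.0],
            "class": [POSITIVE, NEGATIVE, NEGATIVE, POSITIVE, NEGATIVE],
        })
        model = fit(train, KknnConfig(k=3, kernel="triangular", standardize=False),
                    feature_names=["f0"])
        pred, score = predict(model, np.array([[0.0]]))
        assert pred[0] == NEGATIVE

    def test_feature_mismatch_errors(self):
        train = random_frame(30, seed=9)
        model = fit(train, KknnConfig(k=3), feature_names=["f0", "f1"])
        with pytest.raises(ValueError, match="missing feature"):
            predict(model, pd.DataFrame({"f0": [0.0]}))

    def test_standardization_shift_invariance(self):
        train = random_frame(80, seed=10)
        q = random_frame(40, seed=11)
        model = fit(train, KknnConfig(k=5, kernel="biweight"),
                    feature_names=["f0", "f1", "f2"])
        shifted_train = train.copy()
        shifted_q = q.copy()
        shifted_train["f1"] += 1000.0
        shifted_q["f1"] += 1000.0
        model2 = fit(shifted_train, KknnConfig(k=5, kernel="biweight"),
                     feature_names=["f0", "f1", "f2"])
        np.testing.assert_array_equal(predict(model, q)[0], predict(model2, shifted_q)[0])

    @pytest.mark.parametrize("kernel", KERNELS)
    def test_every_kernel_classifies_separable_data(self, kernel):
        train = make_labeled_frame(n_pos=30, n_neg=30, separation=6.0, seed=13)
        test = make_labeled_frame(n_pos=15, n_neg=15, separation=6.0, seed=14)
        model = fit(train, KknnConfig(k=5, kernel=kernel))
        pred, _ = predict(model, test)
        assert (pred == test["class"].to_numpy()).mean() == 1.0


class TestConfusionAndMetrics:
    def test_all_correct(self):
        pred = np.array([POSITIVE, NEGATIVE, POSITIVE])
        c = confusion(pred, pred)
        assert c.fp == c.fn == 0 and c.tp == 2 and c.tn == 1

    def test_all_negative_predictions(self):
        true = np.array([POSITIVE] * 5 + [NEGATIVE] * 3)
        pred = np.array([NEGATIVE] * 8)
        c = confusion(pred, true)
        assert c.fn == 5 and c.tp == 0 and c.tn == 3

    def test_random_labels_match_hand_tally(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            pred = rng.choice([POSITIVE, NEGATIVE], size=n)
            true = rng.choice([POSITIVE, NEGATIVE], size=n)
            c = confusion(pred, true)
            tp = fp = fn = tn = 0
            for p, t in zip(pred, true):
                if p == POSITIVE and t == POSITIVE:
                    tp += 1
                elif p == POSITIVE:
                    fp += 1
                elif t == POSITIVE:
                    fn += 1
                else:
                    tn += 1
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            assert c.total == n
            m = rec_prec_fbeta(c)
            if tp + fn:
                assert m.rec == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert m.prec == pytest.approx(tp / (tp + fp))
            if m.prec + m.rec:
                assert m.fbeta == pytest.approx(
                    2 * m.prec * m.rec / (m.prec + m.rec))

    def test_recall_half(self):
        m = rec_prec_fbeta(ConfusionCounts(tp=5, fp=0, fn=5, tn=0))
        assert m.rec == 0.5

    def test_fbeta_closed_form(self):
        # PREC=0.5, REC=1 -> harmonic mean 2/3
        m = rec_prec_fbeta(ConfusionCounts(tp=5, fp=5, fn=0, tn=0))
        assert m.prec == 0.5 and m.rec == 1.0
        assert m.fbeta == pytest.approx(2 / 3)

    def test_degenerate_zero_denominator_flagged(self):
        m = rec_prec_fbeta(ConfusionCounts(tp=0, fp=0, fn=4, tn=6))
        assert m.prec == 0.0 and "prec" in m.undefined

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([POSITIVE], [POSITIVE, NEGATIVE])


@settings(deadline=None, max_examples=25)
@given(
    n_pos=st.integers(1, 20),
    n_neg=st.integers(1, 20),
    k=st.sampled_from([3, 5, 7]),
    seed=st.integers(0, 1000),
)
def test_rectangular_matches_brute_force_majority(n_pos, n_neg, k, seed):
    """Property: rectangular-kernel prediction == brute-force majority vote."""
    if n_pos + n_neg < k + 1:
        return
    train = make_labeled_frame(n_pos=n_pos, n_neg=n_neg, n_features=2,
                               separation=1.0, seed=seed)
    q = np.random.default_rng(seed + 1).normal(size=(10, 2))
    model = fit(train, KknnConfig(k=k, kernel="rectangular", standardize=False))
    pred, _ = predict(model, q)
    X = train[list(model.feature_names)].to_numpy()
    y = train["class"].to_numpy()
    for i in range(q.shape[0]):
        d = np.sqrt(((X - q[i]) ** 2).sum(axis=1))
        nn = np.argsort(d, kind="stable")[:k]
        votes = (y[nn] == POSITIVE).sum()
        expected = POSITIVE if votes > k - votes else NEGATIVE
        assert pred[i] == expected


class TestFeaturelessBaseline:
    def test_majority_negative(self):
        df = make_labeled_frame(n_pos=5, n_neg=45, seed=1)
        clf = featureless_baseline(df)
        pred = clf.predict(df)
        assert set(pred) == {NEGATIVE}
        assert rec_prec_fbeta(confusion(pred, df["class"].to_numpy())).rec == 0.0

    def test_all_positive_training(self):
        df = make_labeled_frame(n_pos=10, n_neg=0, seed=2)
        df["class"] = POSITIVE
        clf = featureless_baseline(df)
        assert set(clf.predict(df)) == {POSITIVE}

    def test_tie_prefers_non_flowering(self):
        df = make_labeled_frame(n_pos=10, n_neg=10, seed=3)
        assert featureless_baseline(df).majority == NEGATIVE

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            featureless_baseline(pd.DataFrame({"class": []}))
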