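"""KNN prediction, LOOCV and confusion-matrix metrics vs brute-force oracles."""

import math

import numpy as np
import pytest

from clauseminer.feature_table import FeatureTable, FeatureSpec, OutcomeError
from clauseminer.knn import (
    ConfusionMatrix,
    KNNConfig,
    fit_scaling,
    knn_predict,
    loocv,
    matrix_metrics,
    train_test_classify,
)
from tests.conftest import make_table


# -- independent oracle: naive all-pairs KNN with the same tie rules ---------


def oracle_predict(train_X, train_y, x, k, scale=None):
    if scale is not None:
        loc, sd = scale
        train_X = (train_X - loc) / sd
        x = (x - loc) / sd
    d = [(math.dist(row, x), i) for i, row in enumerate(train_X)]
    d.sort(key=lambda t: (t[0], t[1]))  # distance tie -> earlier row
    neigh = [i for _, i in d[:k]]
    votes = {}
    for i in neigh:
        votes[train_y[i]] = votes.get(train_y[i], 0) + 1
    top = max(votes.values())
    tied = {c for c, v in votes.items() if v == top}
    for i in neigh:
        if train_y[i] in tied:
            return train_y[i]


def oracle_loocv(table, k, zscore=True):
    correct = {}
    for i in range(table.n_subjects):
        rest = [j for j in range(table.n_subjects) if j != i]
        X = table.values[rest]
        y = [table.outcome[j] for j in rest]
        scale = None
        if zscore:
            sd = X.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            scale = (X.mean(axis=0), sd)
        correct[table.subjects[i]] = oracle_predict(X, y, table.values[i], k, scale)
    return correct


def test_fit_scaling_degenerate_and_standard():
    one = make_table([[1.0, 2.0]], ["x"], target="x", subjects=["only"])
    # single row: zero variance everywhere, scale falls back to 1
    with pytest.warns(UserWarning, match="constant"):
        st = fit_scaling(one)
    assert st.scale.tolist() == [1.0, 1.0]

    t = make_table([[3, 0], [3, 2], [3, 4], [3, 6]], ["a", "a", "b", "b"], target="a")
    with pytest.warns(UserWarning):
        st = fit_scaling(t)
    assert st.scale[0] == 1.0
    assert st.scale[1] == pytest.approx(np.std([0, 2, 4, 6]))

    rng = np.random.default_rng(0)
    big = make_table(rng.normal(size=(30, 4)), ["a"] * 15 + ["b"] * 15, target="a")
    st = fit_scaling(big)
    z = (big.values - st.location) / st.scale
    np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-12)


def test_knn_k1_identical_row(four_point_table):
    cfg = KNNConfig(k=1, scaling="none")
    assert knn_predict(four_point_table, [5, 5], cfg) == "neg"
    assert knn_predict(four_point_table, [0, 0], cfg) == "pos"


def test_knn_k3_plurality(four_point_table):
    cfg = KNNConfig(k=3, scaling="none")
    assert knn_predict(four_point_table, [0.05, 0], cfg) == "pos"


def test_knn_even_k_tie_goes_to_nearest_neighbor_class():
    # k=2 neighborhood holds one point of each class: the vote ties and the
    # single nearest neighbor decides
    t = make_table([[0.0], [4.0], [10.0], [-10.0]], ["pos", "neg", "pos", "neg"],
                   target="pos")
    cfg = KNNConfig(k=2, scaling="none")
    assert knn_predict(t, [1.9], cfg) == "pos"
    assert knn_predict(t, [2.1], cfg) == "neg"


def test_knn_exact_distance_tie_prefers_earlier_row():
    t = make_table([[0.0], [2.0]], ["a", "b"], target="a")
    cfg = KNNConfig(k=1, scaling="none")
    # equidistant from both training rows: earlier row wins the slot
    assert knn_predict(t, [1.0], cfg) == "a"


def test_knn_feature_mismatch_and_k_validation(four_point_table):
    with pytest.raises(ValueError):
        knn_predict(four_point_table, [1.0], KNNConfig(k=1))
    with pytest.raises(ValueError):
        knn_predict(four_point_table, [0, 0], KNNConfig(k=5, scaling="none"))


@pytest.mark.parametrize("k", [1, 2, 3, 7])
@pytest.mark.parametrize("scaling", ["zscore", "none"])
def test_loocv_matches_brute_force_oracle(k, scaling):
    rng = np.random.default_rng(97 + k)
    for trial in range(6):
        n = int(rng.integers(max(k + 2, 10), 41))
        n_pos = int(rng.integers(3, n - 3))
        vals = rng.normal(size=(n, 4)) * rng.uniform(0.1, 100, size=4)
        table = make_table(vals, ["ASD"] * n_pos + ["NT"] * (n - n_pos))
        cm, preds = loocv(table, KNNConfig(k=k, scaling=scaling))
        expect = oracle_loocv(table, k, zscore=scaling == "zscore")
        assert preds == expect
        assert cm.total == n


def test_loocv_perfectly_separated_clusters():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 0.3, size=(8, 3))
    b = rng.normal(8, 0.3, size=(10, 3))
    table = make_table(np.vstack([a, b]), ["ASD"] * 8 + ["NT"] * 10)
    cm, _ = loocv(table, KNNConfig(k=1))
    assert cm.accuracy == 1.0


def test_loocv_four_point_pathology(four_point_table):
    """Each held-out point's k=3 neighborhood is 1 same-class + 2 other-class:
    every fold is misclassified."""
    cm, _ = loocv(four_point_table, KNNConfig(k=3, scaling="none"))
    assert cm.accuracy == 0.0
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (0, 2, 2, 0)


def test_loocv_k_too_large(four_point_table):
    # k may use every row of a fold's training set (k = N-1) but no more
    with pytest.raises(ValueError):
        loocv(four_point_table, KNNConfig(k=4, scaling="none"))


def test_scaling_invariance_under_column_rescaling():
    rng = np.random.default_rng(7)
    vals = rng.normal(size=(20, 3))
    t1 = make_table(vals.copy(), ["ASD"] * 8 + ["NT"] * 12)
    vals2 = vals.copy()
    vals2[:, 1] *= 1e4  # blow up one column
    t2 = make_table(vals2, ["ASD"] * 8 + ["NT"] * 12)
    for k in (1, 3):
        _, p1 = loocv(t1, KNNConfig(k=k, scaling="zscore"))
        _, p2 = loocv(t2, KNNConfig(k=k, scaling="zscore"))
        assert p1 == p2


def test_confusion_marginals_equal_class_counts():
    rng = np.random.default_rng(13)
    vals = rng.normal(size=(25, 3))
    table = make_table(vals, ["ASD"] * 9 + ["NT"] * 16)
    cm, _ = loocv(table, KNNConfig(k=3))
    assert cm.tp + cm.fn == 9
    assert cm.fp + cm.tn == 16


def test_permuted_labels_drop_to_chance():
    """On separable data with permuted labels, LOOCV accuracy collapses to
    about the majority-class rate.  k is large enough that the plurality
    vote almost always returns the majority label, which makes the
    majority rate the exact null expectation up to binomial noise."""
    rng = np.random.default_rng(3)
    a = rng.normal(0, 0.3, size=(10, 3))
    b = rng.normal(8, 0.3, size=(15, 3))
    vals = np.vstack([a, b])
    accs = []
    for _ in range(20):
        labels = np.array(["ASD"] * 10 + ["NT"] * 15)
        rng.shuffle(labels)
        table = make_table(vals, labels.tolist())
        cm, _ = loocv(table, KNNConfig(k=15))
        accs.append(cm.accuracy)
    majority = 15 / 25
    assert abs(np.mean(accs) - majority) < 0.08


def test_train_test_classify_contract():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 0.4, size=(6, 2))
    b = rng.normal(6, 0.4, size=(6, 2))
    train = make_table(np.vstack([a, b]), ["ASD"] * 6 + ["NT"] * 6)
    a2 = rng.normal(0, 0.4, size=(3, 2))
    b2 = rng.normal(6, 0.4, size=(5, 2))
    test = make_table(
        np.vstack([a2, b2]), ["ASD"] * 3 + ["NT"] * 5,
        subjects=[f"T{i}" for i in range(8)],
    )
    cm, preds = train_test_classify(train, test, KNNConfig(k=1))
    assert cm.accuracy == 1.0
    assert len(preds) == 8
    with pytest.raises(ValueError, match="overlap"):
        train_test_classify(train, train, KNNConfig(k=1))


def test_empty_test_table_is_unrepresentable():
    """A zero-subject table violates the two-level outcome invariant, so an
    empty test set fails before it ever reaches the classifier."""
    with pytest.raises(OutcomeError):
        FeatureTable([], [FeatureSpec("f")], np.empty((0, 1)), [], "ASD")


def test_matrix_metrics_published_cross_validation_cells():
    """The published second-order validation matrix: 8/1 vs 2/17."""
    cm = ConfusionMatrix(tp=8, fn=1, fp=2, tn=17)
    m = matrix_metrics(cm)
    assert m["accuracy"] == pytest.approx(25 / 28)
    assert f"{100 * m['accuracy']:.2f}" == "89.29"
    assert m["ppv"] == pytest.approx(0.80)
    assert m["recall"] == pytest.approx(8 / 9)


def test_matrix_metrics_edges():
    perfect = ConfusionMatrix(tp=5, fn=0, fp=0, tn=9)
    assert matrix_metrics(perfect)["accuracy"] == 1.0
    none_pos = ConfusionMatrix(tp=0, fn=3, fp=0, tn=9)
    m = matrix_metrics(none_pos)
    assert not m["ppv_defined"]
    with pytest.raises(ValueError):
        matrix_metrics(ConfusionMatrix())


def test_against_sklearn_on_tie_free_data():
    """Independent route: scikit-learn agrees wherever no tie rule fires
    (odd k, generic real-valued positions)."""
    sklearn = pytest.importorskip("sklearn.neighbors")
    rng = np.random.default_rng(21)
    X = rng.normal(size=(30, 4))
    y = np.array(["ASD"] * 12 + ["NT"] * 18)
    table = make_table(X, y.tolist())
    clf = sklearn.KNeighborsClassifier(n_neighbors=3)
    clf.fit(X, y)
    queries = rng.normal(size=(15, 4))
    cfg = KNNConfig(k=3, scaling="none")
    for q in queries:
        assert knn_predict(table, q, cfg) == clf.predict(q[None, :])[0]
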