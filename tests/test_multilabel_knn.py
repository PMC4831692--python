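"""Single-label IB1 and the three multi-label KNN classifiers."""

import numpy as np
import pytest

from mlec import (
    MultiLabelDataset,
    NeighborModel,
    brknn_predict,
    iblr_fit,
    iblr_predict,
    knn_predict_single,
    mlknn_fit,
    mlknn_predict,
)
from mlec.knn import IBLRClassifier, kneighbors


def single_label(classes, m=2):
    Y = np.zeros((len(classes), m), dtype=int)
    Y[np.arange(len(classes)), classes] = 1
    return Y


def make_ds(X, Y):
    return MultiLabelDataset(
        ids=[f"s{i}" for i in range(len(X))], X=np.asarray(X), Y=np.asarray(Y)
    )


class TestSingleLabelKNN:
    # 2-D layout around a query at the origin: the 3 closest points are
    # 2 squares (class 1) + 1 triangle (class 0); the next 2 are triangles.
    X = np.array(
        [[0.1, 0], [0, 0.15], [0.2, 0.1],  # square, square, triangle
         [0.5, 0.5], [-0.6, 0.2]]          # triangle, triangle
    )
    classes = [1, 1, 0, 0, 0]

    def test_k3_majority_picks_squares(self):
        model = NeighborModel(self.X, single_label(self.classes), k=3)
        assert knn_predict_single(model, [[0, 0]]) == [1]

    def test_k5_majority_picks_triangles(self):
        model = NeighborModel(self.X, single_label(self.classes), k=5)
        assert knn_predict_single(model, [[0, 0]]) == [0]

    def test_single_training_point_always_wins(self):
        model = NeighborModel([[1.0, 1.0]], single_label([1]), k=1)
        assert knn_predict_single(model, [[50, -3], [0, 0]]).tolist() == [1, 1]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="k"):
            NeighborModel(self.X, single_label(self.classes), k=6)

    def test_multilabel_training_rejected(self):
        Y = np.array([[1, 1]] * 5)
        model = NeighborModel(self.X, Y, k=1)
        with pytest.raises(ValueError, match="single-label"):
            knn_predict_single(model, [[0, 0]])


class TestNeighborSearch:
    def test_matches_bruteforce_all_pairs(self, rng):
        X = rng.normal(size=(40, 5))
        Q = rng.normal(size=(7, 5))
        model = NeighborModel(X, np.ones((40, 1), dtype=int), k=6)
        got = kneighbors(model, Q)
        for qi in range(7):
            d = [(float(np.linalg.norm(Q[qi] - X[t])), t) for t in range(40)]
            expect = [t for _, t in sorted(d)[:6]]
            assert got[qi].tolist() == expect

    def test_distance_ties_break_by_training_index(self):
        X = np.array([[1.0], [1.0], [1.0], [2.0]])
        model = NeighborModel(X, np.ones((4, 1), dtype=int), k=3)
        assert kneighbors(model, [[1.0]])[0].tolist() == [0, 1, 2]


class TestMLkNN:
    def test_smoothed_prior_all_positive(self):
        # label present in all 4 samples, s=1 → (1+4)/(2+4) = 5/6
        ds = make_ds(np.arange(8).reshape(4, 2), [[1, 0]] * 4)
        model = mlknn_fit(ds, k=2, s=1.0)
        assert model.prior[0] == pytest.approx(5 / 6)

    def test_smoothed_prior_all_negative_scores_below_half(self, rng):
        ds = make_ds(rng.normal(size=(4, 2)), [[1, 0]] * 4)
        model = mlknn_fit(ds, k=2, s=1.0)
        assert model.prior[1] == pytest.approx(1 / 6)
        pred = mlknn_predict(model, rng.normal(size=(5, 2)))
        assert (pred.scores[:, 1] < 0.5).all()
        assert (pred.bipartition[:, 1] == 0).all()

    def test_probabilities_strictly_inside_unit_interval(self, separable_dataset):
        model = mlknn_fit(separable_dataset, k=5)
        for arr in (model.prior, model.cond_present, model.cond_absent):
            assert ((arr > 0) & (arr < 1)).all()

    def test_separable_groups_get_correct_posteriors(self):
        # two well-separated clusters with complementary labels
        X = np.vstack([np.zeros((3, 2)), np.full((3, 2), 10.0)])
        Y = [[1, 0]] * 3 + [[0, 1]] * 3
        model = mlknn_fit(make_ds(X, Y), k=2, s=1.0)
        pred = mlknn_predict(model, [[0.1, 0.1], [9.9, 9.9]])
        # hand Bayes with s=1, k=2: prior P(A)=(1+3)/(2+6)=1/2; at fit time
        # (self excluded) A samples see c_A=2 → P(c=2|A)=(1+3)/(3+3)=2/3,
        # B samples see c_A=0 → P(c=2|¬A)=(1+0)/(3+3)=1/6; a query next to
        # cluster A has c_A=2 → posterior (1/2·2/3)/(1/2·2/3+1/2·1/6)=0.8
        # and symmetrically c_B=0 → posterior 0.2
        assert pred.scores[0, 0] == pytest.approx(0.8)
        assert pred.scores[0, 1] == pytest.approx(0.2)
        assert pred.scores[1, 1] == pytest.approx(0.8)
        assert pred.scores[1, 0] == pytest.approx(0.2)
        assert (pred.bipartition == [[1, 0], [0, 1]]).all()

    def test_scores_bounded_and_deterministic(self, separable_dataset, rng):
        model = mlknn_fit(separable_dataset, k=5)
        Q = rng.normal(size=(10, separable_dataset.n_features))
        a = mlknn_predict(model, Q)
        b = mlknn_predict(model, Q)
        assert ((a.scores >= 0) & (a.scores <= 1)).all()
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_posterior_monotone_in_neighbor_count(self, rng):
        # with any fitted model the posterior must be non-decreasing in c_j
        # when conditionals come from a consistent neighborhood structure;
        # check on random fits via direct posterior evaluation
        for trial in range(5):
            X = rng.normal(size=(30, 4))
            Y = (rng.random((30, 3)) < 0.4).astype(int)
            model = mlknn_fit(make_ds(X, Y), k=6, s=1.0)
            for j in range(3):
                post = [
                    model.prior[j] * model.cond_present[j, c]
                    / (
                        model.prior[j] * model.cond_present[j, c]
                        + (1 - model.prior[j]) * model.cond_absent[j, c]
                    )
                    for c in range(7)
                ]
                # not guaranteed strictly monotone for arbitrary data, but a
                # larger neighbor count should never collapse the posterior
                # from certainly-present to certainly-absent
                assert post[-1] > min(post) - 1e-12

    def test_k_at_least_n_rejected(self, rng):
        ds = make_ds(rng.normal(size=(4, 2)), [[1, 0]] * 4)
        with pytest.raises(ValueError, match="k"):
            mlknn_fit(ds, k=4)


class TestBRkNN:
    def test_k1_copies_nearest_neighbor_label_set(self):
        X = [[0.0], [1.0], [2.0]]
        Y = [[1, 1, 0], [0, 1, 0], [0, 0, 1]]
        model = NeighborModel(X, Y, k=1)
        pred = brknn_predict(model, [[0.1], [1.9]])
        assert pred.bipartition.tolist() == [[1, 1, 0], [0, 0, 1]]

    def test_two_of_three_neighbors_give_two_thirds(self):
        X = [[0.0], [0.1], [0.2], [5.0]]
        Y = [[1], [1], [0], [0]]
        model = NeighborModel(X, Y, k=3)
        pred = brknn_predict(model, [[0.0]])
        assert pred.scores[0, 0] == pytest.approx(2 / 3)
        assert pred.bipartition[0, 0] == 1

    def test_all_scores_at_half_fall_back_to_single_top_label(self):
        X = [[0.0], [0.1], [0.2], [0.3]]
        Y = [[1, 0], [0, 1], [1, 0], [0, 1]]  # every label at exactly 2/4
        model = NeighborModel(X, Y, k=4)
        pred = brknn_predict(model, [[0.15]])
        assert pred.scores[0].tolist() == [0.5, 0.5]
        assert pred.bipartition[0].tolist() == [1, 0]  # lowest index wins

    def test_score_equals_bruteforce_neighbor_fraction(self, rng):
        X = rng.normal(size=(30, 3))
        Y = (rng.random((30, 4)) < 0.3).astype(int)
        Q = rng.normal(size=(5, 3))
        model = NeighborModel(X, Y, k=7)
        pred = brknn_predict(model, Q)
        for qi in range(5):
            d = [(float(np.linalg.norm(Q[qi] - X[t])), t) for t in range(30)]
            nbrs = [t for _, t in sorted(d)[:7]]
            np.testing.assert_allclose(pred.scores[qi], Y[nbrs].mean(axis=0))


class TestIBLR:
    def test_separable_training_accuracy(self, separable_dataset):
        model = iblr_fit(separable_dataset, k=10)
        pred = iblr_predict(model, separable_dataset.X)
        agree = (pred.bipartition == separable_dataset.Y).mean()
        assert agree >= 0.9

    def test_scores_strictly_inside_unit_interval(self, separable_dataset, rng):
        model = iblr_fit(separable_dataset, k=10)
        pred = iblr_predict(model, rng.normal(size=(6, separable_dataset.n_features)))
        assert ((pred.scores > 0) & (pred.scores < 1)).all()

    def test_constant_label_falls_back_to_clipped_prior(self, rng):
        X = rng.normal(size=(10, 3))
        Y = np.hstack([np.ones((10, 1), int), (rng.random((10, 1)) < 0.5).astype(int)])
        if Y[:, 1].min() == Y[:, 1].max():  # ensure second label varies
            Y[0, 1] = 1 - Y[0, 1]
        model = iblr_fit(make_ds(X, Y), k=3)
        pred = iblr_predict(model, rng.normal(size=(4, 3)))
        assert (pred.scores[:, 0] == 0.99).all()


class TestClassifierWrappers:
    def test_fit_predict_roundtrip_deterministic(self, separable_dataset):
        clf = IBLRClassifier(k=10).fit(separable_dataset)
        a = clf.predict(separable_dataset.X[:5])
        b = clf.predict(separable_dataset.X[:5])
        np.testing.assert_array_equal(a.scores, b.scores)
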