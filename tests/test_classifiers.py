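"""KNN, Gaussian discriminant analysis, and SVM against closed forms and
brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ppgmark.classifiers import (DiscriminantModel, KNNModel, SVMModel,
                                 load_model, make_model, minkowski_distance,
                                 save_model)


class TestMinkowskiDistance:
    def test_three_four_five(self):
        assert minkowski_distance((0, 0), (3, 4), 2) == pytest.approx(5.0)

    def test_cityblock(self):
        assert minkowski_distance((1, 1), (4, 5), 1) == pytest.approx(7.0)

    def test_large_p_approaches_chebyshev(self):
        assert minkowski_distance((0, 0), (3, 4), 50) == pytest.approx(4.0,
                                                                       abs=1e-2)

    def test_order_below_one_rejected(self):
        with pytest.raises(ValueError):
            minkowski_distance((0, 0), (1, 1), 0.5)

    def test_euclidean_and_cityblock_equivalences(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = rng.normal(size=(2, 5))
            assert minkowski_distance(x, y, 2) == pytest.approx(
                float(np.sqrt(np.sum((x - y) ** 2))), abs=1e-12)
            assert minkowski_distance(x, y, 1) == pytest.approx(
                float(np.sum(np.abs(x - y))), abs=1e-12)


def brute_force_knn(X, y, query, k, metric, weighting, p=2.0, VI=None):
    """Independent full-sort KNN with the documented tie rules."""
    diffs = X - query
    if metric == "euclidean":
        d = np.sqrt((diffs**2).sum(axis=1))
    elif metric == "cityblock":
        d = np.abs(diffs).sum(axis=1)
    elif metric == "chebychev":
        d = np.abs(diffs).max(axis=1)
    elif metric == "minkowski":
        d = (np.abs(diffs) ** p).sum(axis=1) ** (1.0 / p)
    elif metric == "mahalanobis":
        d = np.sqrt(np.einsum("ij,jk,ik->i", diffs, VI, diffs))
    elif metric == "cosine":
        d = 1 - (X @ query) / (np.linalg.norm(X, axis=1)
                               * np.linalg.norm(query))
    elif metric == "correlation":
        Xc = X - X.mean(axis=1, keepdims=True)
        qc = query - query.mean()
        d = 1 - (Xc @ qc) / (np.linalg.norm(Xc, axis=1) * np.linalg.norm(qc))
    else:
        raise ValueError(metric)
    order = np.argsort(d, kind="stable")[:k]
    nd, ny = d[order], y[order]
    if weighting == "inverse" and nd[0] == 0.0:
        return int(ny[nd == 0.0][0])
    w = 1.0 / nd if weighting == "inverse" else np.ones_like(nd)
    w1, w0 = w[ny == 1].sum(), w[ny == 0].sum()
    if w1 > w0:
        return 1
    if w0 > w1:
        return 0
    return int(ny[0])


class TestKNN:
    def test_exact_training_point_k1_returns_its_label(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, 30)
        for metric in ("euclidean", "cityblock", "chebychev"):
            model = KNNModel(k=1, metric=metric).fit(X, y)
            pred, _ = model.predict(X[7])
            assert pred[0] == y[7]

    def test_k1_zero_training_error_on_distinct_points(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, 50)
        model = KNNModel(k=1, metric="euclidean", weighting="uniform").fit(X, y)
        pred, _ = model.predict(X)
        assert np.array_equal(pred, y)

    def test_matches_bruteforce_oracle_small(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            X = rng.normal(size=(60, 3))
            y = rng.integers(0, 2, 60)
            Q = rng.normal(size=(20, 3))
            for metric in ("euclidean", "cityblock", "minkowski", "chebychev"):
                for weighting in ("uniform", "inverse"):
                    for k in (1, 3, 6):
                        model = KNNModel(k=k, metric=metric, p=3.0,
                                         weighting=weighting).fit(X, y)
                        pred, _ = model.predict(Q)
                        Z = model._scale(X)
                        Zq = model._scale(Q)
                        expected = [brute_force_knn(Z, y, q, k, metric,
                                                    weighting, p=3.0)
                                    for q in Zq]
                        assert pred.tolist() == expected

    def test_inverse_weighting_exact_match_wins_outright(self):
        X = np.array([[0.0, 0], [1, 0], [1.01, 0], [0.99, 0]])
        y = np.array([1, 0, 0, 0])
        model = KNNModel(k=4, metric="euclidean", weighting="inverse").fit(X, y)
        pred, score = model.predict(np.array([[0.0, 0.0]]))
        assert pred[0] == 1  # the d=0 neighbor overrides three near ones
        assert score[0] == 1.0

    def test_uniform_tie_breaks_to_nearest_neighbor(self):
        X = np.array([[0.0], [1.0], [3.0], [4.0]])
        y = np.array([1, 1, 0, 0])
        model = KNNModel(k=4, metric="euclidean", weighting="uniform").fit(X, y)
        pred, _ = model.predict(np.array([[1.9]]))
        assert pred[0] == 1  # 2-2 vote; nearest neighbor (1.0, class 1) decides

    def test_query_dimension_mismatch(self):
        model = KNNModel(k=1).fit(np.zeros((5, 3)), np.array([0, 1, 0, 1, 0]))
        with pytest.raises(ValueError):
            model.predict(np.zeros((1, 4)))

    def test_k_larger_than_training_set(self):
        with pytest.raises(ValueError):
            KNNModel(k=10).fit(np.zeros((5, 2)), np.array([0, 1, 0, 1, 0]))

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        model = KNNModel(k=3, weighting="inverse").fit(X, y)
        path = tmp_path / "knn.json"
        save_model(model, path)
        back = load_model(path)
        Q = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(model.predict(Q)[0], back.predict(Q)[0])


class TestDiscriminant:
    def _clouds(self, rng, d=2, n=60, sep=4.0):
        X0 = rng.normal(0, 1, size=(n, d))
        X1 = rng.normal(sep, 1, size=(n, d))
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], n)
        return X, y

    def test_query_at_class_mean_assigned_to_that_class(self):
        rng = np.random.default_rng(5)
        X, y = self._clouds(rng)
        for kind in ("linear", "quadratic"):
            model = DiscriminantModel(kind=kind).fit(X, y)
            pred, post = model.predict(X[y == 1].mean(axis=0))
            assert pred[0] == 1
            assert post[0] > 0.99

    def test_1d_equal_variance_boundary_at_midpoint(self):
        rng = np.random.default_rng(6)
        x0 = rng.normal(0, 1, 4000)
        x1 = rng.normal(3, 1, 4000)
        X = np.concatenate([x0, x1])[:, None]
        y = np.repeat([0, 1], 4000)
        model = DiscriminantModel(kind="linear").fit(X, y)

        def margin(v):
            post = model.posterior(np.array([[v]]))[0]
            return post[1] - post[0]

        boundary = brentq(margin, 0.0, 3.0, xtol=1e-9)
        midpoint = 0.5 * (x0.mean() + x1.mean())
        assert boundary == pytest.approx(midpoint, abs=1e-6)

    def test_asymmetric_cost_flips_decision(self):
        rng = np.random.default_rng(7)
        X, y = self._clouds(rng)
        # query with posterior ~0.2 for class 1
        plain = DiscriminantModel(kind="linear").fit(X, y)
        grid = np.linspace(0, 4, 400)[:, None]
        posts = plain.posterior(np.hstack([grid, grid]))[:, 1]
        q = np.hstack([grid, grid])[np.argmin(np.abs(posts - 0.2))]
        assert plain.predict(q)[0][0] == 0
        # predicting 0 when truth is 1 now costs 10x: expected cost flips
        cost = np.array([[0.0, 10.0], [1.0, 0.0]])
        costly = DiscriminantModel(kind="linear", cost=cost).fit(X, y)
        assert costly.predict(q)[0][0] == 1

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(8)
        X, y = self._clouds(rng)
        model = DiscriminantModel(kind="quadratic").fit(X, y)
        post = model.posterior(rng.normal(2, 3, size=(50, 2)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_one_cost_equals_posterior_argmax(self):
        rng = np.random.default_rng(9)
        X, y = self._clouds(rng, sep=1.5)
        model = DiscriminantModel(kind="quadratic").fit(X, y)
        Q = rng.normal(0.7, 2, size=(100, 2))
        pred, _ = model.predict(Q)
        post = model.posterior(Q)
        np.testing.assert_array_equal(pred, np.argmax(post, axis=1))

    def test_singular_covariance_regularized(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        X = np.column_stack([x, x])  # perfectly collinear features
        y = (x > 0).astype(int)
        model = DiscriminantModel(kind="quadratic").fit(X, y)
        pred, _ = model.predict(np.array([[2.0, 2.0]]))
        assert pred[0] == 1

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        X, y = self._clouds(rng)
        model = DiscriminantModel(kind="quadratic").fit(X, y)
        save_model(model, tmp_path / "da.json")
        back = load_model(tmp_path / "da.json")
        Q = rng.normal(2, 2, size=(20, 2))
        np.testing.assert_allclose(model.posterior(Q), back.posterior(Q),
                                   atol=1e-12)


class TestSVM:
    def test_two_point_maximal_margin_closed_form(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array([0, 1])
        model = SVMModel(C=1e6, kernel="linear").fit(X, y)
        np.testing.assert_allclose(model.beta_, [1.0, 0.0], atol=1e-3)
        assert model.b_ == pytest.approx(-1.0, abs=1e-3)
        # support vectors lie on the margin: |f(x_j)| = 1
        f = model.decision_function(X)
        np.testing.assert_allclose(np.abs(f), 1.0, atol=1e-3)
        # a point on the hyperplane scores ~0
        assert model.decision_function(np.array([[1.0, 5.0]]))[0] == \
            pytest.approx(0.0, abs=1e-3)

    def test_label_flip_negates_decision_values(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(3, 1, (20, 2))])
        y = np.repeat([0, 1], 20)
        a = SVMModel(C=1.0, kernel="linear").fit(X, y)
        b = SVMModel(C=1.0, kernel="linear").fit(X, 1 - y)
        Q = rng.normal(1.5, 1, size=(30, 2))
        # agreement bounded by the solver's 1e-3 feasibility-gap tolerance
        np.testing.assert_allclose(a.decision_function(Q),
                                   -b.decision_function(Q), atol=5e-3)

    def test_translation_invariance_linear_kernel(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(3, 1, (20, 2))])
        y = np.repeat([0, 1], 20)
        Q = rng.normal(1.5, 1, size=(30, 2))
        shift = np.array([100.0, -50.0])
        a = SVMModel(C=1.0, kernel="linear").fit(X, y)
        b = SVMModel(C=1.0, kernel="linear").fit(X + shift, y)
        np.testing.assert_array_equal(a.predict(Q)[0], b.predict(Q + shift)[0])

    def test_dual_objective_matches_bruteforce_qp(self):
        """Tiny separable instance vs an independent dual QP solve."""
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(-2, 0.5, (10, 2)), rng.normal(2, 0.5, (10, 2))])
        y01 = np.repeat([0, 1], 10)
        C = 5.0
        model = SVMModel(C=C, kernel="linear").fit(X, y01)
        Z = model._scale(X)
        s = np.where(y01 == 1, 1.0, -1.0)
        K = (Z @ Z.T) * np.outer(s, s)

        def neg_dual(alpha):
            return 0.5 * alpha @ K @ alpha - alpha.sum()

        from scipy.optimize import minimize
        res = minimize(neg_dual, np.full(20, 0.1),
                       jac=lambda a: K @ a - 1,
                       bounds=[(0, C)] * 20,
                       constraints=[{"type": "eq", "fun": lambda a: a @ s,
                                     "jac": lambda a: s}],
                       method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
        # package dual objective from its dual coefficients
        dual = np.zeros(20)
        dual[model._svc.support_] = np.abs(model._svc.dual_coef_[0])
        assert -neg_dual(dual) == pytest.approx(-res.fun, abs=1e-3)

    def test_more_box_never_more_margin_violations(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal(0, 1, (25, 2)), rng.normal(4, 1, (25, 2))])
        y = np.repeat([0, 1], 25)
        s = np.where(y == 1, 1.0, -1.0)
        violations = []
        for C in (0.01, 0.1, 1.0, 10.0):
            m = SVMModel(C=C, kernel="linear").fit(X, y)
            f = m.decision_function(X)
            violations.append(int(np.sum(s * f < 1 - 1e-6)))
        assert all(a >= b for a, b in zip(violations, violations[1:]))

    @pytest.mark.parametrize("kernel", ["gaussian", "cubic"])
    def test_nonlinear_kernels_fit_and_predict(self, kernel):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(3, 1, (30, 2))])
        y = np.repeat([0, 1], 30)
        model = SVMModel(C=1.0, kernel=kernel).fit(X, y)
        pred, f = model.predict(X)
        assert np.mean(pred == y) > 0.9
        assert np.array_equal(pred, (f > 0).astype(int))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            SVMModel(C=0.0)
        with pytest.raises(ValueError):
            SVMModel(kernel="sigmoid")
        with pytest.raises(ValueError):
            make_model("boosting")
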