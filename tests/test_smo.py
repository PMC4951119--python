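"""The SMO-trained SVM engine: dual optimality, KKT, voting, scoring."""

import numpy as np
import pytest
from scipy.optimize import minimize

from brainmarkers.datamodel import REGIONS
from brainmarkers.smo import (
    ALPHA_BOUND_EPS,
    _combine_votes,
    dual_objective,
    load_binary_model,
    predict_binary,
    predict_multiclass,
    save_binary_model,
    score_predictions,
    train_binary,
    train_multiclass,
)


def qp_dual_optimum(Z, y, C):
    """Generic QP solve of the SVM dual (independent oracle)."""
    n = Z.shape[0]
    Q = (y[:, None] * y[None, :]) * (Z @ Z.T)

    def neg_obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(n)

    res = minimize(
        neg_obj,
        np.zeros(n),
        jac=grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y,
                      "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success, res.message
    return -res.fun


def random_problem(seed, n_max=30, separable=False):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, n_max + 1))
    d = int(rng.integers(1, 6))
    X = rng.normal(size=(n, d))
    if separable:
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        X[:, 0] += 2.0 * y
    else:
        y = np.where(X[:, 0] + rng.normal(scale=1.5, size=n) > 0, 1.0, -1.0)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    return X, y


class TestBinarySVM:
    def test_symmetric_two_point_problem(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = train_binary(X, y, C=100.0)
        np.testing.assert_allclose(model.alpha, [0.5, 0.5], atol=1e-9)
        assert model.bias == pytest.approx(0.0, abs=1e-9)
        f, labels = predict_binary(model, np.array([[-1.0], [0.0], [1.0]]))
        np.testing.assert_allclose(f, [-1.0, 0.0, 1.0], atol=1e-9)
        # margins are +-1 on the training points; zero maps to the first label
        assert labels.tolist() == ["-1", "+1", "+1"]

    def test_separable_matches_qp_objective(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(size=(3, 2)) - 3, rng.normal(size=(3, 2)) + 3])
        y = np.array([-1.0] * 3 + [1.0] * 3)
        model = train_binary(X, y, C=1.0, tol=1e-6)
        Z = (X - model.mean) / model.scale
        assert dual_objective(model) == pytest.approx(
            qp_dual_optimum(Z, y, 1.0), rel=1e-4
        )

    def test_small_c_overlap_boxes_and_kkt(self):
        X, y = random_problem(5, separable=False)
        model = train_binary(X, y, C=0.01, tol=1e-6)
        a, C = model.alpha, model.C
        assert np.all((a >= -ALPHA_BOUND_EPS) & (a <= C + ALPHA_BOUND_EPS))
        Z = (X - model.mean) / model.scale
        f = Z @ model.weights + model.bias
        margins = model.y * f
        free = (a > ALPHA_BOUND_EPS) & (a < C - ALPHA_BOUND_EPS)
        at_zero = a <= ALPHA_BOUND_EPS
        at_c = a >= C - ALPHA_BOUND_EPS
        assert np.all(margins[at_zero] >= 1 - 1e-4)
        assert np.all(margins[at_c] <= 1 + 1e-4)
        assert np.allclose(margins[free], 1.0, atol=1e-4)

    @pytest.mark.parametrize("seed", range(8))
    def test_qp_objective_and_kkt_on_random_problems(self, seed):
        X, y = random_problem(seed, separable=seed % 2 == 0)
        model = train_binary(X, y, C=1.0, tol=1e-6)
        Z = (X - model.mean) / model.scale
        opt = qp_dual_optimum(Z, y, 1.0)
        assert dual_objective(model) == pytest.approx(opt, rel=1e-4, abs=1e-7)
        assert abs(model.alpha @ model.y) < 1e-8

    def test_predictions_agree_with_qp_model_off_boundary(self):
        X, y = random_problem(11)
        model = train_binary(X, y, C=1.0, tol=1e-6)
        from sklearn.svm import SVC

        Z = (X - model.mean) / model.scale
        sk = SVC(kernel="linear", C=1.0, tol=1e-8).fit(Z, y)
        grid = np.random.default_rng(0).normal(size=(100, X.shape[1]))
        f_mine = grid @ model.weights + model.bias
        f_ref = sk.decision_function(grid)
        off = np.abs(f_mine) > 1e-6
        assert np.array_equal(np.sign(f_mine[off]), np.sign(f_ref[off]))

    def test_affine_feature_rescaling_is_invariant(self):
        X, y = random_problem(3)
        model = train_binary(X, y, C=1.0, tol=1e-6)
        X2 = X.copy()
        X2[:, 0] = 5.0 * X2[:, 0] - 7.0  # affine rescale of one feature
        model2 = train_binary(X2, y, C=1.0, tol=1e-6)
        grid = np.random.default_rng(1).normal(size=(50, X.shape[1]))
        grid2 = grid.copy()
        grid2[:, 0] = 5.0 * grid2[:, 0] - 7.0
        _, l1 = predict_binary(model, grid)
        _, l2 = predict_binary(model2, grid2)
        assert l1.tolist() == l2.tolist()

    @pytest.mark.parametrize(
        "bad",
        [
            dict(y=np.ones(4)),  # single class
            dict(X=np.array([[np.nan, 0]] * 4)),  # non-finite
        ],
    )
    def test_invalid_training_inputs(self, bad):
        X = np.arange(8.0).reshape(4, 2)
        y = np.array([1.0, 1.0, -1.0, -1.0])
        kwargs = dict(X=X, y=y)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            train_binary(kwargs["X"], kwargs["y"])

    def test_dimension_mismatch_on_predict(self):
        model = train_binary(
            np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]), C=1.0
        )
        with pytest.raises(ValueError):
            predict_binary(model, np.zeros((2, 3)))

    def test_serialization_round_trip(self, tmp_path):
        X, y = random_problem(2)
        model = train_binary(X, y, C=1.0, class_pair=("BS", "CB"))
        save_binary_model(model, tmp_path / "m.tsv")
        back = load_binary_model(tmp_path / "m.tsv")
        assert back.class_pair == model.class_pair
        np.testing.assert_array_equal(back.alpha, model.alpha)
        np.testing.assert_array_equal(back.weights, model.weights)
        grid = np.random.default_rng(0).normal(size=(20, X.shape[1]))
        np.testing.assert_array_equal(
            back.decision_function(grid), model.decision_function(grid)
        )


def blobs(seed=0, n=12, spread=0.3):
    rng = np.random.default_rng(seed)
    centers = {"BS": (-4, 0), "CB": (4, 0), "CC": (0, 6)}
    X, y = [], []
    for r, c in centers.items():
        X.append(rng.normal(scale=spread, size=(n, 2)) + np.array(c))
        y += [r] * n
    return np.vstack(X), np.array(y, dtype=object)


class TestMulticlass:
    def test_separable_blobs_perfect_training_accuracy(self):
        X, y = blobs()
        model = train_multiclass(X, y)
        pred = predict_multiclass(model, X)
        assert score_predictions(y, pred).total_accuracy == 1.0

    def test_deep_inside_blob_gets_two_votes(self):
        X, y = blobs()
        model = train_multiclass(X, y)
        pred = predict_multiclass(model, np.array([[-4.0, 0.0]]))
        assert pred[0] == "BS"

    def test_absent_class_predicts_remaining_pair(self):
        X, y = blobs()
        keep = y != "CB"
        model = train_multiclass(X[keep], y[keep])
        pred = predict_multiclass(model, X)
        assert set(pred) == {"BS", "CC"}

    def test_single_class_rejected(self):
        X, y = blobs()
        with pytest.raises(ValueError):
            train_multiclass(X[y == "BS"], y[y == "BS"])

    def test_empty_input_gives_empty_labels(self):
        X, y = blobs()
        model = train_multiclass(X, y)
        assert predict_multiclass(model, np.empty((0, 2))).size == 0

    def test_two_class_problem_reduces_to_binary(self):
        X, y = blobs()
        keep = y != "CC"
        model = train_multiclass(X[keep], y[keep])
        binary = model.models[("BS", "CB")]
        f, labels = predict_binary(binary, X[keep])
        pred = predict_multiclass(model, X[keep])
        assert pred.tolist() == labels.tolist()

    def test_rock_paper_scissors_tie_uses_margin_sums(self):
        # one vote each: BS beats CB (+0.4), CB beats CC (+0.9), CC beats BS
        # (decision -0.2 on the BS|CC model). margin sums: BS 0.4, CB 0.9,
        # CC 0.2 -> CB wins.
        decisions = {
            ("BS", "CB"): np.array([0.4]),
            ("BS", "CC"): np.array([-0.2]),
            ("CB", "CC"): np.array([0.9]),
        }
        assert _combine_votes(decisions)[0] == "CB"

    def test_margin_sum_tie_falls_back_to_label_order(self):
        decisions = {
            ("BS", "CB"): np.array([0.5]),
            ("BS", "CC"): np.array([-0.5]),
            ("CB", "CC"): np.array([0.5]),
        }
        # votes 1 each; margin sums equal (0.5) -> smallest label BS wins
        assert _combine_votes(decisions)[0] == "BS"


class TestScoring:
    def test_perfect_predictions(self):
        r = score_predictions(["BS", "CB", "CC"], ["BS", "CB", "CC"])
        assert r.total_accuracy == 1.0
        assert all(r.class_accuracy(c) == 1.0 for c in REGIONS)

    def test_majority_class_predictor(self):
        truth = ["BS", "CB", "CC", "CC"]
        r = score_predictions(truth, ["CC"] * 4)
        assert r.total_accuracy == 0.5
        assert (r.class_accuracy("BS"), r.class_accuracy("CB"),
                r.class_accuracy("CC")) == (0.0, 0.0, 1.0)

    def test_matches_direct_tally_on_random_labels(self):
        rng = np.random.default_rng(9)
        truth = [REGIONS[i] for i in rng.integers(0, 3, size=200)]
        pred = [REGIONS[i] for i in rng.integers(0, 3, size=200)]
        r = score_predictions(truth, pred)
        assert r.n_correct == sum(t == p for t, p in zip(truth, pred))
        for c in REGIONS:
            n_c = sum(t == c for t in truth)
            hit = sum(t == c and p == c for t, p in zip(truth, pred))
            assert r.per_class[c] == (hit, n_c)

    def test_absent_class_is_not_applicable(self):
        r = score_predictions(["BS", "CB"], ["BS", "CB"])
        assert r.class_accuracy("CC") is None

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            score_predictions(["BS"], [])
        with pytest.raises(ValueError):
            score_predictions([], [])
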