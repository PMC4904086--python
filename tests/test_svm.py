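import numpy as np
import pytest

from _oracles import random_svm_instance, svm_dual_qp
from mibci import (
    SVMModel,
    TrainingSet,
    decision_value,
    decision_values,
    predict,
    rbf_kernel,
    rbf_kernel_matrix,
    train_svm,
)
from mibci.errors import ValidationError


def kkt_report(model, data):
    """Return (max box violation, equality residual, max free-SV margin error)."""
    x, y = data.features, data.labels
    alpha_y = np.zeros(len(y))
    # reconstruct alpha*y on the full set from support vectors
    sv_map = {tuple(v): c for v, c in zip(map(tuple, model.support_vectors), model.dual_coefs)}
    for i, row in enumerate(map(tuple, x)):
        alpha_y[i] = sv_map.get(row, 0.0)
    alpha = alpha_y * y
    box = max(np.max(-alpha), np.max(alpha - model.penalty_C), 0.0)
    eq = abs(np.sum(alpha_y))
    eps = 1e-6 * model.penalty_C
    free = (alpha > eps) & (alpha < model.penalty_C - eps)
    if free.any():
        margins = y[free] * decision_values(model, x[free])
        margin_err = float(np.max(np.abs(margins - 1.0)))
    else:
        margin_err = 0.0
    return box, eq, margin_err


class TestKernel:
    def test_zero_distance_is_one(self):
        assert rbf_kernel(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 3.0) == 1.0

    def test_distance_equal_to_width(self):
        x, x2 = np.array([0.0]), np.array([2.0])
        assert rbf_kernel(x, x2, 2.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_kernel_matrix_is_spd(self, rng):
        pts = rng.normal(size=(5, 3))
        k = rbf_kernel_matrix(pts, pts, 1.5)
        assert np.allclose(k, k.T)
        assert np.linalg.eigvalsh(k)[0] > 0

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            rbf_kernel(np.zeros(2), np.ones(2), 0.0)


class TestTrainingSetValidation:
    @pytest.mark.parametrize(
        "x,y",
        [
            (np.ones((2, 2)), [1, 1]),  # one class
            (np.ones((1, 2)), [1]),  # too few samples
            (np.array([[np.inf, 0], [0, 1]]), [1, -1]),  # non-finite
        ],
    )
    def test_invalid_inputs_rejected(self, x, y):
        with pytest.raises(ValidationError):
            TrainingSet(features=x, labels=y)


class TestTraining:
    def test_two_point_boundary_at_midpoint(self):
        data = TrainingSet(features=[[0.0], [2.0]], labels=[-1.0, 1.0])
        model = train_svm(data, C=100.0, g=2.0, tol=1e-10)
        assert decision_value(model, [1.0]) == pytest.approx(0.0, abs=1e-6)
        assert decision_value(model, [0.0]) < 0

    def test_xor_matches_brute_force_oracle(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        model = train_svm(TrainingSet(x, y), C=10.0, g=1.0, tol=1e-10)
        _, obj, _, decide = svm_dual_qp(x, y, 10.0, 1.0)
        assert model.dual_objective == pytest.approx(obj, abs=1e-5)
        assert len(model.dual_coefs) == 4  # all four points are support vectors
        assert np.allclose(decision_values(model, x), decide(x), atol=1e-4)
        assert np.array_equal(predict(model, x), y)

    def test_separable_set_large_C_perfect_training_accuracy(self, rng):
        x = np.vstack([rng.normal(size=(15, 2)) - 4, rng.normal(size=(15, 2)) + 4])
        y = np.concatenate([-np.ones(15), np.ones(15)])
        model = train_svm(TrainingSet(x, y), C=1e4, g=3.0)
        assert np.array_equal(predict(model, x), y)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(15):
            x, y, c, g = random_svm_instance(rng)
            model = train_svm(TrainingSet(x, y), c, g, tol=1e-10)
            _, obj, _, decide = svm_dual_qp(x, y, c, g)
            assert model.dual_objective == pytest.approx(obj, abs=1e-5)
            probe = rng.normal(size=(5, x.shape[1]))
            assert np.allclose(decision_values(model, probe), decide(probe), atol=1e-4)

    def test_kkt_conditions_hold(self, rng):
        for _ in range(10):
            x, y, c, g = random_svm_instance(rng)
            model = train_svm(TrainingSet(x, y), c, g, tol=1e-8)
            box, eq, margin_err = kkt_report(model, TrainingSet(x, y))
            assert box <= 1e-10
            assert eq <= 1e-8
            assert margin_err <= 1e-3

    def test_margin_violation_nonincreasing_in_C(self, rng):
        """Raising C tightens the fit: the optimal total hinge slack
        sum_i max(0, 1 - y_i f(x_i)) is non-increasing in C (the 0-1
        training error itself need not be monotone, for any solver)."""
        x = np.vstack([rng.normal(size=(30, 2)) - 0.5, rng.normal(size=(30, 2)) + 0.5])
        y = np.concatenate([-np.ones(30), np.ones(30)])
        slacks = []
        for c in (0.01, 0.1, 1.0, 10.0, 100.0):
            model = train_svm(TrainingSet(x, y), c, 2.0, tol=1e-8)
            hinge = np.maximum(0.0, 1.0 - y * decision_values(model, x)).sum()
            slacks.append(hinge)
        assert all(a >= b - 1e-6 for a, b in zip(slacks, slacks[1:]))

    def test_scale_relation_features_and_width(self, rng):
        x = rng.normal(size=(20, 3))
        y = np.sign(x[:, 0]) + (x[:, 0] == 0)
        m1 = train_svm(TrainingSet(x, y), 5.0, 1.3, tol=1e-10)
        m2 = train_svm(TrainingSet(4.0 * x, y), 5.0, 4.0 * 1.3, tol=1e-10)
        probe = rng.normal(size=(6, 3))
        assert np.allclose(
            decision_values(m1, probe), decision_values(m2, 4.0 * probe), atol=1e-6
        )

    def test_flipping_labels_flips_predictions(self, rng):
        x, y, c, g = random_svm_instance(rng)
        probe = rng.normal(size=(8, x.shape[1]))
        m_pos = train_svm(TrainingSet(x, y), c, g, tol=1e-10)
        m_neg = train_svm(TrainingSet(x, -y), c, g, tol=1e-10)
        assert np.array_equal(predict(m_pos, probe), -predict(m_neg, probe))


class TestPrediction:
    def test_zero_decision_value_maps_to_plus_one(self):
        model = SVMModel(
            support_vectors=np.empty((0, 2)),
            dual_coefs=np.empty(0),
            bias=0.0,
            kernel_width_g=1.0,
            penalty_C=1.0,
            dual_objective=0.0,
        )
        assert predict(model, np.zeros((1, 2)))[0] == 1.0

    def test_dimension_mismatch_rejected(self, rng):
        x, y, c, g = random_svm_instance(rng)
        model = train_svm(TrainingSet(x, y), c, g)
        with pytest.raises(ValidationError):
            decision_values(model, np.zeros((2, x.shape[1] + 1)))

    def test_on_margin_support_vector_identity(self, rng):
        x = np.vstack([rng.normal(size=(10, 2)) - 2, rng.normal(size=(10, 2)) + 2])
        y = np.concatenate([-np.ones(10), np.ones(10)])
        model = train_svm(TrainingSet(x, y), C=10.0, g=2.0, tol=1e-8)
        _, _, margin_err = kkt_report(model, TrainingSet(x, y))
        assert margin_err <= 1e-3


class TestCrossCheckAgainstSklearn:
    def test_decision_values_agree_with_libsvm(self, rng):
        """Independent implementation check: scikit-learn's SVC with
        gamma = 1/g^2 solves the same dual."""
        from sklearn.svm import SVC

        x = rng.normal(size=(40, 2))
        y = np.sign(x[:, 0] + 0.3 * rng.normal(size=40))
        y[y == 0] = 1
        c, g = 5.0, 1.7
        ours = train_svm(TrainingSet(x, y), c, g, tol=1e-10)
        ref = SVC(C=c, gamma=1.0 / g**2, kernel="rbf", tol=1e-8).fit(x, y)
        probe = rng.normal(size=(10, 2))
        assert np.allclose(
            decision_values(ours, probe), ref.decision_function(probe), atol=1e-4
        )


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, rng, tmp_path):
        x, y, c, g = random_svm_instance(rng)
        model = train_svm(TrainingSet(x, y), c, g)
        back = SVMModel.from_dict(model.to_dict())
        probe = rng.normal(size=(5, x.shape[1]))
        assert np.allclose(decision_values(model, probe), decision_values(back, probe))
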