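"""BP-ANN: features, forward pass, cost, gradients, training, prediction."""

import numpy as np
import pytest

from posefit import bpann, synth
from posefit.body import WAIST
from posefit.quat import from_axis_angle


def _random_model(rng) -> bpann.AnnModel:
    return bpann.AnnModel(
        theta2=rng.standard_normal((15, 10)),
        theta3=rng.standard_normal((5, 16)),
    )


def _zero_model() -> bpann.AnnModel:
    return bpann.AnnModel(theta2=np.zeros((15, 10)), theta3=np.zeros((5, 16)))


class TestWaistFeature:
    def test_identity_waist(self, rng):
        from posefit.quat import random_unit
        frame = random_unit(rng, 11)
        frame[WAIST] = [1.0, 0, 0, 0]
        x = bpann.extract_waist_features(frame)
        assert np.allclose(x, np.eye(3).ravel())

    def test_quarter_turn_about_x(self, rng):
        from posefit.quat import random_unit
        frame = random_unit(rng, 11)
        frame[WAIST] = from_axis_angle((1, 0, 0), np.pi / 2)
        x = bpann.extract_waist_features(frame)
        assert np.allclose(x, [1, 0, 0, 0, 0, -1, 0, 1, 0], atol=1e-12)

    def test_feature_reshapes_to_rotation(self, rng):
        from posefit.quat import random_unit
        frames = random_unit(rng, (20, 11))
        X = bpann.extract_waist_features(frames)
        R = X.reshape(-1, 3, 3)
        assert np.allclose(R @ np.swapaxes(R, 1, 2), np.eye(3)[None], atol=1e-9)
        assert np.allclose(np.linalg.det(R), 1.0)


class TestForward:
    def test_zero_weights_give_half(self):
        out = bpann.forward(_zero_model(), np.zeros((3, 9)))
        assert np.allclose(out, 0.5)

    def test_outputs_strictly_in_unit_interval(self, rng):
        model = _random_model(rng)
        out = bpann.forward(model, rng.standard_normal((50, 9)))
        assert np.all((out > 0) & (out < 1))

    def test_matches_per_neuron_loop_oracle(self, rng):
        model = _random_model(rng)
        X = rng.standard_normal((7, 9))
        vec = bpann.forward(model, X)
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        for n in range(7):
            hidden = np.array([sig(model.theta2[j] @ np.r_[1.0, X[n]]) for j in range(15)])
            out = np.array([sig(model.theta3[k] @ np.r_[1.0, hidden]) for k in range(5)])
            assert np.max(np.abs(out - vec[n])) < 1e-12

    def test_saturating_output_weight(self, rng):
        model = _zero_model()
        model.theta3[2, 0] = 50.0  # huge positive bias on output 2
        out = bpann.forward(model, np.zeros((1, 9)))
        assert out[0, 2] > 1 - 1e-9

    def test_nan_weights_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            bpann.AnnModel(theta2=np.full((15, 10), np.nan), theta3=np.zeros((5, 16)))


class TestCost:
    def test_zero_weight_cost_is_five_log_two(self, rng):
        # all outputs 0.5: one -log(1/2) for the hot class, four for the rest
        X = rng.standard_normal((1, 9))
        Y = bpann.one_hot(np.array([3]))
        J = bpann.cost(_zero_model(), X, Y, lam=0.0)
        assert J == pytest.approx(5 * np.log(2), abs=1e-12)

    def test_perfect_predictions_drive_cost_to_zero(self):
        model = _zero_model()
        model.theta3[:, 0] = -50.0
        model.theta3[0, 0] = 50.0  # output 1 hot, rest cold
        Y = bpann.one_hot(np.array([1, 1]))
        assert bpann.cost(model, np.zeros((2, 9)), Y, lam=0.0) < 1e-6

    def test_regularization_strictly_increases_cost(self, rng):
        model = _random_model(rng)
        X = rng.standard_normal((4, 9))
        Y = bpann.one_hot(rng.integers(1, 6, size=4))
        assert bpann.cost(model, X, Y, lam=1.0) > bpann.cost(model, X, Y, lam=0.0)

    def test_bias_weights_not_regularized(self):
        model = _zero_model()
        model.theta2[:, 0] = 3.0  # bias column only
        X, Y = np.zeros((1, 9)), bpann.one_hot(np.array([1]))
        assert bpann.cost(model, X, Y, lam=10.0) == pytest.approx(
            bpann.cost(model, X, Y, lam=0.0))


class TestGradients:
    def test_against_central_finite_differences(self, rng):
        model = _random_model(rng)
        X = rng.standard_normal((7, 9))
        Y = bpann.one_hot(rng.integers(1, 6, size=7))
        lam = 0.1
        g2, g3 = bpann.gradients(model, X, Y, lam)
        h = 1e-5
        for theta, g in ((model.theta2, g2), (model.theta3, g3)):
            idx = [(0, 0), (3, 5), (theta.shape[0] - 1, theta.shape[1] - 1)]
            for i, j in idx:
                orig = theta[i, j]
                theta[i, j] = orig + h
                Jp = bpann.cost(model, X, Y, lam)
                theta[i, j] = orig - h
                Jm = bpann.cost(model, X, Y, lam)
                theta[i, j] = orig
                fd = (Jp - Jm) / (2 * h)
                assert abs(g[i, j] - fd) / max(abs(fd), 1e-8) < 1e-6

    def test_l2_term_adds_lam_over_m_times_weight(self, rng):
        model = _random_model(rng)
        X = rng.standard_normal((4, 9))
        Y = bpann.one_hot(np.array([1, 2, 3, 4]))
        g2_0, _ = bpann.gradients(model, X, Y, 0.0)
        g2_1, _ = bpann.gradients(model, X, Y, 2.0)
        assert np.allclose(g2_1[:, 1:] - g2_0[:, 1:], (2.0 / 4) * model.theta2[:, 1:])
        assert np.allclose(g2_1[:, 0], g2_0[:, 0])  # bias column untouched


@pytest.fixture(scope="module")
def category_features():
    """Waist features of the five category orientations plus noise."""
    rng = np.random.default_rng(7)
    from posefit.quat import qmul, small_rotation
    X, y = [], []
    for cat, q in synth.CATEGORY_WAIST_QUAT.items():
        quats = qmul(q, small_rotation(rng, 0.1, 60))
        frames = np.tile([1.0, 0, 0, 0], (60, 11, 1))
        frames[:, WAIST, :] = quats
        X.append(bpann.extract_waist_features(frames))
        y.extend([cat] * 60)
    return np.concatenate(X), np.array(y)


class TestTraining:

    def test_separable_categories_learned(self, category_features):
        X, y = category_features
        model = bpann.train(X, y, bpann.AnnConfig(seed=0))
        pred = bpann.predict_category(model, X, t1=0.5)
        assert np.mean(pred == y) >= 0.99

    def test_cost_history_non_increasing(self, category_features):
        X, y = category_features
        model = bpann.train(X, y, bpann.AnnConfig(seed=0))
        hist = np.array(model.meta["cost_history"])
        assert np.all(np.diff(hist) <= 0)

    def test_seed_determinism(self, category_features):
        X, y = category_features
        cfg = bpann.AnnConfig(seed=3, max_epochs=50)
        a = bpann.train(X, y, cfg)
        b = bpann.train(X, y, cfg)
        assert np.array_equal(a.theta2, b.theta2) and np.array_equal(a.theta3, b.theta3)

    def test_missing_category_rejected(self, rng):
        X = rng.standard_normal((10, 9))
        with pytest.raises(ValueError, match=r"lacks categories \[3, 4, 5\]"):
            bpann.train(X, np.array([1, 2] * 5))


class TestPrediction:
    def _scores_model(self, scores):
        """A model whose output equals sigmoid(bias) = the wanted scores."""
        model = _zero_model()
        model.theta3[:, 0] = -np.log(1.0 / np.asarray(scores) - 1.0)
        return model

    def test_argmax_above_threshold(self):
        model = self._scores_model([0.9, 0.1, 0.1, 0.1, 0.1])
        assert bpann.predict_category(model, np.zeros((1, 9)), t1=0.5)[0] == 1

    def test_all_below_threshold_rejected(self):
        model = self._scores_model([0.4, 0.3, 0.2, 0.2, 0.1])
        assert bpann.predict_category(model, np.zeros((1, 9)), t1=0.5)[0] == 0

    def test_tie_breaks_to_lowest_category(self):
        model = self._scores_model([0.7, 0.9, 0.9, 0.1, 0.1])
        assert bpann.predict_category(model, np.zeros((1, 9)), t1=0.5)[0] == 2


def test_model_json_round_trip(tmp_path, rng):
    model = _random_model(rng)
    model.meta = {"lam": 0.01}
    model.to_json(tmp_path / "ann.json")
    back = bpann.AnnModel.from_json(tmp_path / "ann.json")
    assert np.allclose(back.theta2, model.theta2)
    assert np.allclose(back.theta3, model.theta3)
    assert back.meta["lam"] == 0.01
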