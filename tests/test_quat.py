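"""Quaternion algebra, frame calibration, and inter-segment angles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from posefit import quat
from posefit.body import (CalibrationSet, N_SEGMENTS, O1_GROUP, Q_INIT1, Q_INIT2,
                          WAIST, calibrate_to_animation, inter_segment_angle,
                          relative_to_waist)

I = np.array([1.0, 0, 0, 0])


class TestAlgebra:
    def test_identity_element(self, rng):
        q = quat.random_unit(rng)
        assert np.allclose(quat.qmul(I, q), q)
        assert np.allclose(quat.qmul(q, I), q)

    def test_hamilton_i_squared(self):
        i = np.array([0.0, 1, 0, 0])
        assert np.allclose(quat.qmul(i, i), [-1, 0, 0, 0])

    def test_norm_multiplicativity(self, rng):
        a = quat.random_unit(rng, 500)
        b = quat.random_unit(rng, 500)
        assert np.max(np.abs(quat.qnorm(quat.qmul(a, b)) - 1.0)) < 1e-9

    def test_inverse_is_conjugate(self):
        assert np.allclose(quat.qinv(I), I)
        assert np.allclose(quat.qinv([0, 1, 0, 0]), [0, -1, 0, 0])

    def test_inverse_cancels(self, rng):
        q = quat.random_unit(rng, 200)
        prod = quat.qmul(q, quat.qinv(q))
        assert np.max(np.abs(prod - I)) < 1e-9

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError):
            quat.qinv([0.0, 0, 0, 0])
        with pytest.raises(ValueError):
            quat.normalize([0.0, 0, 0, 0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            quat.qmul([np.nan, 0, 0, 0], I)

    def test_canonicalize_hemisphere(self, rng):
        q = quat.random_unit(rng, 300)
        c = quat.canonicalize(np.concatenate([q, -q]))
        assert np.all(c[..., 0] >= 0)
        assert np.allclose(c[:300], c[300:])
        # w == 0 tie broken on the first nonzero component
        assert np.allclose(quat.canonicalize([0.0, -1, 0, 0]), [0, 1, 0, 0])


class TestMatrixConversion:
    def test_identity(self):
        assert np.allclose(quat.quat_to_matrix(I), np.eye(3))

    def test_quarter_turn_about_x(self):
        s = np.sqrt(2) / 2
        expected = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        assert np.allclose(quat.quat_to_matrix([s, s, 0, 0]), expected)

    def test_double_cover(self, rng):
        q = quat.random_unit(rng, 100)
        assert np.allclose(quat.quat_to_matrix(q), quat.quat_to_matrix(-q))

    def test_matches_scipy_rotation(self, rng):
        q = quat.random_unit(rng, 200)
        ours = quat.quat_to_matrix(q)
        scipys = Rotation.from_quat(q, scalar_first=True).as_matrix()
        assert np.max(np.abs(ours - scipys)) < 1e-12

    def test_round_trip(self, rng):
        q = quat.random_unit(rng, 1000)
        back = quat.matrix_to_quat(quat.quat_to_matrix(q))
        err = np.minimum(np.max(np.abs(back - q), axis=-1), np.max(np.abs(back + q), axis=-1))
        assert np.max(err) < 1e-9

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            quat.quat_to_matrix([1.1, 0, 0, 0])


class TestRotateVector:
    def test_identity(self):
        assert np.allclose(quat.rotate_vector(I, [1, 0, 0]), [1, 0, 0])

    def test_quarter_turn_about_z(self):
        q = quat.from_axis_angle((0, 0, 1), np.pi / 2)
        assert np.allclose(quat.rotate_vector(q, [1, 0, 0]), [0, 1, 0])

    def test_isometry_and_matrix_consistency(self, rng):
        q = quat.random_unit(rng, 100)
        v = rng.standard_normal((100, 3))
        out = quat.rotate_vector(q, v)
        assert np.max(np.abs(np.linalg.norm(out, axis=-1) - np.linalg.norm(v, axis=-1))) < 1e-9
        via_matrix = np.einsum("nij,nj->ni", quat.quat_to_matrix(q), v)
        assert np.max(np.abs(out - via_matrix)) < 1e-9


class TestCalibration:
    def _random_cal(self, rng) -> CalibrationSet:
        return CalibrationSet(cali=quat.random_unit(rng, N_SEGMENTS))

    def test_calibration_frame_maps_to_init_constants(self, rng):
        cal = self._random_cal(rng)
        out = calibrate_to_animation(cal.cali, cal)
        for i in range(N_SEGMENTS):
            expect = Q_INIT1 if i in O1_GROUP else Q_INIT2
            assert np.allclose(out[i], expect, atol=1e-12)

    def test_common_rotation_factors_through(self, rng):
        cal = self._random_cal(rng)
        r = quat.random_unit(rng)
        raw = quat.qmul(cal.cali, r)
        out = calibrate_to_animation(raw, cal)
        for i in range(N_SEGMENTS):
            init = Q_INIT1 if i in O1_GROUP else Q_INIT2
            assert np.allclose(out[i], quat.qmul(init, r), atol=1e-12)

    def test_non_unit_raw_rejected(self, rng):
        cal = self._random_cal(rng)
        raw = cal.cali.copy()
        raw[3] *= 1.01
        with pytest.raises(ValueError):
            calibrate_to_animation(raw, cal)

    def test_missing_segment_named_in_error(self, rng):
        cal = self._random_cal(rng)
        with pytest.raises(ValueError, match="11 segments"):
            calibrate_to_animation(cal.cali[:10], cal)

    def test_init_constants_are_unit(self):
        assert abs(np.linalg.norm(Q_INIT1) - 1) < 1e-12
        assert abs(np.linalg.norm(Q_INIT2) - 1) < 1e-12

    def test_json_round_trip(self, rng, tmp_path):
        cal = self._random_cal(rng)
        cal.to_json(tmp_path / "cal.json")
        back = CalibrationSet.from_json(tmp_path / "cal.json")
        assert np.allclose(back.cali, cal.cali)
        assert np.allclose(back.init1, cal.init1)


class TestRelativeToWaist:
    def test_all_equal_to_waist_gives_identities(self, rng):
        q = quat.random_unit(rng)
        frame = np.tile(q, (N_SEGMENTS, 1))
        rel = relative_to_waist(frame)
        assert np.allclose(rel, np.tile([1.0, 0, 0, 0], (10, 1)), atol=1e-12)

    def test_identity_waist_passes_through(self, rng):
        frame = quat.random_unit(rng, N_SEGMENTS)
        frame[WAIST] = I
        rel = relative_to_waist(frame)
        nonwaist = [i for i in range(N_SEGMENTS) if i != WAIST]
        assert np.allclose(np.abs(rel), np.abs(frame[nonwaist]), atol=1e-12)

    def test_recomposition_recovers_frame(self, rng):
        frame = quat.random_unit(rng, (50, N_SEGMENTS))
        rel = relative_to_waist(frame)
        waist = frame[:, WAIST, :]
        nonwaist = [i for i in range(N_SEGMENTS) if i != WAIST]
        recomposed = quat.qmul(waist[:, None, :], rel)
        err = np.minimum(
            np.max(np.abs(recomposed - frame[:, nonwaist, :]), axis=-1),
            np.max(np.abs(recomposed + frame[:, nonwaist, :]), axis=-1),
        )
        assert np.max(err) < 1e-9


class TestInterSegmentAngle:
    def test_equal_orientations_give_zero(self, rng):
        q = quat.random_unit(rng)
        assert inter_segment_angle(q, q) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_right_angle(self, rng):
        qa = quat.random_unit(rng)
        # rotate the image of the x-axis by 90° about a perpendicular axis
        axis_world = quat.rotate_vector(qa, np.array([0.0, 0, 1]))
        qb = quat.qmul(quat.from_axis_angle(axis_world, np.pi / 2), qa)
        assert inter_segment_angle(qa, qb) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_range_and_zero_axis(self, rng):
        a = quat.random_unit(rng, 200)
        b = quat.random_unit(rng, 200)
        ang = inter_segment_angle(a, b)
        assert np.all((ang >= 0) & (ang <= np.pi))
        with pytest.raises(ValueError):
            inter_segment_angle(a[0], b[0], axis=(0, 0, 0))
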