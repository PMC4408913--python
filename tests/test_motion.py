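"""Residual rigid transforms and stage-wise MAD attribution."""

import math

import numpy as np
import pytest

from reprotrace.motion import (
    RigidTransform,
    load_flirt_matrix,
    mean_abs_diff,
    residual,
    rotation_angle,
    save_flirt_matrix,
    series_residuals,
    stage_mad_profile,
    translation_norm,
)
from reprotrace.synthetic import (
    _rotation_about,
    gen_rigid_pair,
    gen_rigid_series_pair,
    gen_stage_series,
)


def rot_z(deg, t=(0.0, 0.0, 0.0)):
    return RigidTransform.from_parts(_rotation_about([0, 0, 1], deg), np.array(t))


class TestRigidTransform:
    def test_identity_matrix_text(self):
        t = load_flirt_matrix("1 0 0 0\n0 1 0 0\n0 0 1 0\n0 0 0 1\n")
        assert t.is_identity()

    def test_bad_last_row_rejected(self):
        text = "1 0 0 0\n0 1 0 0\n0 0 1 0\n0 0 0 2\n"
        with pytest.raises(ValueError, match="last row"):
            load_flirt_matrix(text)

    def test_non_orthonormal_rotation_rejected_with_magnitude(self):
        m = np.eye(4)
        m[0, 0] = 1.1
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(m)

    def test_reflection_rejected(self):
        m = np.eye(4)
        m[0, 0] = -1.0  # det = -1, still orthonormal
        with pytest.raises(ValueError, match="det"):
            RigidTransform(m)

    def test_write_read_roundtrip_bit_identical(self, tmp_path, rng):
        t1, _, _ = gen_rigid_pair(angle_deg=12.5, translation_mm=3.0, seed=42)
        path = tmp_path / "MAT_0000"
        save_flirt_matrix(t1, path)
        loaded = load_flirt_matrix(path)
        assert np.array_equal(loaded.matrix, t1.matrix)


class TestResidual:
    def test_equal_transforms_give_identity(self):
        t = rot_z(17.0, (1.0, 2.0, 3.0))
        assert residual(t, t).is_identity()

    def test_identity_second_argument_returns_first(self):
        t = rot_z(9.0, (0.5, 0.0, -2.0))
        r = residual(t, RigidTransform.identity())
        assert np.allclose(r.matrix, t.matrix)

    def test_planted_residual_recovered(self):
        t1, t2, truth = gen_rigid_pair(
            axis=(1, 2, 3), angle_deg=4.2, translation_mm=(0.1, -0.2, 0.05), seed=3
        )
        g = np.asarray(truth.params["residual_matrix"])
        assert np.allclose(residual(t1, t2).matrix, g, atol=1e-9)


class TestAngles:
    def test_identity_angle_and_norm_are_zero(self):
        i = RigidTransform.identity()
        assert rotation_angle(i) == 0.0
        assert translation_norm(i) == 0.0

    def test_closed_form_30_degrees(self):
        assert rotation_angle(rot_z(30.0)) == pytest.approx(30.0, abs=1e-12)

    @pytest.mark.parametrize("axis,angle", [((1, 0, 0), 45.0), ((1, 1, 1), 0.096),
                                            ((0, 2, -1), 179.0)])
    def test_axis_angle_construction_recovered(self, axis, angle):
        t = RigidTransform.from_parts(_rotation_about(np.array(axis, float), angle),
                                      np.zeros(3))
        assert rotation_angle(t) == pytest.approx(angle, rel=1e-9, abs=1e-9)

    def test_angle_invariant_under_conjugation(self, rng):
        t = rot_z(23.0)
        q = _rotation_about(rng.normal(size=3), 77.0)
        conj = RigidTransform.from_parts(q @ t.rotation @ q.T, np.zeros(3))
        assert rotation_angle(conj) == pytest.approx(23.0, abs=1e-9)

    def test_345_translation(self):
        t = RigidTransform.from_parts(np.eye(3), np.array([3.0, 4.0, 0.0]))
        assert translation_norm(t) == 5.0

    def test_random_translation_matches_componentwise(self, rng):
        v = rng.normal(size=3)
        t = RigidTransform.from_parts(np.eye(3), v)
        assert translation_norm(t) == pytest.approx(
            math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2), rel=1e-15)


class TestSeriesResiduals:
    def test_identical_series_all_zero(self):
        series = [rot_z(a, (a, 0, 0)) for a in (0.0, 1.0, 2.0)]
        res = series_residuals(series, series)
        assert res.max_rotation_angle == 0.0
        # T·T^-1 leaves translation rounding at the femtometre scale
        assert res.max_translation_norm == pytest.approx(0.0, abs=1e-12)

    def test_single_perturbed_timepoint_carries_the_maxima(self):
        s1, s2, truth = gen_rigid_series_pair(
            8, angle_deg=0.5, translation_mm=0.01, seed=6)
        res = series_residuals(s1, s2)
        assert res.argmax_rotation == truth.params["planted_timepoint"]
        assert res.argmax_translation == truth.params["planted_timepoint"]

    def test_maxima_equal_max_over_timepoints(self):
        s1, s2, _ = gen_rigid_series_pair(5, angle_deg=1.0, translation_mm=0.1, seed=7)
        res = series_residuals(s1, s2)
        assert res.max_rotation_angle == max(m.rotation_angle for m in res.per_timepoint)
        assert res.max_translation_norm == max(
            m.translation_norm for m in res.per_timepoint)

    def test_length_mismatch_rejected(self):
        t = RigidTransform.identity()
        with pytest.raises(ValueError):
            series_residuals([t, t], [t])


class TestMeanAbsDiff:
    def test_identical_images(self, rng):
        a = rng.random((4, 4, 4))
        assert mean_abs_diff(a, a) == 0.0

    def test_constant_offset(self, rng):
        a = rng.random((4, 4, 4, 3))
        assert mean_abs_diff(a, a + 2.0) == pytest.approx(2.0)

    def test_matches_bruteforce_loop(self, rng):
        a = rng.random((3, 3, 3))
        b = rng.random((3, 3, 3))
        expected = np.mean([abs(a[i] - b[i]) for i in np.ndindex(3, 3, 3)])
        assert mean_abs_diff(a, b) == pytest.approx(expected, rel=1e-14)

    def test_mask_restricts_average(self, rng):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        b[0, 0, 0] = 8.0
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, :2] = True
        assert mean_abs_diff(a, b, mask=mask) == 4.0

    def test_per_volume_on_4d(self, rng):
        a = rng.random((4, 4, 4, 2))
        b = a.copy()
        b[..., 1] += 1.0
        per = mean_abs_diff(a, b, per_volume=True)
        assert per[0] == 0.0 and per[1] == pytest.approx(1.0)
        # pooled view averages over timepoints jointly
        assert mean_abs_diff(a, b) == pytest.approx(0.5)


class TestStageMADProfile:
    def test_constructed_profile(self):
        pairs, truth = gen_stage_series(
            (8, 8, 8), 3, [("mc", 0.2), ("smooth", 0.1), ("intnorm", 0.5),
                           ("final", 1.0)], seed=8)
        prof = stage_mad_profile(pairs, reference="final")
        assert prof.normalized == pytest.approx([0.2, 0.1, 0.5, 1.0], abs=1e-12)
        assert prof.normalized[-1] == 1.0

    def test_zeros_then_reference(self):
        a = np.ones((4, 4, 4))
        pairs = [("s1", a, a.copy()), ("s2", a, a.copy()), ("final", a, a + 0.5)]
        prof = stage_mad_profile(pairs, reference="final")
        assert prof.normalized == [0.0, 0.0, 1.0]

    def test_scale_invariance(self):
        pairs, _ = gen_stage_series((8, 8, 8), 1, [("mc", 0.3), ("final", 0.6)], seed=9)
        scaled = [(n, 10.0 * a, 10.0 * b) for n, a, b in pairs]
        p1 = stage_mad_profile(pairs, reference="final")
        p2 = stage_mad_profile(scaled, reference="final")
        assert p1.normalized == pytest.approx(p2.normalized, rel=1e-12)

    def test_zero_reference_rejected(self):
        a = np.ones((4, 4, 4))
        with pytest.raises(ValueError, match="no difference"):
            stage_mad_profile([("final", a, a.copy())], reference="final")

    def test_missing_reference_rejected(self):
        a = np.ones((4, 4, 4))
        with pytest.raises(ValueError, match="reference"):
            stage_mad_profile([("mc", a, a)], reference="final")
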