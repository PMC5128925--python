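"""Stereotaxic frame, skull-flat angle, trajectory angles, planned geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from stereotrack.errors import GeometryError
from stereotrack.stereotaxic_frame import (
    DuralSurface, angles_from_direction, bl_distance, build_frame,
    derive_planned, direction_from_angles, landmark_offsets, skull_flat_angle,
)
from stereotrack.volume_io import make_point_table


@pytest.fixture
def canonical_frame():
    return build_frame([0.0, 0.0, 0.0], [0.0, -8.31, 0.0])


class TestFrame:
    def test_identity_frame_semantics(self, canonical_frame):
        # 1 mm anterior of bregma -> (AP=+1, ML=0, DV=0)
        assert np.allclose(canonical_frame.to_stereo([0.0, 1.0, 0.0]), [1, 0, 0])

    def test_round_trip(self, canonical_frame):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-10, 10, (100, 3))
        stereo = canonical_frame.to_stereo(pts)
        assert np.allclose(canonical_frame.from_stereo(stereo), pts, atol=1e-9)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(GeometryError):
            build_frame([1, 2, 3], [1, 2, 3])


class TestSkullFlat:
    def test_equal_height_is_flat(self):
        assert skull_flat_angle([0, 0, 2.0], [0, -8, 2.0]) == pytest.approx(0.0)

    def test_trig_oracle(self):
        # |B-L| = 8.31 mm with a 0.1639 mm DV drop at lambda
        d = 8.31
        dz = 0.1639
        dy = np.sqrt(d ** 2 - dz ** 2)
        gamma = skull_flat_angle([0, 0, 0], [0, -dy, -dz])
        assert gamma == pytest.approx(np.degrees(np.arcsin(dz / d)), abs=1e-9)
        assert gamma == pytest.approx(1.1301, abs=1e-3)

    def test_swap_flips_sign(self):
        b, lam = np.array([0, 0, 0.3]), np.array([0, -8, 0.0])
        assert skull_flat_angle(b, lam) == pytest.approx(-skull_flat_angle(lam, b))

    def test_positive_when_lambda_ventral(self):
        assert skull_flat_angle([0, 0, 0.5], [0, -8, 0.0]) > 0


class TestBLDistance:
    def test_reference_distance(self):
        assert bl_distance([0, 0, 0], [0, -8.31, 0]) == pytest.approx(8.31)

    def test_coincident(self):
        assert bl_distance([1, 1, 1], [1, 1, 1]) == 0.0

    def test_rigid_invariance(self):
        from stereotrack.registration import rigid_from_params
        rng = np.random.default_rng(11)
        b, lam = np.array([0.3, 0.2, 4.0]), np.array([0.1, -8.0, 3.9])
        d0 = bl_distance(b, lam)
        for _ in range(20):
            t = rigid_from_params(np.r_[rng.uniform(-30, 30, 3),
                                        rng.uniform(-10, 10, 3)])
            assert bl_distance(t.apply(b), t.apply(lam)) == pytest.approx(d0, abs=1e-9)


class TestLandmarkOffsets:
    def test_identical_landmarks_zero(self, canonical_frame):
        pts = make_point_table(["bregma", "lambda"], [[0, 0, 0], [0, -8.3, 0]])
        out = landmark_offsets(pts, pts, canonical_frame)
        assert np.allclose(out[["dAP", "dML", "dDV", "ED"]].to_numpy(), 0.0)

    def test_pure_anterior_offset(self, canonical_frame):
        animal = make_point_table(["bregma"], [[0.0, 0.3, 0.0]])
        template = make_point_table(["bregma"], [[0.0, 0.0, 0.0]])
        out = landmark_offsets(animal, template, canonical_frame).iloc[0]
        assert (out.dAP, out.dML, out.dDV, out.ED) == pytest.approx((0.3, 0, 0, 0.3))

    def test_ed_is_norm(self, canonical_frame):
        rng = np.random.default_rng(5)
        a = rng.uniform(-1, 1, (4, 3))
        b = rng.uniform(-1, 1, (4, 3))
        ids = list("wxyz")
        out = landmark_offsets(make_point_table(ids, a), make_point_table(ids, b),
                               canonical_frame)
        assert np.allclose(out["ED"], np.linalg.norm(a - b, axis=1), atol=1e-12)


class TestAngles:
    def test_vertical(self):
        assert np.allclose(direction_from_angles(0, 0, "left"), [0, 0, -1])

    def test_negative_alpha_means_lateral_entry(self):
        # left hemisphere, alpha = -18: entry lateral (more negative ML)
        # than tip, so the entry->tip direction has a positive ML component
        d = direction_from_angles(-18, 0, "left")
        assert d[0] > 0 and d[2] < 0
        alpha, beta = angles_from_direction(d, "left")
        assert alpha == pytest.approx(-18, abs=1e-9)
        assert beta == pytest.approx(0, abs=1e-9)
        # mirrored on the right hemisphere
        dr = direction_from_angles(-18, 0, "right")
        assert dr[0] < 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.floats(-89, 89), hst.floats(-89, 89),
           hst.sampled_from(["left", "right"]))
    def test_round_trip(self, alpha, beta, hemi):
        a, b = angles_from_direction(direction_from_angles(alpha, beta, hemi), hemi)
        assert a == pytest.approx(alpha, abs=1e-9)
        assert b == pytest.approx(beta, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(GeometryError):
            direction_from_angles(90, 0, "left")
        with pytest.raises(GeometryError):
            angles_from_direction([0, 0, 1], "left")


class TestDerivePlanned:
    def test_flat_dura_vertical(self, canonical_frame):
        dura = DuralSurface.flat(0.0)
        plan = derive_planned([-5.0, -2.0, 8.0], 0, 0, "left", dura, canonical_frame)
        assert plan.d_plan == pytest.approx(8.0, abs=1e-3)
        assert np.allclose(plan.entry, [-2.0, -5.0, 0.0], atol=1e-3)
        assert np.allclose(plan.target, [-2.0, -5.0, -8.0], atol=1e-6)

    def test_flat_dura_inclined_closed_form(self, canonical_frame):
        # depth 7 mm at alpha = -18 deg: D = 7 / cos(18) = 7.361 mm and the
        # entry is displaced 7 * tan(18) = 2.274 mm laterally
        dura = DuralSurface.flat(0.0)
        plan = derive_planned([-5.0, -2.0, 7.0], -18, 0, "left", dura, canonical_frame)
        assert plan.d_plan == pytest.approx(7.0 / np.cos(np.radians(18)), abs=1e-3)
        ml_disp = abs(plan.entry[0] - plan.target[0])
        assert ml_disp == pytest.approx(7.0 * np.tan(np.radians(18)), abs=1e-3)
        # entry lateral of target on the left hemisphere
        assert plan.entry[0] < plan.target[0]

    def test_curved_dura_definitional(self, zero_noise_bundle):
        truth = zero_noise_bundle.truth
        plan = truth.plan
        d = np.linalg.norm(plan.target - plan.entry)
        assert d == pytest.approx(plan.d_plan, abs=1e-9)
        # entry on the dural surface to half a voxel
        h = truth.dura.height_at(plan.entry[0], plan.entry[1])
        assert abs(plan.entry[2] - h) <= 0.5 * zero_noise_bundle.spec.voxel_size

    def test_target_above_dura_rejected(self, canonical_frame):
        dura = DuralSurface.flat(0.0)
        with pytest.raises(GeometryError):
            derive_planned([-5.0, -2.0, -1.0], 0, 0, "left", dura, canonical_frame)
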