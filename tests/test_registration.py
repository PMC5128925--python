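"""Foreground extraction, transforms, resampling and MI registration."""

import numpy as np
import pytest

import stereotrack as st
from stereotrack.errors import SegmentationError
from stereotrack.registration import (
    AffineTransform, compose, extract_foreground, identity_transform, invert,
    mutual_information, register_mi, resample, rigid_from_params,
)
from stereotrack.volume_io import Modality, Volume3D

from conftest import transform_errors


class TestForeground:
    def test_mask_covers_head(self, zero_noise_bundle):
        b = zero_noise_bundle
        fg = extract_foreground(b.modalities["MRIpost"], dilation_mm=0.5)
        brain = np.asarray(b.brain_mask.data) > 0
        covered = (np.asarray(fg.data) > 0)[brain].mean()
        assert covered > 0.999

    def test_dilation_monotone(self, zero_noise_bundle):
        v = zero_noise_bundle.modalities["MRIpost"]
        m0 = np.asarray(extract_foreground(v, dilation_mm=0.0).data) > 0
        m5 = np.asarray(extract_foreground(v, dilation_mm=0.5).data) > 0
        assert np.all(m5[m0])
        assert m5.sum() > m0.sum()

    def test_ellipsoid_volume_oracle(self):
        # bright ellipsoid on black background: mask volume ~ (4/3) pi abc
        a, b, c = 3.0, 4.0, 2.5
        voxel = 0.2
        n = 48
        aff = np.diag([voxel] * 3 + [1.0])
        aff[:3, 3] = -voxel * (n - 1) / 2
        idx = np.indices((n, n, n)).reshape(3, -1).T * voxel + aff[:3, 3]
        data = (((idx / [a, b, c]) ** 2).sum(1) <= 1).reshape(n, n, n) * 100.0
        vol = Volume3D(data, aff, Modality.MRI)
        mask = extract_foreground(vol, dilation_mm=0.0)
        measured = mask.data.sum() * voxel ** 3
        analytic = 4 / 3 * np.pi * a * b * c
        assert abs(measured - analytic) / analytic < 0.10

    def test_empty_raises(self):
        vol = Volume3D(np.zeros((8, 8, 8)), np.eye(4), Modality.MRI)
        with pytest.raises(SegmentationError):
            extract_foreground(vol, threshold=1.0)


class TestTransforms:
    def test_inverse_composes_to_identity(self):
        t = rigid_from_params([10, -5, 3, 1.2, -0.4, 2.0])
        assert np.allclose(compose(t, invert(t)).matrix, np.eye(4), atol=1e-9)

    def test_rigid_closure(self):
        a = rigid_from_params([5, 0, -3, 1, 0, 0])
        b = rigid_from_params([0, 7, 2, 0, -1, 0.5])
        assert compose(a, b).dof == "rigid6"

    def test_chain_pointwise(self):
        rng = np.random.default_rng(2)
        chain = [rigid_from_params(np.r_[rng.uniform(-20, 20, 3),
                                         rng.uniform(-5, 5, 3)])
                 for _ in range(3)]
        pts = rng.uniform(-10, 10, (50, 3))
        composed = compose(compose(chain[0], chain[1]), chain[2])
        step = pts
        for t in chain[::-1]:  # compose(a, b)(x) = a(b(x))
            step = t.apply(step)
        assert np.allclose(composed.apply(pts), step, atol=1e-9)

    def test_rigid_orthonormality_enforced(self):
        bad = np.eye(4)
        bad[0, 0] = 2.0
        with pytest.raises(ValueError):
            AffineTransform(bad, "rigid6")
        AffineTransform(bad, "affine12")  # fine as affine

    def test_json_round_trip(self, tmp_path):
        t = rigid_from_params([1, 2, 3, 0.5, -0.5, 0.25], provenance="x->y")
        p = tmp_path / "t.json"
        t.to_json(p)
        back = AffineTransform.from_json(p)
        assert np.allclose(back.matrix, t.matrix)
        assert back.dof == "rigid6" and back.provenance == "x->y"


class TestResample:
    def test_identity_same_grid(self, zero_noise_bundle):
        v = zero_noise_bundle.template
        out = resample(v, identity_transform(), v, "linear")
        assert np.allclose(np.asarray(out.data), np.asarray(v.data), atol=1e-6)

    def test_nearest_preserves_label_values(self, zero_noise_bundle):
        lm = zero_noise_bundle.truth.region.labelmap
        t = rigid_from_params([3, -2, 1, 0.4, 0.2, -0.3])
        out = resample(lm, t, lm, "nearest")
        assert set(np.unique(out.data)) <= set(np.unique(lm.data))

    def test_one_voxel_translation_shifts_index(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 1, (12, 12, 12))
        vox = 0.2
        aff = np.diag([vox] * 3 + [1.0])
        v = Volume3D(data, aff, Modality.MRI)
        t = rigid_from_params([0, 0, 0, vox, 0, 0])  # +1 voxel along x
        out = resample(v, t, v, "linear")
        assert np.allclose(np.asarray(out.data)[1:], data[:-1], atol=1e-9)


class TestMutualInformation:
    def test_aligned_beats_shifted(self, zero_noise_bundle):
        # brute-force joint-histogram MI oracle on identical grids
        a = np.asarray(zero_noise_bundle.template.data)
        mi_aligned = mutual_information(a, a)
        shift = int(round(2.0 / zero_noise_bundle.spec.voxel_size))  # 2 mm
        mi_shifted = mutual_information(a[shift:], a[:-shift])
        assert mi_aligned > mi_shifted

    def test_symmetry_under_swap(self, zero_noise_bundle):
        a = np.asarray(zero_noise_bundle.template.data)
        b = np.asarray(zero_noise_bundle.modalities["CTpost"].data)
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(b, a), abs=1e-9)


class TestRegisterMI:
    def test_self_registration(self, registration_spec):
        b = st.generate_phantom(registration_spec((0.0,) * 6))
        est = register_mi(b.template, b.template, "rigid6")
        ang, disp = transform_errors(est, identity_transform())
        assert ang <= 0.05
        assert disp <= 0.02

    def test_known_displacement_snr20(self, registration_spec):
        # 5 deg rotation + 1.2 mm translation at SNR 20
        b = st.generate_phantom(registration_spec((0, 0, 5.0, 1.2, 0, 0),
                                                  noise=50.0))
        est = register_mi(b.modalities["MRIpost"], b.template, "rigid6")
        ang, disp = transform_errors(est, b.truth.transforms["MRIpost"])
        assert ang <= 0.2
        assert disp <= 0.05

    def test_affine_recovers_rigid_truth(self, registration_spec):
        b = st.generate_phantom(registration_spec((2.0, -1.5, 1.0, 0.8, -0.6, 0.4)))
        est = register_mi(b.modalities["MRIpost"], b.template, "affine12")
        E = np.linalg.inv(b.truth.transforms["MRIpost"].matrix) @ est.matrix
        pts = np.array([[x, y, z] for x in (-5, 5) for y in (-7, 7)
                        for z in (-4.5, 4.5)])
        err = np.linalg.norm(pts @ E[:3, :3].T + E[:3, 3] - pts, axis=1).max()
        assert err <= 0.15

    def test_simpleitk_cross_check(self, registration_spec):
        """Independent oracle: SimpleITK's Mattes MI registration should
        agree with ours on the same misaligned pair."""
        sitk = pytest.importorskip("SimpleITK")
        b = st.generate_phantom(registration_spec((3.0, -2.0, 1.5, 1.0, -0.7, 0.5)))
        est = register_mi(b.modalities["MRIpost"], b.template, "rigid6")

        def to_sitk(vol):
            img = sitk.GetImageFromArray(np.asarray(vol.data, np.float32).T)
            img.SetSpacing(tuple(float(s) for s in vol.voxel_sizes))
            img.SetOrigin(tuple(float(o) for o in vol.affine[:3, 3]))
            return img

        fixed = to_sitk(b.template)
        moving = to_sitk(b.modalities["MRIpost"])
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=48)
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(0.2, seed=1)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=0.5, minStep=1e-5, numberOfIterations=300)
        reg.SetOptimizerScalesFromPhysicalShift()
        init = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.MOMENTS)
        reg.SetInitialTransform(init, inPlace=False)
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        reg.SetSmoothingSigmasPerLevel([2, 1, 0])
        out = reg.Execute(fixed, moving)
        euler = sitk.Euler3DTransform(sitk.CompositeTransform(out).GetNthTransform(0))
        # SimpleITK maps fixed -> moving points; invert to compare
        R = np.asarray(euler.GetMatrix()).reshape(3, 3)
        t = np.asarray(euler.GetTranslation())
        c = np.asarray(euler.GetCenter())
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = t + c - R @ c
        sitk_est = invert(AffineTransform(m, "rigid6", "sitk fixed->moving"))
        ang, disp = transform_errors(est, sitk_est)
        assert ang <= 0.5
        assert disp <= 0.2
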