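"""Principal-axis fitting, entry/tip derivation and trajectory transforms."""

import numpy as np
import pandas as pd
import pytest

from stereotrack.errors import AmbiguousAxisError, GeometryError, InputError
from stereotrack.phantom import rasterize_cylinder
from stereotrack.registration import identity_transform, rigid_from_params
from stereotrack.segmentation import ingest_mask
from stereotrack.stereotaxic_frame import DuralSurface, direction_from_angles
from stereotrack.trajectory import (
    Trajectory, extents_entry_tip, ingest_observer, principal_axis,
    reconstruct_from_axis, table_to_trajectories, to_template,
    trajectories_to_table,
)
from stereotrack.volume_io import Modality, Volume3D


def _mask_from(data, voxel=0.1):
    aff = np.diag([voxel] * 3 + [1.0])
    aff[:3, 3] = -voxel * (np.array(data.shape) - 1) / 2
    return ingest_mask(Volume3D(data.astype(np.uint8), aff, Modality.MASK), "CT")


def _line_mask(n=81):
    data = np.zeros((9, 9, n))
    data[4, 4, :] = 1
    return _mask_from(data)


class TestPrincipalAxis:
    def test_vertical_line(self):
        centroid, d, explained = principal_axis(_line_mask())
        assert np.allclose(d, [0, 0, -1], atol=1e-12)
        assert explained == pytest.approx(1.0)
        assert np.allclose(centroid[:2], 0.0, atol=1e-9)

    def test_sign_fixed_ventral(self):
        # eigenvector sign is arbitrary; the returned axis must point ventral
        _, d, _ = principal_axis(_line_mask())
        assert d[2] < 0

    def test_isotropic_cloud_rejected(self):
        data = np.zeros((12, 12, 12))
        data[2:10, 2:10, 2:10] = 1
        with pytest.raises(AmbiguousAxisError):
            principal_axis(_mask_from(data))

    def test_tiny_extent_rejected(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 3:6] = 1
        with pytest.raises(AmbiguousAxisError):
            principal_axis(_mask_from(data))

    def test_tilted_cylinder_angle_recovery(self):
        # 0.2 mm x 8 mm cylinder at alpha = -18 deg, 0.1 mm voxels
        voxel = 0.1
        shape = (60, 24, 96)
        aff = np.diag([voxel] * 3 + [1.0])
        aff[:3, 3] = -voxel * (np.array(shape) - 1) / 2
        d_true = direction_from_angles(-18.0, 0.0, "left")
        occ = rasterize_cylinder(shape, aff, -4.0 * d_true, 4.0 * d_true, 0.1)
        em = _mask_from(occ >= 0.5)
        _, d, _ = principal_axis(em)
        from stereotrack.stereotaxic_frame import angles_from_direction
        alpha, beta = angles_from_direction(d, "left")
        assert alpha == pytest.approx(-18.0, abs=0.3)
        assert beta == pytest.approx(0.0, abs=0.3)


class TestExtents:
    def test_vertical_line_extents(self):
        em = _line_mask()
        centroid, d, _ = principal_axis(em)
        entry, tip = extents_entry_tip(em, centroid, d)
        assert np.linalg.norm(entry - tip) == pytest.approx(8.0, abs=1e-9)
        assert entry[2] > tip[2]

    def test_tilted_cylinder_length(self):
        voxel = 0.1
        shape = (60, 24, 96)
        aff = np.diag([voxel] * 3 + [1.0])
        aff[:3, 3] = -voxel * (np.array(shape) - 1) / 2
        d_true = direction_from_angles(-18.0, 0.0, "left")
        occ = rasterize_cylinder(shape, aff, -4.0 * d_true, 4.0 * d_true, 0.1)
        em = _mask_from(occ >= 0.5)
        centroid, d, _ = principal_axis(em)
        entry, tip = extents_entry_tip(em, centroid, d)
        assert abs(np.linalg.norm(entry - tip) - 8.0) <= 2 * voxel * np.sqrt(3)


class TestReconstruct:
    def test_flat_dura_vertical(self):
        dura = DuralSurface.flat(0.0)
        traj = reconstruct_from_axis([1.0, 2.0, -3.0], [0, 0, -1], dura, 8.0,
                                     "rec-mri")
        assert np.allclose(traj.entry, [1, 2, 0], atol=1e-6)
        assert np.allclose(traj.tip, [1, 2, -8], atol=1e-6)
        assert traj.depth == 8.0  # exactly D_plan

    def test_flat_dura_tilted_closed_form(self):
        dura = DuralSurface.flat(0.0)
        d = direction_from_angles(-18.0, 0.0, "left")
        centroid = np.array([0.0, 0.0, -3.0])
        traj = reconstruct_from_axis(centroid, d, dura, 7.361, "rec-ct")
        # line-plane intersection: entry = centroid + s * d with s = -z/dz
        s = -centroid[2] / d[2]
        assert np.allclose(traj.entry, centroid + s * d, atol=1e-3)

    def test_no_crossing_raises(self):
        dura = DuralSurface.flat(0.0, x_range=(-1, 1), y_range=(-1, 1))
        with pytest.raises(GeometryError):
            reconstruct_from_axis([50.0, 50.0, -3.0], [0, 0, -1], dura, 8.0,
                                  "rec-mri")


class TestToTemplate:
    def _traj(self):
        return Trajectory.from_points([0, 0, 0], [1.0, 0.5, -7.0], "mri")

    def test_identity_unchanged(self):
        t = self._traj()
        out = to_template(t, identity_transform())
        assert np.allclose(out.entry, t.entry)
        assert np.allclose(out.tip, t.tip)
        assert out.alpha == pytest.approx(t.alpha)

    def test_translation_preserves_angles(self):
        t = self._traj()
        out = to_template(t, rigid_from_params([0, 0, 0, 3.0, -2.0, 1.0]))
        assert out.alpha == pytest.approx(t.alpha, abs=1e-9)
        assert out.beta == pytest.approx(t.beta, abs=1e-9)
        assert np.allclose(out.entry, t.entry + [3, -2, 1])

    def test_truth_chain_on_phantom(self, zero_noise_bundle):
        # map the native-space truth trajectory through the recorded chain
        b = zero_noise_bundle
        chain = b.truth.transforms["MRIpost"]  # identity for this bundle
        out = to_template(b.truth.trajectory, chain)
        assert np.linalg.norm(out.tip - b.truth.trajectory.tip) <= 0.1

    def test_invariants_rechecked_after_transform(self):
        t = self._traj()
        out = to_template(t, rigid_from_params([10, -4, 6, 1, 1, 1]))
        assert np.allclose(out.tip, out.entry + out.depth * out.direction,
                           atol=1e-6)


class TestObserver:
    def test_simple_pair(self):
        pts = pd.DataFrame({
            "id": ["t1:entry", "t1:tip"],
            "x": [0.0, 0.0], "y": [0.0, 0.0], "z": [0.0, -8.0],
            "source": "obs-ct",
        })
        (traj,) = ingest_observer(pts)
        assert traj.alpha == pytest.approx(0.0)
        assert traj.beta == pytest.approx(0.0)
        assert traj.depth == pytest.approx(8.0)
        assert traj.source == "obs-ct"

    def test_entry_ventral_of_tip_rejected(self):
        pts = pd.DataFrame({
            "id": ["t1:entry", "t1:tip"],
            "x": [0.0, 0.0], "y": [0.0, 0.0], "z": [-8.0, 0.0],
            "source": "obs-ct",
        })
        with pytest.raises(GeometryError):
            ingest_observer(pts)

    def test_missing_pair_rejected(self):
        pts = pd.DataFrame({"id": ["t1:entry"], "x": [0.0], "y": [0.0],
                            "z": [0.0], "source": "obs-ct"})
        with pytest.raises(InputError):
            ingest_observer(pts)

    def test_table_round_trip(self):
        trajs = [Trajectory.from_points([0, 0, 0], [1, 1, -6], "ct",
                                        "template", "right", "A1"),
                 Trajectory.from_points([1, 0, 2], [0.5, -1, -5], "mri",
                                        "native", "left", "A2")]
        back = table_to_trajectories(trajectories_to_table(trajs))
        for orig, b in zip(trajs, back):
            assert np.allclose(b.entry, orig.entry)
            assert np.allclose(b.tip, orig.tip)
            assert b.source == orig.source and b.traj_id == orig.traj_id
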