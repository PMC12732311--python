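"""Geometric data model: resampling, rigid transforms, masks, NIfTI I/O."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from redose_uq import (
    CaseManifest,
    DeformationField,
    GridGeometry,
    RigidTransform,
    StructureMask,
    VolumeGrid,
    apply_rigid,
    mask_volume_cc,
    resample,
)
from redose_uq import io as rio
from redose_uq.grids import GeometryError


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VolumeGrid.from_array(np.asarray(values, dtype=float), spacing, origin)


class TestGeometry:
    def test_rejects_nonpositive_spacing_and_size(self):
        with pytest.raises(GeometryError):
            GridGeometry((0, 0, 0), (1, 0, 1), (4, 4, 4))
        with pytest.raises(GeometryError):
            GridGeometry((0, 0, 0), (1, 1, 1), (4, 0, 4))

    def test_voxel_centers_follow_origin_plus_index_times_spacing(self):
        g = GridGeometry((10.0, -5.0, 0.0), (2.0, 3.0, 1.0), (2, 2, 2))
        centers = g.voxel_centers()
        assert np.allclose(centers[1, 1, 1], [12.0, -2.0, 1.0])
        assert np.allclose(g.to_physical(g.to_index(centers)), centers)

    def test_value_count_must_match_size(self):
        with pytest.raises(GeometryError):
            VolumeGrid(GridGeometry((0, 0, 0), (1, 1, 1), (3, 3, 3)), np.zeros((3, 3, 2)))


class TestResample:
    def test_identity_geometry_is_idempotent(self, rng):
        vol = make_volume(rng.normal(size=(6, 7, 8)))
        for interp in ("linear", "nearest"):
            out, valid = resample(vol, vol.geometry, interp)
            assert valid.all()
            if interp == "nearest":
                assert np.array_equal(out.values, vol.values)
            else:
                np.testing.assert_allclose(out.values, vol.values, rtol=1e-12)

    def test_constant_volume_resamples_to_constant_on_finer_grid(self):
        vol = make_volume(np.full((5, 5, 5), 7.25), spacing=(2.0, 2.0, 2.0))
        fine = GridGeometry((1.0, 1.0, 1.0), (0.5, 0.5, 0.5), (8, 8, 8))
        out, valid = resample(vol, fine, "linear")
        assert valid.all()
        np.testing.assert_allclose(out.values, 7.25, rtol=1e-12)

    def test_linear_ramp_interpolates_exactly_between_centers(self):
        # value = x coordinate in mm; trilinear interpolation reproduces it
        g = GridGeometry((0, 0, 0), (5.0, 5.0, 5.0), (6, 3, 3))
        ramp = VolumeGrid(g, g.voxel_centers()[..., 0])
        target = GridGeometry((12.5, 5.0, 5.0), (1.0, 1.0, 1.0), (1, 1, 1))
        out, valid = resample(ramp, target, "linear")
        assert valid.all()
        assert out.values[0, 0, 0] == pytest.approx(12.5, abs=1e-12)

    def test_out_of_extent_samples_take_outside_value_and_are_flagged(self):
        vol = make_volume(np.ones((4, 4, 4)))
        target = GridGeometry((-10.0, 0.0, 0.0), (1.0, 1.0, 1.0), (4, 4, 4))
        out, valid = resample(vol, target, "linear", outside_value=-1.0)
        assert not valid.all()
        assert np.all(out.values[~valid] == -1.0)

    def test_round_trip_through_finer_grid_preserves_constant(self):
        vol = make_volume(np.full((5, 5, 5), 3.0), spacing=(2.0, 2.0, 2.0))
        fine = GridGeometry((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (9, 9, 9))
        mid, _ = resample(vol, fine, "linear")
        back, _ = resample(mid, vol.geometry, "linear")
        assert np.all(back.values == 3.0)

    def test_matches_simpleitk_resampling(self, rng):
        """Independent oracle: SimpleITK linear resampling on a random
        volume and an offset, finer target grid."""
        sitk = pytest.importorskip("SimpleITK")
        vals = rng.normal(size=(10, 11, 12))
        src = make_volume(vals, spacing=(1.5, 2.0, 1.0), origin=(3.0, -2.0, 1.0))
        target = GridGeometry((4.2, 0.7, 2.9), (0.9, 1.1, 0.8), (9, 8, 10))
        ours, valid = resample(src, target, "linear", outside_value=0.0)

        img = sitk.GetImageFromArray(np.ascontiguousarray(vals.T))  # sitk is x-fastest
        img.SetSpacing(src.geometry.spacing)
        img.SetOrigin(src.geometry.origin)
        ref = sitk.Image(*target.size, sitk.sitkFloat64)
        ref.SetSpacing(target.spacing)
        ref.SetOrigin(target.origin)
        out = sitk.Resample(img, ref, sitk.Transform(), sitk.sitkLinear, 0.0)
        theirs = sitk.GetArrayFromImage(out).T
        np.testing.assert_allclose(ours.values[valid], theirs[valid], atol=1e-9)


class TestRigid:
    def test_identity_returns_point(self):
        p = np.array([1.0, 2.0, 3.0])
        assert np.allclose(apply_rigid(p, RigidTransform()), p)

    def test_pure_translation(self):
        t = RigidTransform(translation=(5.0, 0.0, 0.0))
        assert np.allclose(apply_rigid(np.array([1.0, 2.0, 3.0]), t), [6.0, 2.0, 3.0])

    def test_quarter_turn_about_z(self):
        t = RigidTransform(rotation=(0.0, 0.0, np.pi / 2))
        out = apply_rigid(np.array([1.0, 0.0, 0.0]), t)
        assert np.allclose(out, [0.0, 1.0, 0.0], atol=1e-9)

    def test_round_trip_error_below_nanometre(self, rng):
        """Composing with the inverse returns the point to within 1e-9 mm
        over 1000 random transforms and points."""
        for _ in range(1000):
            t = RigidTransform(
                rotation=tuple(rng.uniform(-np.pi, np.pi, 3)),
                translation=tuple(rng.uniform(-50, 50, 3)),
                center=tuple(rng.uniform(-20, 20, 3)),
            )
            p = rng.uniform(-100, 100, 3)
            back = t.inverse().apply(t.apply(p))
            assert np.linalg.norm(back - p) < 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        angles=st.tuples(*[st.floats(-3.0, 3.0)] * 3),
        trans=st.tuples(*[st.floats(-30.0, 30.0)] * 3),
        point=st.tuples(*[st.floats(-80.0, 80.0)] * 3),
    )
    def test_rotation_preserves_distance_to_center(self, angles, trans, point):
        t = RigidTransform(rotation=angles, translation=trans, center=(1.0, -2.0, 3.0))
        p = np.array(point)
        c = np.array(t.center)
        mapped = t.apply(p)
        assert np.linalg.norm(mapped - np.array(trans) - c) == pytest.approx(
            np.linalg.norm(p - c), abs=1e-9
        )


class TestMasksAndFields:
    def test_mask_volume_in_cc(self):
        vals = np.zeros((10, 10, 10))
        vals[:10, :10, :10] = 1.0
        mask = StructureMask("m", "serial", make_volume(vals))
        vol, empty = mask_volume_cc(mask)
        assert vol == pytest.approx(1.0)
        assert not empty

    def test_single_clinical_voxel_volume(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 1.0
        mask = StructureMask("m", "serial", make_volume(vals, spacing=(0.8, 0.8, 2.5)))
        vol, empty = mask_volume_cc(mask)
        assert vol == pytest.approx(0.0016)

    def test_empty_mask_flagged(self):
        mask = StructureMask("m", "parallel", make_volume(np.zeros((3, 3, 3))), allow_empty=True)
        vol, empty = mask_volume_cc(mask)
        assert vol == 0.0 and empty

    def test_unflagged_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            StructureMask("m", "serial", make_volume(np.zeros((3, 3, 3))))

    def test_zero_field_composed_with_rigid_reproduces_rigid_mapping(self):
        geom = GridGeometry((0, 0, 0), (2.0, 2.0, 2.0), (5, 5, 5))
        rigid = RigidTransform(rotation=(0.1, -0.2, 0.3), translation=(4.0, -1.0, 2.0),
                               center=(4.0, 4.0, 4.0))
        composed = DeformationField.zero(geom).compose_rigid(rigid)
        centers = geom.voxel_centers()
        expected = rigid.apply(centers.reshape(-1, 3)).reshape(centers.shape)
        np.testing.assert_allclose(composed.mapped_points(), expected, atol=1e-12)

    def test_field_geometry_must_match(self):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (4, 4, 4))
        with pytest.raises(GeometryError):
            DeformationField(geom, np.zeros((4, 4, 3, 3)))


class TestIO:
    def test_volume_round_trip(self, tmp_path, rng):
        vol = make_volume(rng.normal(size=(6, 5, 4)).astype(np.float32),
                          spacing=(1.5, 2.0, 2.5), origin=(-4.0, 3.0, 0.0))
        path = tmp_path / "v.nii.gz"
        rio.save_volume(vol, path)
        back = rio.load_volume(path)
        assert back.geometry == vol.geometry
        np.testing.assert_allclose(back.values, vol.values, rtol=1e-6)

    def test_field_round_trip_with_vector_layout(self, tmp_path, rng):
        geom = GridGeometry((0, 0, 0), (2.0, 2.0, 2.0), (5, 6, 7))
        field = DeformationField(geom, rng.normal(size=(5, 6, 7, 3)).astype(np.float32))
        path = tmp_path / "f.nii.gz"
        rio.save_field(field, path)
        back = rio.load_field(path)
        assert back.geometry == geom
        np.testing.assert_allclose(back.displacement, field.displacement, rtol=1e-6)

    def test_manifest_round_trip_and_missing_file_rejection(self, tmp_path, rng):
        vol = make_volume(rng.normal(size=(4, 4, 4)))
        for name in ("prior.nii.gz", "dose.nii.gz", "reirr.nii.gz"):
            rio.save_volume(vol, tmp_path / name)
        mvals = np.zeros((4, 4, 4))
        mvals[1:3, 1:3, 1:3] = 1
        mask = StructureMask("cord", "serial", make_volume(mvals))
        rio.save_mask(mask, tmp_path / "m_prior.nii.gz")
        rio.save_mask(mask, tmp_path / "m_reirr.nii.gz")
        manifest = CaseManifest(
            case_id="c1",
            prior_volume="prior.nii.gz",
            prior_dose="dose.nii.gz",
            reirradiation_volume="reirr.nii.gz",
            oars=[{"name": "cord", "organ_class": "serial",
                   "prior_mask": "m_prior.nii.gz", "reirradiation_mask": "m_reirr.nii.gz"}],
        )
        mpath = tmp_path / "manifest.json"
        rio.save_manifest(manifest, mpath)
        back = rio.load_manifest(mpath)
        assert back.case_id == "c1" and back.oars[0]["name"] == "cord"

        (tmp_path / "dose.nii.gz").unlink()
        with pytest.raises(FileNotFoundError):
            rio.load_manifest(mpath)

    def test_duplicate_oar_names_rejected(self):
        with pytest.raises(ValueError):
            CaseManifest(
                case_id="c", prior_volume="a", prior_dose="b", reirradiation_volume="c",
                oars=[{"name": "x", "organ_class": "serial", "prior_mask": "p",
                       "reirradiation_mask": "r"},
                      {"name": "x", "organ_class": "parallel", "prior_mask": "p2",
                       "reirradiation_mask": "r2"}],
            )
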