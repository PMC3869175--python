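import numpy as np
import pytest

from cardiomesh.phantom import PhantomSpec, generate_mask, rotation_matrix, sparsify
from cardiomesh.shape import (
    BinaryMask,
    analyze_mask,
    compute_axes,
    find_pools_and_valves,
    fit_basal_plane,
    initial_affine,
    load_mask,
    save_mask,
    truncate_base,
)
from cardiomesh.templates import truncated_ellipsoid_volume


@pytest.fixture(scope="module")
def lv_phantom():
    return generate_mask(PhantomSpec())


@pytest.fixture(scope="module")
def biv_phantom():
    return generate_mask(PhantomSpec(topology="BiV"))


class TestBinaryMask:
    def test_invariants(self):
        with pytest.raises(ValueError):
            BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            BinaryMask(np.ones((4, 4, 4), bool), (1, 0, 1), (0, 0, 0))

    def test_nifti_roundtrip(self, tmp_path, lv_phantom):
        mask, _ = lv_phantom
        p = str(tmp_path / "m.nii")
        save_mask(mask, p)
        back = load_mask(p)
        assert np.array_equal(back.voxels, mask.voxels)
        np.testing.assert_allclose(back.spacing, mask.spacing)
        np.testing.assert_allclose(back.origin, mask.origin)

    def test_metaimage_reader(self, tmp_path, lv_phantom):
        mask, _ = lv_phantom
        # write a minimal local-data .mha by hand
        p = tmp_path / "m.mha"
        header = (
            "ObjectType = Image\nNDims = 3\nBinaryData = True\n"
            f"DimSize = {' '.join(map(str, mask.voxels.shape))}\n"
            f"ElementSpacing = {' '.join(map(str, mask.spacing))}\n"
            f"Offset = {' '.join(map(str, mask.origin))}\n"
            "ElementType = MET_UCHAR\nElementDataFile = LOCAL\n"
        )
        with open(p, "wb") as fh:
            fh.write(header.encode())
            fh.write(np.ascontiguousarray(mask.voxels.transpose(2, 1, 0)).astype(np.uint8).tobytes())
        back = load_mask(str(p))
        assert np.array_equal(back.voxels, mask.voxels)
        np.testing.assert_allclose(back.spacing, mask.spacing)


class TestPools:
    def test_lv_single_pool_centroid(self, lv_phantom):
        mask, gt = lv_phantom
        lv, rv, valve = find_pools_and_valves(mask)
        assert rv is None
        # analytic centroid of the truncated inner-ellipsoid cavity
        a, b, c = 25.0, 25.0, 40.0
        zb = gt.z_base
        num = np.pi * a * b * (zb**2 / 2 - zb**4 / (4 * c**2) - (c**2 / 2 - c**2 / 4))
        vol = truncated_ellipsoid_volume(a, b, c, zb)
        z_expect = num / vol
        centroid = mask.world(np.argwhere(lv)).mean(axis=0)
        assert np.linalg.norm(centroid - [0, 0, z_expect]) <= 1.5  # ~1 voxel

    def test_biv_two_pools_lv_larger(self, biv_phantom):
        mask, _ = biv_phantom
        lv, rv, _ = find_pools_and_valves(mask)
        assert rv is not None
        assert lv.sum() > rv.sum()

    def test_solid_blob_raises(self):
        vox = np.zeros((20, 20, 20), bool)
        vox[5:15, 5:15, 5:15] = True
        with pytest.raises(ValueError):
            find_pools_and_valves(BinaryMask(vox, (1, 1, 1), (0, 0, 0)))

    def test_closed_shell_raises(self):
        # base_level > 1 keeps the shell closed: no opening, no valve
        spec = PhantomSpec(base_level=2.0)
        mask, _ = generate_mask(spec)
        with pytest.raises(ValueError):
            find_pools_and_valves(mask)


class TestBasalPlane:
    def test_coplanar_exact(self):
        vox = np.zeros((30, 30, 30), bool)
        vox[5:25, 5:25, 10] = True
        point, normal = fit_basal_plane(vox, (1, 1, 1), (0, 0, 0))
        assert abs(abs(normal[2]) - 1.0) < 1e-12
        assert abs(point[2] - 10.0) < 1e-9

    def test_flat_truncation_recovered(self, lv_phantom):
        mask, gt = lv_phantom
        lv, _, valve = find_pools_and_valves(mask)
        ref = mask.world(np.argwhere(lv)).mean(axis=0)
        point, normal = fit_basal_plane(valve, mask.spacing, mask.origin, ref)
        # plane z = z_base within half a voxel; normal toward +z
        assert normal[2] > 0.99
        z_at = point[2] + (0 - point[0]) * 0 + 0
        assert abs(np.dot(point, normal) - gt.z_base) <= 1.0

    def test_tilted_truncation_normal_within_2deg(self):
        spec = PhantomSpec(rotation_axis=(1, 0, 0), rotation_angle_deg=10.0)
        mask, gt = generate_mask(spec)
        lv, _, valve = find_pools_and_valves(mask)
        ref = mask.world(np.argwhere(lv)).mean(axis=0)
        _, normal = fit_basal_plane(valve, mask.spacing, mask.origin, ref)
        true_n = gt.R @ [0, 0, 1]
        ang = np.degrees(np.arccos(np.clip(abs(np.dot(normal, true_n)), 0, 1)))
        assert ang <= 2.0

    def test_collinear_raises(self):
        vox = np.zeros((30, 30, 30), bool)
        vox[5:25, 10, 10] = True
        with pytest.raises(ValueError):
            fit_basal_plane(vox, (1, 1, 1), (0, 0, 0))


class TestAxes:
    def test_axis_aligned_phantom(self, lv_phantom):
        mask, _ = lv_phantom
        d = analyze_mask(mask)
        assert abs(d.axis_long[2]) > np.cos(np.deg2rad(1.0))

    def test_sparse_slice_normal_exact(self, lv_phantom):
        mask, _ = lv_phantom
        sp = sparsify(mask, 8.0)
        lv, rv, valve = find_pools_and_valves(mask)
        ref = mask.world(np.argwhere(lv)).mean(axis=0)
        plane = fit_basal_plane(valve, mask.spacing, mask.origin, ref)
        axis_long, _, _, _, _ = compute_axes(sp, lv, rv, plane)
        assert abs(axis_long[2]) == 1.0  # definitional

    def test_rotation_equivariance(self):
        d0 = analyze_mask(generate_mask(PhantomSpec(topology="BiV"))[0])
        spec = PhantomSpec(topology="BiV", rotation_axis=(0.3, 1, 0.2),
                           rotation_angle_deg=18.0, translation=(4, -2, 3))
        mask, gt = generate_mask(spec)
        d1 = analyze_mask(mask)
        for a0, a1 in ((d0.axis_long, d1.axis_long), (d0.axis_lr, d1.axis_lr)):
            ang = np.degrees(np.arccos(np.clip(abs(np.dot(gt.R @ a0, a1)), 0, 1)))
            assert ang <= 2.0
        np.testing.assert_allclose(
            d1.lv_centroid, gt.R @ d0.lv_centroid + gt.t, atol=1.8
        )

    def test_axes_orthonormal_right_handed(self, biv_phantom):
        d = analyze_mask(biv_phantom[0])
        F = d.frame
        np.testing.assert_allclose(F.T @ F, np.eye(3), atol=1e-8)
        assert np.linalg.det(F) > 0.99


class TestDimensions:
    def test_sqrt5_std_on_solid_ellipsoid(self):
        # uniform solid ellipsoid: semi-axis = sqrt(5) * coordinate std
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, size=(200000, 3))
        pts = pts[np.sum(pts**2, axis=1) <= 1.0] * [30.0, 30.0, 50.0]
        est = np.sqrt(5.0) * pts.std(axis=0)
        np.testing.assert_allclose(est, [30, 30, 50], rtol=0.05)

    def test_wall_thickness(self, lv_phantom):
        d = analyze_mask(lv_phantom[0])
        assert abs(d.wall_thickness - 10.0) <= 1.0  # +- spacing

    def test_lv_only_has_no_rv_fields(self, lv_phantom):
        d = analyze_mask(lv_phantom[0])
        assert d.rv_centroid is None and d.rv_size is None and d.rv_pool is None


class TestTruncateBase:
    def test_offset_zero_exact(self, lv_phantom):
        mask, gt = lv_phantom
        d = analyze_mask(mask)
        out = truncate_base(mask, d.basal_plane, offset_mm=0.0)
        z = out.world(np.argwhere(out.voxels))[:, 2]
        assert z.max() <= gt.z_base + 1.0

    def test_idempotence(self, lv_phantom):
        mask, _ = lv_phantom
        d = analyze_mask(mask)
        once = truncate_base(mask, d.basal_plane, 5.0)
        twice = truncate_base(once, d.basal_plane, 5.0)
        assert np.array_equal(once.voxels, twice.voxels)

    def test_extent_shrinks_by_offset(self, lv_phantom):
        mask, _ = lv_phantom
        d = analyze_mask(mask)
        out = truncate_base(mask, d.basal_plane, 7.0)
        z0 = mask.world(np.argwhere(mask.voxels))[:, 2]
        z1 = out.world(np.argwhere(out.voxels))[:, 2]
        shrink = z0.max() - z1.max()
        assert abs(shrink - 7.0) <= 1.5

    def test_over_truncation_raises(self, lv_phantom):
        mask, _ = lv_phantom
        d = analyze_mask(mask)
        with pytest.raises(ValueError):
            truncate_base(mask, d.basal_plane, offset_mm=80.0)


class TestInitialAffine:
    def _descriptor(self, frame, scaling, centroid):
        from cardiomesh.shape import ShapeDescriptor

        return ShapeDescriptor(
            axis_long=frame[:, 2], axis_lr=frame[:, 0], axis_third=frame[:, 1],
            basal_plane=(np.zeros(3), frame[:, 2]), centroid=np.asarray(centroid, float),
            lv_centroid=np.asarray(centroid, float), lv_size=np.ones(3),
            scaling=np.asarray(scaling, float), wall_thickness=10.0,
        )

    def test_identity(self):
        d = self._descriptor(np.eye(3), [1, 1, 1], [0, 0, 0])
        A, t = initial_affine(d, d)
        np.testing.assert_allclose(A, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_rotation_and_scale_recovery(self):
        R = rotation_matrix([1, 2, 0.5], 0.6)
        s = 1.3
        d0 = self._descriptor(np.eye(3), [10, 11, 12], [1, 2, 3])
        d1 = self._descriptor(R, np.array([10, 11, 12]) * s, R @ [1, 2, 3])
        A, t = initial_affine(d0, d1)
        np.testing.assert_allclose(A, s * R, atol=1e-6)

    def test_determinant_positive(self):
        R = rotation_matrix([0, 1, 0], 2.0)
        d0 = self._descriptor(np.eye(3), [5, 6, 7], [0, 0, 0])
        d1 = self._descriptor(R, [9, 3, 8], [5, 5, 5])
        A, _ = initial_affine(d0, d1)
        assert np.linalg.det(A) > 0
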