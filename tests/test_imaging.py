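"""Image processing: filters, segmentation, joint coordinate system fits."""

import numpy as np
import pytest
from scipy import ndimage

from jointload.errors import (
    EmptyMaskError,
    FitError,
    InvalidArgumentError,
    SegmentationError,
)
from jointload.imaging import (
    JointCoordinateSystem,
    Plane,
    add_cartilage_layer,
    build_joint_cs,
    crop_distal_third,
    downsample,
    fill_voids,
    find_symmetry_plane,
    fit_dorsal_arc,
    fit_head_circle,
    median_filter,
    segment,
    trabecular_mask,
)
from jointload.voxel import VoxelImage

H = 0.12  # default phantom spacing (mm)


class TestDownsample:
    def test_constant_stays_constant(self):
        img = VoxelImage(np.full((12, 12, 12), 7.0), 0.06)
        out = downsample(img, 0.36)
        assert out.shape == (2, 2, 2)
        assert np.allclose(out.data, 7.0)
        assert out.spacing_mm == pytest.approx(0.36)

    def test_factor_six_cube(self):
        img = VoxelImage(np.zeros((12, 6, 6)), 0.06)
        out = downsample(img, 0.36)
        assert out.shape == (2, 1, 1)

    def test_checkerboard_averages(self):
        idx = np.indices((8, 8, 8)).sum(axis=0)
        img = VoxelImage((idx % 2).astype(float), 0.06)
        out = downsample(img, 0.12)
        assert np.allclose(out.data, 0.5)

    def test_binary_majority_vote(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[:2] = True  # the first 2x2x2 block row is fully solid
        data[2:, 0, 0] = True   # 2/8 of block (1,0,0): minority, stays void
        data[2:, 2:, 2:] = True  # 8/8 of block (1,1,1): solid
        out = downsample(VoxelImage(data, 0.06), 0.12)
        assert out.data.dtype == bool
        assert out.data[0].all()
        assert not out.data[1, 0, 0]
        assert out.data[1, 1, 1]

    def test_upsampling_rejected(self):
        img = VoxelImage(np.zeros((4, 4, 4)), 0.12)
        with pytest.raises(InvalidArgumentError):
            downsample(img, 0.06)


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = VoxelImage(np.full((8, 8, 8), 3.0), 0.06)
        assert np.allclose(median_filter(img, 2).data, 3.0)

    def test_impulse_removed(self):
        data = np.ones((9, 9, 9))
        data[4, 4, 4] = 100.0
        out = median_filter(VoxelImage(data, 0.06), 2)
        assert np.allclose(out.data, 1.0)

    def test_binary_stays_binary(self):
        rng = np.random.default_rng(3)
        img = VoxelImage(rng.random((8, 8, 8)) > 0.5, 0.06)
        out = median_filter(img, 1)
        assert out.data.dtype == bool


class TestSegment:
    def test_bimodal_threshold_exact(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        grey = np.where(mask, 100.0, 0.0)
        out = segment(VoxelImage(grey, 0.06), 50.0)
        assert np.array_equal(out.data, mask)

    def test_threshold_above_max_fails(self):
        img = VoxelImage(np.full((4, 4, 4), 10.0), 0.06)
        with pytest.raises(SegmentationError):
            segment(img, 11.0)

    def test_smaller_component_dropped(self):
        grey = np.zeros((12, 6, 6))
        grey[:4, :3, :3] = 100.0
        grey[8:, :2, :2] = 100.0  # smaller, disconnected
        out = segment(VoxelImage(grey, 0.06), 50.0)
        assert out.data[:4, :3, :3].all()
        assert not out.data[8:].any()


class TestFillVoids:
    def test_hollow_sphere_filled(self):
        idx = np.indices((16, 16, 16)) - 7.5
        r = np.sqrt((idx**2).sum(axis=0))
        shell = (r <= 6) & (r >= 4)
        out = fill_voids(VoxelImage(shell, 0.06))
        assert out.data[(r <= 6)].all()

    def test_solid_block_unchanged(self):
        img = VoxelImage(np.ones((6, 6, 6), dtype=bool), 0.06)
        assert np.array_equal(fill_voids(img).data, img.data)

    def test_open_cavity_untouched(self):
        # C-shape: cavity connected to the border stays open
        data = np.ones((8, 8, 8), dtype=bool)
        data[2:6, 2:6, 2:] = False
        out = fill_voids(VoxelImage(data, 0.06))
        assert np.array_equal(out.data, data)


class TestSymmetryPlane:
    def test_phantom_plane_recovered(self, phantom):
        plane = find_symmetry_plane(phantom.image)
        # true symmetry plane of the phantom is z = 0
        assert abs(abs(plane.normal[2]) - 1.0) < np.sin(np.deg2rad(1.0))
        assert abs(plane.offset_mm) < H

    def test_translation_equivariance(self, solid_phantom):
        img = solid_phantom.image
        shifted = VoxelImage(img.data, img.spacing_mm,
                             img.origin_mm + np.array([1.2, -0.6, 2.4]))
        p0 = find_symmetry_plane(img)
        p1 = find_symmetry_plane(shifted)
        # normal unchanged, offset shifts by the translation component
        assert np.allclose(np.abs(p0.normal), np.abs(p1.normal), atol=0.02)
        shift = np.array([1.2, -0.6, 2.4]) @ p1.normal
        assert p1.offset_mm - (p0.offset_mm * np.sign(p0.normal @ p1.normal)
                               ) == pytest.approx(shift, abs=H)

    def test_self_mirrored_union_is_perfect(self):
        # elongated along x so the mirror plane contains the long axis;
        # solid core keeps the blob one filled component
        rng = np.random.default_rng(0)
        blob = rng.random((40, 12, 11)) > 0.55
        blob[:, 4:8, 7:] = True
        data = np.concatenate([blob, blob[:, :, ::-1]], axis=2)
        img = VoxelImage(data, 0.36)
        plane = find_symmetry_plane(img, region="all")
        assert plane.dice == pytest.approx(1.0, abs=0.05)
        # plane sits at the mirror seam (z = 11 voxels from origin)
        assert abs(plane.normal[2]) > 0.999
        assert plane.offset_mm * np.sign(plane.normal[2]) == pytest.approx(
            11 * 0.36, abs=0.36)


class TestHeadCircle:
    def test_hemisphere_radius_recovered(self, solid_phantom):
        plane = find_symmetry_plane(solid_phantom.image)
        cor, r = fit_head_circle(solid_phantom.image, plane)
        true_r = solid_phantom.true_r_h_mm
        assert abs(r - true_r) <= true_r * 0.05 + H
        assert np.linalg.norm(cor - solid_phantom.true_cor_mm) <= 2 * H

    def test_noisy_circle_matches_grid_oracle(self):
        """Geometric circle fit vs a brute-force grid minimizer."""
        from jointload.imaging import _circle_fit

        rng = np.random.default_rng(42)
        th = np.linspace(-1.2, 1.2, 40)
        r_true, c_true = 3.0, np.array([1.0, -0.5])
        pts = c_true + r_true * np.column_stack([np.cos(th), np.sin(th)])
        pts += rng.normal(scale=0.5 * H, size=pts.shape)
        c_fit, r_fit = _circle_fit(pts)

        # oracle: exhaustive grid over centre, best radius in closed form
        best = (np.inf, None, None)
        for cx in np.arange(0.8, 1.2, 0.01):
            for cy in np.arange(-0.7, -0.3, 0.01):
                d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
                r = d.mean()
                err = np.sum((d - r) ** 2)
                if err < best[0]:
                    best = (err, np.array([cx, cy]), r)
        assert np.linalg.norm(c_fit - best[1]) <= 0.012  # grid resolution
        assert abs(r_fit - best[2]) <= 0.02

    def test_collinear_points_rejected(self):
        from jointload.imaging import _circle_fit

        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(FitError):
            _circle_fit(pts)


class TestDorsalArc:
    def test_straight_shaft_reports_infinite_radius(self, solid_phantom):
        plane = find_symmetry_plane(solid_phantom.image)
        arc = fit_dorsal_arc(solid_phantom.image, plane,
                             cor_mm=solid_phantom.true_cor_mm,
                             head_radius_mm=solid_phantom.true_r_h_mm)
        assert np.isinf(arc.r_b_mm)
        assert arc.tilt_deg == 0.0

    def test_bent_shaft_radius_recovered(self, bent_phantom):
        plane = find_symmetry_plane(bent_phantom.image)
        arc = fit_dorsal_arc(bent_phantom.image, plane,
                             cor_mm=bent_phantom.true_cor_mm,
                             head_radius_mm=bent_phantom.true_r_h_mm)
        true_rb = bent_phantom.spec.dorsal_arc_radius_mm
        assert arc.r_b_mm == pytest.approx(true_rb, rel=0.02)
        # palmar side of the bow is +y by construction
        assert arc.palmar_dir @ np.array([0.0, 1.0, 0.0]) > 0.8

    def test_mirrored_bone_flips_palmar_not_tilt(self, bent_phantom):
        """The tilt is palmar-relative, so mirroring a bone (left vs right
        side) flips the recovered palmar direction while the tilt angle,
        being anatomical, is preserved."""
        img = bent_phantom.image
        mirrored = VoxelImage(img.data[:, ::-1, :].copy(), img.spacing_mm,
                              img.origin_mm.copy())
        p0 = find_symmetry_plane(img)
        p1 = find_symmetry_plane(mirrored)
        a0 = fit_dorsal_arc(img, p0, cor_mm=bent_phantom.true_cor_mm,
                            head_radius_mm=bent_phantom.true_r_h_mm)
        # the mirrored phantom's head centre maps y -> -y (about the array
        # centre; the true centre is at y=0 only up to the origin offset)
        ny = img.shape[1]
        y_flip = 2 * (img.origin_mm[1] + 0.5 * ny * img.spacing_mm)
        cor_m = bent_phantom.true_cor_mm.copy()
        cor_m[1] = y_flip - cor_m[1]
        a1 = fit_dorsal_arc(mirrored, p1, cor_mm=cor_m,
                            head_radius_mm=bent_phantom.true_r_h_mm)
        assert a1.tilt_deg == pytest.approx(a0.tilt_deg, abs=1.0)
        assert a0.palmar_dir[1] * a1.palmar_dir[1] < 0


class TestBuildJointCS:
    def test_phantom_cor_and_radius(self, phantom):
        cs = build_joint_cs(phantom.image, palmar_hint=np.array([0, 1, 0]))
        assert np.linalg.norm(cs.cor_mm - phantom.true_cor_mm) <= H
        assert cs.r_h_mm == pytest.approx(phantom.true_r_h_mm, rel=0.02)

    def test_axes_orthonormal_right_handed(self, phantom):
        cs = build_joint_cs(phantom.image, palmar_hint=np.array([0, 1, 0]))
        assert np.allclose(cs.axes.T @ cs.axes, np.eye(3), atol=1e-9)
        assert np.linalg.det(cs.axes) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self, phantom):
        cs1 = build_joint_cs(phantom.image, palmar_hint=np.array([0, 1, 0]))
        cs2 = build_joint_cs(phantom.image, palmar_hint=np.array([0, 1, 0]))
        assert np.array_equal(cs1.cor_mm, cs2.cor_mm)
        assert np.array_equal(cs1.axes, cs2.axes)
        assert cs1.r_h_mm == cs2.r_h_mm

    def test_grid_rotation_equivariance(self, solid_phantom):
        img = solid_phantom.image
        rot = VoxelImage(np.rot90(img.data, k=1, axes=(0, 1)).copy(),
                         img.spacing_mm)
        cs0 = build_joint_cs(img, palmar_hint=np.array([0, 1, 0]))
        cs1 = build_joint_cs(rot, palmar_hint=np.array([-1, 0, 0]))
        # the distal axis rotates with the grid: +x -> +y
        assert np.allclose(cs1.axes[:, 0], [0, 1, 0], atol=0.02)
        assert cs1.r_h_mm == pytest.approx(cs0.r_h_mm, rel=0.01)

    def test_json_round_trip(self, phantom, tmp_path):
        cs = build_joint_cs(phantom.image, palmar_hint=np.array([0, 1, 0]))
        path = tmp_path / "cs.json"
        cs.to_json(path)
        cs2 = JointCoordinateSystem.from_json(path)
        assert np.allclose(cs2.axes, cs.axes)
        assert np.allclose(cs2.cor_mm, cs.cor_mm)
        assert cs2.r_b_mm == cs.r_b_mm  # inf survives JSON via null


class TestCropDistalThird:
    def test_extent_is_one_third(self, phantom):
        cs = phantom.true_cs
        out = crop_distal_third(phantom.image, cs)
        pts = out.voxel_centers_mm(np.argwhere(out.data))
        t = (pts - cs.cor_mm) @ cs.x_axis
        expected = cs.bone_length_mm / 3.0
        assert np.ptp(t) == pytest.approx(expected, abs=2 * H)

    def test_head_entirely_retained(self, phantom):
        cs = phantom.true_cs
        out = crop_distal_third(phantom.image, cs)
        # head cap voxels (distal of the CoR) survive the crop
        orig = phantom.image
        pts = orig.voxel_centers_mm(np.argwhere(orig.data))
        n_head = int(((pts - cs.cor_mm) @ cs.x_axis > 0).sum())
        pts_c = out.voxel_centers_mm(np.argwhere(out.data))
        n_head_c = int(((pts_c - cs.cor_mm) @ cs.x_axis > 0).sum())
        assert n_head_c == n_head

    def test_idempotent(self, phantom):
        cs = phantom.true_cs
        once = crop_distal_third(phantom.image, cs)
        twice = crop_distal_third(once, cs)
        assert int(once.data.sum()) == int(twice.data.sum())


class TestCartilage:
    def test_radial_extent(self, solid_phantom):
        cs = solid_phantom.true_cs
        cropped = crop_distal_third(solid_phantom.image, cs)
        lab = add_cartilage_layer(cropped, cs, trabecular_peel_voxels=4)
        cart = np.argwhere(lab.cartilage)
        assert len(cart)
        d = np.linalg.norm(lab.labels.voxel_centers_mm(cart) - cs.cor_mm, axis=1)
        assert d.max() <= 1.2 * cs.r_h_mm + H
        assert d.max() >= 1.2 * cs.r_h_mm - 2 * H

    def test_radius_factor_one_gives_no_cartilage(self, solid_phantom):
        cs = solid_phantom.true_cs
        cropped = crop_distal_third(solid_phantom.image, cs)
        lab = add_cartilage_layer(cropped, cs, radius_factor=1.0,
                                  trabecular_peel_voxels=4)
        assert int(lab.cartilage.sum()) == 0

    def test_labels_partition(self, phantom):
        cs = phantom.true_cs
        cropped = crop_distal_third(phantom.image, cs)
        lab = add_cartilage_layer(cropped, cs, trabecular_peel_voxels=4)
        labels = lab.labels.data
        assert set(np.unique(labels)) <= {0, 1, 2}
        assert not (lab.bone & lab.cartilage).any()
        assert lab.trabecular_mask.data.sum() > 0
        assert not (lab.trabecular_mask.data & ~lab.bone).any()


class TestTrabecularMask:
    def test_thin_hollow_tube_has_no_trabecular_bone(self):
        data = np.zeros((20, 16, 16), dtype=bool)
        idx = np.indices((16, 16)) - 7.5
        r = np.sqrt((idx**2).sum(axis=0))
        ring = (r <= 7) & (r >= 5)
        data[:, ring] = True
        with pytest.raises(EmptyMaskError):
            trabecular_mask(VoxelImage(data, 0.12), peel_voxels=2)

    def test_mask_excludes_cortex(self, phantom):
        cs = phantom.true_cs
        cropped = crop_distal_third(phantom.image, cs)
        mask = trabecular_mask(cropped, peel_voxels=4)
        pts = mask.voxel_centers_mm(np.argwhere(mask.data))
        rel = pts - cs.cor_mm
        # within the head dome (clear of the shaft junction, where the peel
        # follows the union surface), no mask voxel may reach into the
        # cortical shell beyond R_H - thickness
        cap = rel @ cs.x_axis > 0.3
        cap &= np.hypot(rel @ cs.y_axis, rel @ cs.z_axis) < 0.7
        d = np.linalg.norm(rel[cap], axis=1)
        shell_inner = phantom.true_r_h_mm - phantom.spec.cortical_thickness_mm
        assert (d <= shell_inner + H).all()

    def test_zero_peel_keeps_all_interior_bone(self, phantom):
        cs = phantom.true_cs
        cropped = crop_distal_third(phantom.image, cs)
        m0 = trabecular_mask(cropped, peel_voxels=0)
        m4 = trabecular_mask(cropped, peel_voxels=4)
        assert m0.data.sum() >= m4.data.sum()
        assert np.array_equal(m0.data, cropped.data.astype(bool))
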