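"""Volume-based estimators: labelling, skeletons, bone axis, ellipsoid fits."""

import numpy as np
import pytest

from osteomorph.morpho3d import (
    analyse_skeleton,
    branch_angles,
    estimate_bone_axis,
    fit_ellipsoid_3d,
    label_regions_3d,
    mean_volume_3d,
    separate_by_volume,
    skeletonise_3d,
    Region3D,
)
from osteomorph.phantoms import CylinderSpec, RotationTriple, li_threshold, voxelise


def ball(radius, size=None, centre=None):
    size = size or int(2 * radius + 9)
    c = centre or (size / 2,) * 3
    zz, yy, xx = np.mgrid[0:size, 0:size, 0:size]
    return ((zz + 0.5 - c[0]) ** 2 + (yy + 0.5 - c[1]) ** 2
            + (xx + 0.5 - c[2]) ** 2) <= radius ** 2


class TestLabelling3D:
    def test_two_separated_spheres(self):
        vol = np.zeros((30, 30, 60), bool)
        vol[:, :, :30] |= ball(5, 30)
        vol[:, :, 30:] |= ball(5, 30)
        regions = label_regions_3d(vol)
        assert len(regions) == 2

    def test_corner_touching_voxels_merge_under_26_connectivity(self):
        vol = np.zeros((4, 4, 4), bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True
        assert len(label_regions_3d(vol)) == 1

    def test_physical_volume_uses_voxel_size(self):
        vol = np.zeros((5, 5, 5), bool)
        vol[1:3, 1:3, 1:3] = True
        region = label_regions_3d(vol, voxel_size=0.8)[0]
        assert region.volume == pytest.approx(8 * 0.8 ** 3)

    def test_empty_volume(self):
        assert label_regions_3d(np.zeros((5, 5, 5), bool)) == []


class TestVolumeSeparation:
    @pytest.mark.parametrize("volume, group", [
        (100.0, "lacunae"),
        (750.0, "excluded"),
        (1200.0, "canals"),
        (10.0, "noise"),
    ])
    def test_cutoffs(self, volume, group):
        region = Region3D(label=1, coords=np.zeros((1, 3), int),
                         voxel_count=1, volume=volume)
        sep = separate_by_volume([region])
        if group == "noise":
            assert sep.n_noise == 1
        else:
            assert [r.volume for r in getattr(sep, group)] == [volume]


class TestSkeleton:
    def test_straight_tube_thins_to_axial_chain(self):
        vol = np.zeros((60, 13, 13), bool)
        zz, yy, xx = np.mgrid[0:60, 0:13, 0:13]
        vol[((yy - 6.2) ** 2 + (xx - 6.2) ** 2 <= 25) & (zz >= 3) & (zz < 57)] = True
        skel = skeletonise_3d(vol)
        pts = np.argwhere(skel)
        assert skel[vol].sum() == skel.sum()  # skeleton subset of object
        assert pts[:, 1].std() < 1.0 and pts[:, 2].std() < 1.0
        assert pts[:, 0].max() - pts[:, 0].min() > 35

    def test_prismatic_even_symmetric_tube_survives(self):
        # parallel thinning deletes this shape entirely; the fallback must
        # recover its principal-axis line
        vol = np.zeros((60, 16, 16), bool)
        yy, xx = np.mgrid[0:16, 0:16]
        sec = ((yy - 7.5) ** 2 + (xx - 7.5) ** 2) <= 25
        vol[3:57] = sec
        skel = skeletonise_3d(vol)
        pts = np.argwhere(skel)
        assert len(pts) >= 40
        assert pts[:, 1].std() < 1.0 and pts[:, 2].std() < 1.0
        assert skel[vol].sum() == skel.sum()

    def test_solid_sphere_reduces_to_small_cluster(self):
        skel = skeletonise_3d(ball(8))
        assert 1 <= skel.sum() <= 10

    def test_empty_volume_raises(self):
        with pytest.raises(ValueError):
            skeletonise_3d(np.zeros((5, 5, 5), bool))


def chain(points):
    vol = np.zeros((40, 40, 40), bool)
    for p in points:
        vol[p] = True
    return vol


class TestAnalyseSkeleton:
    def test_straight_chain_one_branch_two_endpoints(self):
        skel = chain([(k, 10, 10) for k in range(5, 35)])
        graph = analyse_skeleton(skel)
        assert len(graph.branches) == 1
        assert len(graph.endpoints) == 2
        assert graph.junctions == []
        b = graph.branches[0]
        assert b.euclidean_length == pytest.approx(29.0)
        assert b.path_length == pytest.approx(29.0)

    def test_y_shape_three_branches_one_junction(self):
        # constructed fixture with known topology
        pts = ([(k, 20, 20) for k in range(5, 21)]
               + [(20 + k, 20 + k, 20) for k in range(1, 10)]
               + [(20 + k, 20 - k, 20) for k in range(1, 10)])
        graph = analyse_skeleton(chain(pts))
        assert len(graph.endpoints) == 3
        assert len(graph.junctions) == 1
        assert len(graph.branches) == 3

    def test_path_length_bounds_euclidean(self):
        # an L-shaped path: euclidean < path length
        pts = ([(k, 10, 10) for k in range(5, 20)]
               + [(19, 10 + k, 10) for k in range(1, 12)])
        graph = analyse_skeleton(chain(pts))
        for b in graph.branches:
            assert b.path_length >= b.euclidean_length - 1e-9

    def test_isolated_voxel_degenerate_branch(self):
        graph = analyse_skeleton(chain([(10, 10, 10)]))
        assert len(graph.branches) == 1
        assert graph.branches[0].euclidean_length == 0.0


class TestBoneAxis:
    def test_phantom_mode_returns_z(self):
        axis = estimate_bone_axis(phantom=True)
        np.testing.assert_allclose(axis.direction, [0, 0, 1])

    def test_concentric_circles_give_z(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([100 + 50 * np.cos(t), 80 + 50 * np.sin(t)])
        axis = estimate_bone_axis(pts, pts, slice_span=1000.0)
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=1e-9)

    def test_offset_centres_tilt_by_atan(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        first = np.column_stack([100 + 50 * np.cos(t), 80 + 50 * np.sin(t)])
        last = first + [10.0, 0.0]
        axis = estimate_bone_axis(first, last, slice_span=1000.0)
        tilt = np.degrees(np.arccos(axis.direction[2]))
        assert tilt == pytest.approx(np.degrees(np.arctan(10 / 1000)), abs=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_bone_axis(np.zeros((2, 2)), np.zeros((5, 2)), slice_span=10)


class TestBranchAngles:
    axis = estimate_bone_axis(phantom=True)

    @pytest.mark.parametrize("vector, omega, theta", [
        ((0, 0, 1), 90.0, None),   # parallel to the bone axis
        ((1, 0, 0), 0.0, 0.0),     # in-plane along the tangent
        ((1, 0, 1), 45.0, 0.0),    # 45 deg elevation
        ((0, 1, 0), 0.0, 90.0),    # in-plane radial
    ])
    def test_reference_directions(self, vector, omega, theta):
        o, t = branch_angles(np.array(vector, float), self.axis)
        assert o == pytest.approx(omega, abs=1e-9)
        if theta is None:
            assert t is None
        else:
            assert t == pytest.approx(theta, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            branch_angles(np.zeros(3), self.axis)


class TestEllipsoidFit:
    def test_sphere_semi_axes_match_radius(self):
        region = label_regions_3d(ball(10))[0]
        fit = fit_ellipsoid_3d(region)
        assert fit.fit_ok
        for r in fit.semi_axes:
            assert r == pytest.approx(10, rel=0.03)

    def test_two_voxel_region_fails(self):
        coords = np.array([[1, 1, 1], [1, 1, 2]])
        fit = fit_ellipsoid_3d(coords)
        assert not fit.fit_ok

    def test_coplanar_region_fails(self):
        zz, yy = np.mgrid[0:10, 0:10]
        coords = np.column_stack([zz.ravel(), yy.ravel(), np.full(100, 3)])
        assert not fit_ellipsoid_3d(coords).fit_ok

    def test_volume_is_triaxial_product(self):
        region = label_regions_3d(ball(8))[0]
        fit = fit_ellipsoid_3d(region, voxel_size=0.5)
        r1, r2, r3 = fit.semi_axes
        assert fit.volume == pytest.approx(4 / 3 * np.pi * r1 * r2 * r3)

    def test_mean_volume_excludes_failures(self):
        ok = fit_ellipsoid_3d(label_regions_3d(ball(6))[0])
        bad = fit_ellipsoid_3d(np.array([[0, 0, 0], [0, 0, 1]]))
        est = mean_volume_3d([ok, ok, bad])
        assert est.n == 2
        assert est.n_skipped == 1
        assert est.mean_volume == pytest.approx(ok.volume)
        assert est.sd == 0.0

    def test_all_failed_raises(self):
        bad = fit_ellipsoid_3d(np.array([[0, 0, 0]]))
        with pytest.raises(ValueError):
            mean_volume_3d([bad])


class TestSkeletonOnCylinders:
    def test_skeleton_angles_within_two_degrees(self):
        axis = estimate_bone_axis(phantom=True)
        for rot in (RotationTriple(10, 30, 40), RotationTriple(70, 55, 15),
                    RotationTriple(45, 85, 70)):
            spec = CylinderSpec(rotation=rot, length=150, domain_edge=180)
            binary, _ = li_threshold(voxelise(spec))
            graph = analyse_skeleton(skeletonise_3d(binary))
            branch = graph.longest_branch()
            omega, theta = branch_angles(branch, axis)
            gt = spec.ground_truth()
            assert abs(omega - gt.omega_true) < 2.0
            assert abs(theta - gt.theta_true) < 2.0
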