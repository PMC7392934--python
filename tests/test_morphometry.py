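"""Landmark/mesh morphometry against constructed and analytic oracles."""

import numpy as np
import pytest

from ossimetrics import synthetic as syn
from ossimetrics.geometry import Axis3D, random_rotation
from ossimetrics.io import LandmarkSet
from ossimetrics.mass_properties import mass_properties_from_mask
from ossimetrics.morphometry import (SurfacePatch, characteristic_lengths,
                                     equivalent_diameter, fit_plane,
                                     global_frame, hinge_axis,
                                     lever_geometry, patch_area_centroid,
                                     point_distance, projected_area,
                                     stapes_com_coordinates, stapes_frame)


class TestLengths:
    def test_total_length_from_constructed_landmarks(self):
        lm = LandmarkSet(points={
            "head_tip": [0, 0, 0], "umbo_tip": [0, 0, 7.88],
            "lateral_process_tip": [0, 0, 7.88 - 5.26]}, side="right")
        out = characteristic_lengths(lm, "malleus")
        assert out["L_mal"] == pytest.approx(7.88)
        assert out["L_manu"] == pytest.approx(5.26)
        assert out["L_manu/L_mal"] == pytest.approx(5.26 / 7.88)

    def test_manubrium_ratio_consistent_with_sheep_means(self):
        """Mean manubrium/total length 5.26/7.88 rounds to the tabulated
        sheep ratio 0.67."""
        assert round(5.26 / 7.88, 2) == pytest.approx(0.67, abs=0.01)

    def test_coincident_points_zero(self):
        assert point_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_missing_landmark_named(self):
        lm = LandmarkSet(points={"head_tip": [0, 0, 0]}, side="right")
        with pytest.raises(KeyError, match="umbo_tip"):
            characteristic_lengths(lm, "malleus")

    def test_com_anchored_lengths(self):
        lm = LandmarkSet(points={
            "head_tip": [0, 0, 3], "umbo_tip": [0, 0, -5],
            "lateral_process_tip": [0, 0, -2]}, side="right")
        out = characteristic_lengths(lm, "malleus", com=[0, 0, 0])
        assert out["L_head"] == pytest.approx(3.0)
        assert out["L_umbo"] == pytest.approx(5.0)
        assert out["L_head/L_umbo"] == pytest.approx(0.6)

    def test_rigid_invariance(self, rng):
        pts = {"head_tip": rng.uniform(-3, 3, 3),
               "umbo_tip": rng.uniform(-3, 3, 3),
               "lateral_process_tip": rng.uniform(-3, 3, 3)}
        lm = LandmarkSet(points=pts, side="right")
        base = characteristic_lengths(lm, "malleus")
        moved = lm.transformed(random_rotation(rng), rng.uniform(-9, 9, 3))
        got = characteristic_lengths(moved, "malleus")
        for k, v in base.items():
            assert got[k] == pytest.approx(v, rel=1e-12)


class TestPatches:
    def test_single_right_triangle(self):
        patch = SurfacePatch(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                             faces=[[0, 1, 2]])
        area, centroid = patch_area_centroid(patch)
        assert area == pytest.approx(0.5)
        np.testing.assert_allclose(centroid, [1 / 3, 1 / 3, 0])

    def test_unit_square_two_triangles(self):
        patch = SurfacePatch(
            vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
            faces=[[0, 1, 2], [0, 2, 3]])
        area, centroid = patch_area_centroid(patch)
        assert area == pytest.approx(1.0)
        np.testing.assert_allclose(centroid, [0.5, 0.5, 0])

    def test_hemisphere_area(self):
        patch = syn.hemisphere_patch(1.0)
        area, _ = patch_area_centroid(patch)
        assert area == pytest.approx(2 * np.pi, rel=0.005)

    def test_zero_area_rejected(self):
        patch = SurfacePatch(vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                             faces=[[0, 1, 2]])
        with pytest.raises(ValueError):
            patch_area_centroid(patch)


class TestPlaneAndProjection:
    def test_planar_patch_projects_to_itself(self, rng):
        rot = random_rotation(rng)
        patch = syn.elliptical_disc_patch(1.5, 0.7, center=(1, 2, 3),
                                          rotation=rot)
        point, normal = fit_plane(patch)
        assert abs(np.dot(normal, rot[:, 2])) == pytest.approx(1.0, abs=1e-9)
        assert projected_area(patch) == pytest.approx(patch.area, rel=1e-9)

    def test_hemisphere_projection_halves_area(self):
        """Projecting a hemisphere onto its equatorial plane gives pi r^2,
        half of the 3D surface area."""
        patch = syn.hemisphere_patch(1.0)
        proj = projected_area(patch,
                              plane=(np.zeros(3), np.array([0, 0, 1.0])))
        assert proj == pytest.approx(np.pi, rel=0.01)
        assert proj / patch.area == pytest.approx(0.5, abs=0.005)

    def test_curved_footplate_matches_closed_form(self):
        """Spherical-cap footplate: projected/full area = (1+cos theta)/2."""
        theta = np.arccos(0.88)  # ratio 0.94, like a real footplate
        patch = syn.spherical_cap_patch(1.0, theta)
        expected_ratio = (1 + np.cos(theta)) / 2
        ratio = projected_area(
            patch, plane=(np.zeros(3), np.array([0, 0, 1.0]))) / patch.area
        assert ratio == pytest.approx(expected_ratio, rel=0.005)
        assert ratio == pytest.approx(0.94, abs=0.01)

    def test_projection_never_exceeds_area(self, rng):
        for _ in range(5):
            patch = syn.spherical_cap_patch(
                rng.uniform(0.5, 2.0), rng.uniform(0.3, 1.5),
                rotation=random_rotation(rng), n_theta=16, n_phi=32)
            assert projected_area(patch) <= patch.area * (1 + 1e-9)

    def test_collinear_patch_rejected(self):
        patch = SurfacePatch(
            vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
            faces=[[0, 1, 2], [1, 2, 3]])
        with pytest.raises(ValueError):
            fit_plane(patch)


class TestEquivalentDiameter:
    @pytest.mark.parametrize("area,expected", [
        (2.86, 1.90),   # human projected footplate
        (1.45, 1.36),   # sheep projected footplate
        (np.pi / 4, 1.0),
    ])
    def test_reference_values(self, area, expected):
        assert equivalent_diameter(area) == pytest.approx(expected, abs=0.01)

    def test_round_trip(self, rng):
        for a in rng.uniform(0.1, 10.0, 10):
            d = equivalent_diameter(a)
            assert np.pi * d * d / 4 == pytest.approx(a, rel=1e-12)


class TestStapesFrame:
    def test_recovers_synthetic_plate_dimensions(self, sheep_stapes):
        frame, meas = stapes_frame(sheep_stapes.patches["footplate"],
                                   sheep_stapes.patches["head"])
        truth = sheep_stapes.truth.extras
        assert meas["a"] == pytest.approx(truth["a"], rel=0.01)
        assert meas["b"] == pytest.approx(truth["b"], rel=0.01)
        assert meas["h"] == pytest.approx(truth["h"], rel=0.01)
        # z points from footplate toward the head (lateral)
        head_dir = (sheep_stapes.truth.landmarks["head_center"]
                    - sheep_stapes.truth.landmarks["footplate_center"])
        assert np.dot(frame.z, head_dir) > 0
        assert frame.handedness == "right"

    def test_sheep_like_aspect_ratio(self, sheep_stapes):
        _, meas = stapes_frame(sheep_stapes.patches["footplate"],
                               sheep_stapes.patches["head"])
        assert meas["a/b"] == pytest.approx(2.2, abs=0.1)

    def test_rigid_invariance(self, sheep_stapes, rng):
        fp, head = (sheep_stapes.patches["footplate"],
                    sheep_stapes.patches["head"])
        _, base = stapes_frame(fp, head)
        rot, t = random_rotation(rng), rng.uniform(-4, 4, 3)
        _, moved = stapes_frame(fp.transformed(rot, t),
                                head.transformed(rot, t))
        for k in ("a", "b", "h"):
            assert moved[k] == pytest.approx(base[k], abs=1e-6)

    def test_com_height_is_euclidean_distance(self, sheep_stapes):
        frame, _ = stapes_frame(sheep_stapes.patches["footplate"],
                                sheep_stapes.patches["head"])
        mp = mass_properties_from_mask(sheep_stapes.mask,
                                       sheep_stapes.density)
        out = stapes_com_coordinates(frame, mp.com)
        assert out["h_c"] == pytest.approx(
            point_distance(frame.origin, mp.com), rel=1e-12)
        assert 0 < out["h_c"] < 2.1

    def test_degenerate_head_in_plane_rejected(self):
        fp = syn.elliptical_disc_patch(1.0, 0.5)
        head = syn.elliptical_disc_patch(0.2, 0.2, center=(2.0, 0, 0))
        with pytest.raises(ValueError, match="plane"):
            stapes_frame(fp, head)


class TestHingeAndLever:
    def test_axis_through_two_points(self):
        axis = hinge_axis([0, 0, 0], [1, 0, 0])
        np.testing.assert_allclose(axis.direction, [1, 0, 0])

    def test_swapped_inputs_same_line(self, rng):
        p, q = rng.uniform(-3, 3, 3), rng.uniform(-3, 3, 3)
        a1, a2 = hinge_axis(p, q), hinge_axis(q, p)
        np.testing.assert_allclose(a1.direction, a2.direction)
        assert a2.distance_to(a1.point) == pytest.approx(0.0, abs=1e-9)

    def test_landmarks_lie_on_axis(self, sheep_chain):
        lm = sheep_chain.landmarks
        axis = hinge_axis(lm["anterior_process"], lm["short_process_tip"])
        assert axis.distance_to(lm["anterior_process"]) < 1e-12
        assert axis.distance_to(lm["short_process_tip"]) < 1e-12

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            hinge_axis([1, 1, 1], [1, 1, 1])

    def test_constructed_lever(self):
        axis = Axis3D([0, 0, 0], [1, 0, 0])
        lg = lever_geometry(axis, [0, 4, 0], [0, 2, 0])
        assert (lg.l1, lg.l2, lg.ratio) == (4.0, 2.0, 2.0)

    def test_mean_lever_arms_give_sheep_like_ratio(self):
        """Mean L1/mean L2 = 4.16/1.69 = 2.46, close to the mean-of-ratios
        2.47 (aggregation-order difference)."""
        axis = Axis3D([0, 0, 0], [1, 0, 0])
        lg = lever_geometry(axis, [0, 4.16, 0], [0, 1.69, 0])
        assert lg.ratio == pytest.approx(2.462, abs=0.02)

    def test_umbo_on_axis_rejected(self):
        axis = Axis3D([0, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError):
            lever_geometry(axis, [2, 0, 0], [0, 1, 0])

    def test_scaling_behaviour(self, rng):
        """L1, L2 scale linearly with uniform scaling; the ratio does not."""
        axis = Axis3D([0, 0, 0], rng.standard_normal(3))
        u, i = rng.uniform(-3, 3, 3), rng.uniform(-3, 3, 3)
        base = lever_geometry(axis, u, i)
        scaled = lever_geometry(Axis3D([0, 0, 0], axis.direction),
                                3.7 * u, 3.7 * i)
        assert scaled.l1 == pytest.approx(3.7 * base.l1, rel=1e-12)
        assert scaled.l2 == pytest.approx(3.7 * base.l2, rel=1e-12)
        assert scaled.ratio == pytest.approx(base.ratio, rel=1e-12)

    def test_chain_recovers_generated_levers(self, sheep_chain):
        lm = sheep_chain.landmarks
        axis = hinge_axis(lm["anterior_process"], lm["short_process_tip"])
        mp = mass_properties_from_mask(sheep_chain.mask, sheep_chain.density)
        lg = lever_geometry(axis, lm["umbo_tip"], lm["isj_centroid"],
                            com=mp.com)
        truth = sheep_chain.truth.extras
        assert lg.l1 == pytest.approx(truth["L1_realized"], rel=1e-12)
        assert lg.l2 == pytest.approx(truth["L2_realized"], rel=1e-12)
        assert lg.d_axis_com == pytest.approx(truth["d_axis_com"], rel=0.01)


class TestGlobalFrame:
    def test_origin_shift(self, sheep_stapes):
        frame, _ = stapes_frame(sheep_stapes.patches["footplate"],
                                sheep_stapes.patches["head"])
        c = np.array([1.0, -2.0, 0.5])
        gf = global_frame(c, frame)
        np.testing.assert_allclose(gf.axes, frame.axes)
        np.testing.assert_allclose(gf.to_local(c), [0, 0, 0], atol=1e-12)

    def test_chain_part_coms_balance(self, sheep_chain):
        """Mass-weighted mean of per-ossicle COMs in the intrinsic frame is
        the origin, and the part COMs match the generator's analytic ones."""
        frame, _ = stapes_frame(sheep_chain.patches["footplate"],
                                sheep_chain.patches["head"])
        truth = sheep_chain.truth
        parts = truth.extras["part_groups"]
        gf = global_frame(truth.mass_properties.com, frame)
        local = {k: gf.to_local(p.com) for k, p in parts.items()}
        weighted = sum(p.mass * local[k] for k, p in parts.items())
        total = sum(p.mass for p in parts.values())
        np.testing.assert_allclose(weighted / total, 0.0, atol=1e-9)
        for k, p in parts.items():
            np.testing.assert_allclose(
                gf.to_world(local[k]), p.com, atol=1e-9)
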