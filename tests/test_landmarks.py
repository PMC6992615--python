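"""Slice measurements: landmarks, partition, contact, supraduction angle."""

import math

import numpy as np
import pytest

from oculogas.geometry import EyeModel, GasBubble, analytic_contact_rates
from oculogas.landmarks import (
    PartitionedContour,
    SliceGeometry,
    axis_from_angle_points,
    circle_contour,
    contour_length,
    locate_limbus,
    locate_meniscus,
    measure_contact,
    measure_contact_plane,
    measure_supraduction,
    partition_retina,
    place_landmarks,
    point_at,
    project_point,
    select_slice,
)
from oculogas.phantom import ImagingParams, render_stack
from oculogas.segmentation import otsu_threshold_image, segment_slice, segment_stack


def make_circle_geom(R=12.0, center=(40.0, 40.0), axis_deg=0.0, limbus_offset=6.0, n=2048):
    """Circle-contour geometry with the axis rotated by axis_deg in-plane."""
    a = math.radians(axis_deg)
    axis = np.array([math.sin(a), -math.cos(a)])  # 0 deg = anterior up (image y down)
    sup = np.array([math.cos(a), math.sin(a)])
    th_l = limbus_offset / R
    c = np.asarray(center, dtype=float)
    x_ir = R * math.cos(th_l)
    w = R * math.sin(th_l)
    return SliceGeometry(
        contour=circle_contour(center, R, n),
        axis_point=c,
        axis_dir=axis,
        superior_dir=sup,
        angle_superior=c + x_ir * axis + w * sup,
        angle_inferior=c + x_ir * axis - w * sup,
        pixel_spacing_mm=0.4375,
    )


class TestContourOps:
    def test_polyline_arc_length_against_cumulative_oracle(self):
        rng = np.random.default_rng(3)
        # irregular convex polygon
        th = np.sort(rng.uniform(0, 2 * math.pi, 40))
        r = rng.uniform(8, 12, 40)
        poly = np.column_stack([r * np.cos(th), r * np.sin(th)])
        seg_lengths = np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1)
        assert contour_length(poly) == pytest.approx(seg_lengths.sum(), abs=1e-9)
        # walking s along the contour lands at the cumulative-length position
        cum = np.concatenate([[0.0], np.cumsum(seg_lengths)])
        for s in rng.uniform(0, cum[-1], 20):
            p = point_at(poly, s)
            i = np.searchsorted(cum, s, side="right") - 1
            t = (s - cum[i]) / seg_lengths[i]
            expected = poly[i] + t * (poly[(i + 1) % len(poly)] - poly[i])
            assert np.allclose(p, expected, atol=1e-9)

    def test_project_inverts_point_at(self):
        geom = make_circle_geom()
        for s in (0.0, 10.0, 37.3, 60.1):
            p = point_at(geom.contour, s)
            assert project_point(geom.contour, p) == pytest.approx(s, abs=0.05)


class TestLimbus:
    def test_angle_on_contour_recovers_itself(self):
        geom = make_circle_geom()
        lim = locate_limbus(geom)
        assert np.allclose(lim["superior"], geom.angle_superior, atol=0.05)
        assert np.allclose(lim["inferior"], geom.angle_inferior, atol=0.05)

    def test_angle_on_perpendicular_diameter(self):
        """An angle point on the diameter perpendicular to the axis maps to
        that diameter's endpoint on the circle."""
        geom = make_circle_geom()
        geom.angle_superior = geom.axis_point + np.array([6.0, 0.0])
        geom.angle_inferior = geom.axis_point - np.array([6.0, 0.0])
        lim = locate_limbus(geom)
        assert np.allclose(lim["superior"], geom.axis_point + [12.0, 0.0], atol=0.05)
        assert np.allclose(lim["inferior"], geom.axis_point - [12.0, 0.0], atol=0.05)

    def test_rotation_equivariance(self):
        base = locate_limbus(make_circle_geom(axis_deg=0.0))
        rot = locate_limbus(make_circle_geom(axis_deg=25.0))
        c = np.array([40.0, 40.0])
        a = math.radians(25.0)
        Rm = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        # image y points down, so the in-plane rotation matrix applies directly
        for side in ("superior", "inferior"):
            expected = c + Rm.T @ (base[side] - c)
            alt = c + Rm @ (base[side] - c)
            err = min(np.linalg.norm(rot[side] - expected), np.linalg.norm(rot[side] - alt))
            assert err < 0.05

    def test_phantom_limbus_recovered_within_a_pixel(self):
        eye = EyeModel.from_clinical(25.4, "supine", 5.0)
        stack, truth = render_stack(eye, GasBubble(0.6), ImagingParams(noise_sd=0.0),
                                    "supine", 5.0)
        k = truth.central_slice
        img = stack.data[k]
        seg = segment_slice(img, otsu_threshold_image(img), stack.pixel_spacing_mm)
        a_s = np.asarray(truth.landmarks_xy_mm["angle_superior"])
        a_i = np.asarray(truth.landmarks_xy_mm["angle_inferior"])
        _, axis_dir, sup_dir = axis_from_angle_points(a_s, a_i, seg.circle_xy_mm)
        geom = SliceGeometry(
            contour=circle_contour(seg.circle_xy_mm, seg.circle_r_mm),
            axis_point=np.asarray(seg.circle_xy_mm),
            axis_dir=axis_dir,
            superior_dir=sup_dir,
            angle_superior=a_s,
            angle_inferior=a_i,
            pixel_spacing_mm=stack.pixel_spacing_mm,
        )
        lim = locate_limbus(geom)
        # The perpendicular from the angle meets the globe at a shallow
        # grazing angle, which roughly doubles any circle-fit error along
        # the chord; 1.5 px absorbs that amplification.
        for side, key in (("superior", "limbus_superior"), ("inferior", "limbus_inferior")):
            truth_pt = np.asarray(truth.landmarks_xy_mm[key])
            assert np.linalg.norm(lim[side] - truth_pt) < 1.5 * stack.pixel_spacing_mm

    def test_exact_contour_limbus_recovered_subpixel(self):
        eye = EyeModel.from_clinical(25.4, "supine", 5.0)
        stack, truth = render_stack(eye, GasBubble(0.6), ImagingParams(noise_sd=0.0),
                                    "supine", 5.0)
        a_s = np.asarray(truth.landmarks_xy_mm["angle_superior"])
        a_i = np.asarray(truth.landmarks_xy_mm["angle_inferior"])
        _, axis_dir, sup_dir = axis_from_angle_points(a_s, a_i, truth.center_xy_mm)
        geom = SliceGeometry(
            contour=circle_contour(truth.center_xy_mm, truth.radius_mm),
            axis_point=np.asarray(truth.center_xy_mm),
            axis_dir=axis_dir,
            superior_dir=sup_dir,
            angle_superior=a_s,
            angle_inferior=a_i,
            pixel_spacing_mm=stack.pixel_spacing_mm,
        )
        lim = locate_limbus(geom)
        for side, key in (("superior", "limbus_superior"), ("inferior", "limbus_inferior")):
            truth_pt = np.asarray(truth.landmarks_xy_mm[key])
            assert np.linalg.norm(lim[side] - truth_pt) < 0.1


class TestLandmarkPlacement:
    def test_circle_landmarks_at_expected_central_angles(self):
        R = 12.0
        geom = make_circle_geom(R=R)
        lm = place_landmarks(geom)
        c = geom.axis_point
        for side in ("superior", "inferior"):
            limb = lm["limbus"][side]
            for name, dist in (("ora", 7.0), ("equator", 13.5)):
                p = lm[f"{name}_{side}"]
                v1 = (limb - c) / np.linalg.norm(limb - c)
                v2 = (p - c) / np.linalg.norm(p - c)
                ang = math.acos(np.clip(v1 @ v2, -1, 1))
                assert ang == pytest.approx(dist / R, abs=2e-3)  # arc = R * theta

    def test_polygonal_contour_distances_match_segment_oracle(self):
        geom = make_circle_geom(n=64)  # coarse polygon, not a smooth circle
        lm = place_landmarks(geom)
        poly = geom.contour
        seg_lengths = np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_lengths)])
        L = cum[-1]
        for side in ("superior", "inferior"):
            s_l = lm["s"][f"limbus_{side}"]
            for name, dist in (("ora", 7.0), ("equator", 13.5)):
                s_x = lm["s"][f"{name}_{side}"]
                walked = min((s_x - s_l) % L, (s_l - s_x) % L)
                assert walked == pytest.approx(dist, abs=0.05)

    def test_contour_too_short_rejected(self):
        geom = make_circle_geom(R=3.5, limbus_offset=2.0)
        with pytest.raises(ValueError, match="too short"):
            place_landmarks(geom)


class TestPartition:
    def test_circle_partition_closed_form_lengths(self):
        R = 12.0
        part = partition_retina(make_circle_geom(R=R))
        th_l = 6.0 / R
        for side in ("superior", "inferior"):
            assert part.lengths_mm[f"{side}_anterior"] == pytest.approx(6.5, abs=0.05)
            expected_post = R * (math.pi - (th_l + 13.5 / R))
            assert part.lengths_mm[f"{side}_posterior"] == pytest.approx(expected_post, abs=0.05)

    def test_superior_inferior_mirror_symmetry(self):
        part = partition_retina(make_circle_geom())
        assert part.lengths_mm["superior_anterior"] == pytest.approx(
            part.lengths_mm["inferior_anterior"], abs=1e-6
        )
        assert part.lengths_mm["superior_posterior"] == pytest.approx(
            part.lengths_mm["inferior_posterior"], abs=1e-6
        )

    def test_partition_completeness(self):
        """Parts + ora-anterior remainder account for the full contour."""
        R = 12.0
        geom = make_circle_geom(R=R)
        part = partition_retina(geom)
        covered = sum(part.lengths_mm.values())
        anterior_remainder = 2.0 * (6.0 + 7.0)  # limbus offset + ora arc per side
        assert covered + anterior_remainder == pytest.approx(contour_length(geom.contour),
                                                             rel=1e-3)


class TestSelectSlice:
    def test_phantom_picks_central_slice(self):
        eye = EyeModel.from_clinical(25.4, "supine", 0.0)
        stack, truth = render_stack(eye, GasBubble(0.5), ImagingParams(noise_sd=0.0),
                                    "supine", 0.0)
        seg = segment_stack(stack)
        assert select_slice(seg, 25.4) == truth.central_slice

    def test_selected_extent_error_is_minimal(self):
        eye = EyeModel.from_clinical(25.4, "supine", 0.0)
        stack, _ = render_stack(eye, GasBubble(0.5), ImagingParams(noise_sd=0.0),
                                "supine", 0.0)
        seg = segment_stack(stack)
        k = select_slice(seg, 25.4)
        errs = {
            i: abs(2 * s.circle_r_mm + 1.6 - 25.4)
            for i, s in enumerate(seg.slices)
            if np.isfinite(s.circle_r_mm)
        }
        assert errs[k] == min(errs.values())

    def test_axial_length_mismatch_rejected(self):
        eye = EyeModel.from_clinical(25.4, "supine", 0.0)
        stack, _ = render_stack(eye, GasBubble(0.5), ImagingParams(noise_sd=0.0),
                                "supine", 0.0)
        seg = segment_stack(stack)
        with pytest.raises(ValueError, match="axial length"):
            select_slice(seg, 40.0)


class TestContact:
    def make_phantom_slice(self, f, posture="supine", angle=0.0, noise=0.0):
        eye = EyeModel.from_clinical(25.4, posture, angle)
        stack, truth = render_stack(eye, GasBubble(f), ImagingParams(noise_sd=noise),
                                    posture, angle)
        k = truth.central_slice
        img = stack.data[k]
        seg = segment_slice(img, otsu_threshold_image(img), stack.pixel_spacing_mm)
        a_s = np.asarray(truth.landmarks_xy_mm["angle_superior"])
        a_i = np.asarray(truth.landmarks_xy_mm["angle_inferior"])
        _, axis_dir, sup_dir = axis_from_angle_points(a_s, a_i, seg.circle_xy_mm)
        geom = SliceGeometry(
            contour=circle_contour(seg.circle_xy_mm, seg.circle_r_mm),
            axis_point=np.asarray(seg.circle_xy_mm),
            axis_dir=axis_dir,
            superior_dir=sup_dir,
            angle_superior=a_s,
            angle_inferior=a_i,
            pixel_spacing_mm=stack.pixel_spacing_mm,
        )
        return eye, stack, img, seg, partition_retina(geom)

    def test_empty_gas_all_zero(self):
        _, stack, _, seg, part = self.make_phantom_slice(0.0)
        res = measure_contact(part, seg.gas_mask, stack.pixel_spacing_mm)
        assert all(r == 0.0 for r in res.rate_pct.values())

    def test_full_gas_all_hundred(self):
        _, stack, _, seg, part = self.make_phantom_slice(1.0)
        res = measure_contact(part, seg.gas_mask, stack.pixel_spacing_mm)
        assert all(r == pytest.approx(100.0) for r in res.rate_pct.values())

    def test_mask_probe_matches_analytic_oracle(self):
        """Mask-probe contact rates vs the closed-form oracle (f=0.6, supine)."""
        eye, stack, _, seg, part = self.make_phantom_slice(0.6)
        res = measure_contact(part, seg.gas_mask, stack.pixel_spacing_mm)
        oracle = analytic_contact_rates(eye, GasBubble(0.6)).rate_pct
        for name, rate in res.rate_pct.items():
            assert rate == pytest.approx(oracle[name], abs=3.0)

    def test_meniscus_plane_matches_analytic_oracle(self):
        eye, stack, img, seg, part = self.make_phantom_slice(0.6, angle=9.5)
        men = locate_meniscus(img, seg.threshold, seg.circle_xy_mm, seg.circle_r_mm,
                              stack.pixel_spacing_mm)
        assert men is not None and men[1]  # gas floats to the top
        res = measure_contact_plane(part, men[0], men[1])
        oracle = analytic_contact_rates(
            EyeModel.from_clinical(25.4, "supine", 9.5), GasBubble(0.6)
        ).rate_pct
        for name, rate in res.rate_pct.items():
            assert rate == pytest.approx(oracle[name], abs=3.0)

    def test_contact_never_exceeds_part_length(self):
        _, stack, _, seg, part = self.make_phantom_slice(0.45, noise=10.0)
        res = measure_contact(part, seg.gas_mask, stack.pixel_spacing_mm)
        for name in res.part_length_mm:
            assert 0.0 <= res.contact_length_mm[name] <= res.part_length_mm[name] + 1e-9
            assert 0.0 <= res.rate_pct[name] <= 100.0

    def test_no_meniscus_on_single_phase_slice(self):
        _, stack, img, seg, _ = self.make_phantom_slice(0.0)
        men = locate_meniscus(img, seg.threshold, seg.circle_xy_mm, seg.circle_r_mm,
                              stack.pixel_spacing_mm)
        assert men is None


class TestSupraduction:
    def test_reference_alignment_is_zero(self):
        for posture, axis in (("supine", [0.0, -1.0]), ("prone", [0.0, 1.0])):
            assert measure_supraduction(axis, posture).degrees == pytest.approx(0.0)

    @pytest.mark.parametrize("posture, angle", [
        ("prone", 9.5), ("supine", -16.1), ("supine", 13.2), ("prone", 29.9),
    ])
    def test_phantom_angle_recovery(self, posture, angle):
        eye = EyeModel.from_clinical(25.4, posture, angle)
        stack, truth = render_stack(eye, GasBubble(0.6), ImagingParams(noise_sd=0.0),
                                    posture, angle)
        a_s = np.asarray(truth.landmarks_xy_mm["angle_superior"])
        a_i = np.asarray(truth.landmarks_xy_mm["angle_inferior"])
        _, axis_dir, _ = axis_from_angle_points(a_s, a_i, truth.center_xy_mm)
        measured = measure_supraduction(axis_dir, posture)
        assert measured.degrees == pytest.approx(angle, abs=0.5)
        assert math.copysign(1, measured.degrees) == math.copysign(1, angle)

    def test_undefined_axis_rejected(self):
        with pytest.raises(ValueError):
            measure_supraduction([0.0, 0.0], "supine")
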