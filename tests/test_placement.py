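import time

import numpy as np
import pytest

from headmc.placement import (CuttingPlane, IntersectionCurve, cutting_plane,
                              extract_segment, mesh_plane_intersection,
                              place_optodes, resample_smooth, _arc_between)
from headmc._geometry import SurfaceLocator


def brute_force_plane_segments(nodes, faces, plane):
    """Independent per-triangle edge-crossing enumeration."""
    d = plane.signed_distance(nodes)
    scale = np.abs(d).max() or 1.0
    d = np.where(d == 0.0, 1e-12 * scale, d)
    segments = set()
    for tri in faces:
        pts = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            a, b = tri[i], tri[j]
            if (d[a] > 0) != (d[b] > 0):
                w = d[a] / (d[a] - d[b])
                pts.append(tuple(np.round(nodes[a] + w * (nodes[b] - nodes[a]),
                                          9)))
        if len(pts) == 2:
            segments.add(frozenset(pts))
    return segments


def loops_to_segments(loops):
    segs = set()
    for loop in loops:
        v = np.round(loop.vertices, 9)
        for i in range(len(v) - 1):
            segs.add(frozenset([tuple(v[i]), tuple(v[i + 1])]))
    return segs


class TestCuttingPlane:
    def test_axis_aligned_example(self):
        p = cutting_plane([0, 0, 100], [80, 0, 0], [-80, 0, 0])
        np.testing.assert_allclose(np.abs(p.normal), [0, 1, 0], atol=1e-12)

    def test_contains_all_three_points(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            poi, le, re_ = rng.normal(scale=50, size=(3, 3))
            scale = max(np.linalg.norm(le - poi), np.linalg.norm(re_ - poi))
            try:
                p = cutting_plane(poi, le, re_)
            except ValueError:
                continue
            for q in (poi, le, re_):
                assert abs(p.signed_distance(q)[0]) < 1e-9 * scale

    def test_normal_superior_component_nonnegative(self):
        p = cutting_plane([3, 5, 40], [70, 2, -3], [-68, 1, -4])
        assert p.normal[2] >= 0

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="collinear"):
            cutting_plane([0, 0, 0], [1, 0, 0], [2, 0, 0])


class TestMeshPlaneIntersection:
    def test_unit_sphere_great_circle(self, icosphere):
        loops = mesh_plane_intersection(
            icosphere, CuttingPlane(point=[0, 0, 0], normal=[0, 0, 1]))
        assert len(loops) == 1
        assert loops[0].closed
        assert loops[0].length_mm == pytest.approx(2 * np.pi, rel=0.02)

    def test_matches_brute_force_enumeration(self, icosphere):
        """Chained loops contain exactly the brute-force segment set for
        100 random planes."""
        rng = np.random.default_rng(42)
        tested = 0
        for _ in range(100):
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            point = rng.uniform(-0.8, 0.8, size=3)
            plane = CuttingPlane(point=point, normal=normal)
            expected = brute_force_plane_segments(
                icosphere.nodes, icosphere.scalp_faces, plane)
            loops = mesh_plane_intersection(icosphere, plane)
            assert loops_to_segments(loops) == expected
            tested += 1
        assert tested == 100

    def test_no_intersection_returns_empty(self, icosphere):
        loops = mesh_plane_intersection(
            icosphere, CuttingPlane(point=[0, 0, 5], normal=[0, 0, 1]))
        assert loops == []

    def test_loops_sorted_by_length(self, reference_mesh, reference_surface):
        poi = reference_surface.points[0]
        plane = cutting_plane(poi, reference_surface.left_ear,
                              reference_surface.right_ear)
        loops = mesh_plane_intersection(reference_mesh, plane)
        lengths = [c.length_mm for c in loops]
        assert lengths == sorted(lengths, reverse=True)

    def test_cumulative_arc_monotone(self, icosphere):
        loops = mesh_plane_intersection(
            icosphere, CuttingPlane(point=[0, 0, 0.3], normal=[0, 0, 1]))
        assert np.all(np.diff(loops[0].cumulative_arc_mm) > 0)


def circle_curve(radius=90.0, n=720, noise=0.0, rng=None):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius + (rng.normal(scale=noise, size=n) if noise else 0.0)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(n)])
    pts = np.vstack([pts, pts[:1]])
    return IntersectionCurve(pts, closed=True)


class TestExtractSegment:
    def test_quarter_circumference_subtends_half_pi_each_side(self):
        c = circle_curve(radius=1.0)
        seg = extract_segment(c, poi=[1, 0, 0], half_length_mm=np.pi / 2)
        a, b = seg.vertices[0], seg.vertices[-1]
        angle = np.arccos(np.clip(np.dot(a, b) / (np.linalg.norm(a)
                                                  * np.linalg.norm(b)), -1, 1))
        assert angle == pytest.approx(np.pi, abs=0.02)

    def test_poi_vertex_is_arc_midpoint(self):
        c = circle_curve(radius=50.0)
        poi = c.vertices[40]
        seg = extract_segment(c, poi, half_length_mm=30.0)
        mid = seg.point_at_arc(seg.length_mm / 2)[0]
        np.testing.assert_allclose(mid, poi, atol=1e-9)

    def test_arc_length_is_twice_half_length(self):
        c = circle_curve(radius=70.0)
        seg = extract_segment(c, c.vertices[100], half_length_mm=45.0)
        resummed = np.linalg.norm(np.diff(seg.vertices, axis=0), axis=1).sum()
        assert resummed == pytest.approx(90.0, abs=2 * np.pi * 70 / 720)

    def test_too_long_raises(self):
        c = circle_curve(radius=10.0)
        with pytest.raises(ValueError, match="half_length"):
            extract_segment(c, c.vertices[0], half_length_mm=100.0)


class TestResampleSmooth:
    def test_straight_line_is_fixed_point(self):
        pts = np.linspace([0, 0, 0], [10, 0, 0], 101)
        out = resample_smooth(IntersectionCurve(pts, closed=False),
                              step_mm=0.1, window_mm=5.0)
        np.testing.assert_allclose(out.vertices, pts, atol=1e-9)

    def test_noise_rms_halved_on_circle(self):
        rng = np.random.default_rng(5)
        c = circle_curve(radius=90.0, noise=0.5, rng=rng)
        seg = extract_segment(c, c.vertices[0], half_length_mm=100.0)
        out = resample_smooth(seg, step_mm=0.1, window_mm=5.0)

        def rms(v):
            return np.sqrt(np.mean(
                (np.linalg.norm(v[:, :2], axis=1) - 90.0) ** 2))

        assert rms(out.vertices) <= 0.5 * rms(seg.vertices)

    def test_arc_length_preserved_within_two_percent(self):
        """Length is preserved for curves whose features are larger than
        the smoothing window (the intended input class)."""
        rng = np.random.default_rng(6)
        c = circle_curve(radius=90.0, noise=0.1, rng=rng)
        seg = extract_segment(c, c.vertices[0], half_length_mm=80.0)
        out = resample_smooth(seg)
        assert out.length_mm == pytest.approx(seg.length_mm, rel=0.02)

    def test_vertex_spacing_uniform(self):
        c = circle_curve(radius=30.0)
        seg = extract_segment(c, c.vertices[0], half_length_mm=40.0)
        out = resample_smooth(seg, step_mm=0.1, window_mm=5.0)
        gaps = np.diff(out.cumulative_arc_mm)[:-1]  # last gap may be partial
        assert np.all(np.abs(gaps - 0.1) < 1e-3)

    def test_short_curve_warns_and_skips(self):
        pts = np.linspace([0, 0, 0], [2, 0, 0], 21)
        with pytest.warns(UserWarning, match="smoothing skipped"):
            resample_smooth(IntersectionCurve(pts, closed=False),
                            step_mm=0.1, window_mm=5.0)


class TestPlaceOptodes:
    def test_reference_five_and_fifty(self, reference_mesh, reference_surface,
                                      forehead_poi):
        """Requested 5 and 50 mm are achieved within 0.1 mm with the POI
        arc-centered between the source and the far detector."""
        layout = place_optodes(
            reference_mesh, forehead_poi,
            (reference_surface.left_ear, reference_surface.right_ear),
            [5.0, 50.0])
        ach = layout.achieved_distances_mm()
        assert ach[0] == pytest.approx(5.0, abs=0.1)
        assert ach[1] == pytest.approx(50.0, abs=0.1)
        # centering: POI is 25 mm (arc) from both the source and far detector
        curve = layout.curve
        s_poi = curve.cumulative_arc_mm[
            np.argmin(np.linalg.norm(curve.vertices - layout.poi, axis=1))]
        s_src = s_poi - 25.0
        assert _arc_between(curve, s_src, s_poi) == pytest.approx(25.0,
                                                                  abs=0.1)

    def test_runs_under_one_second(self, reference_mesh, reference_surface,
                                   forehead_poi):
        t0 = time.perf_counter()
        place_optodes(reference_mesh, forehead_poi,
                      (reference_surface.left_ear,
                       reference_surface.right_ear), [5.0, 50.0])
        assert time.perf_counter() - t0 < 1.0

    def test_arc_exceeds_chord_on_sphere(self, icosphere):
        """On a sphere the curved arc always beats the Euclidean chord."""
        mesh = icosphere
        poi = np.array([0.0, 0.0, 1.0])
        ears = (np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]))
        d = 1.2  # radians ~ mm on the unit sphere
        layout = place_optodes(mesh, poi, ears, [d],
                               segment_margin_mm=0.3, window_mm=0.5)
        chord = np.linalg.norm(layout.detectors[0].pos - layout.source_pos)
        arc = layout.detectors[0].achieved_mm
        assert arc > chord
        assert chord == pytest.approx(2 * np.sin(d / 2), rel=0.05)

    def test_achieved_equals_dense_polyline_summation(
            self, reference_mesh, reference_surface, forehead_poi):
        layout = place_optodes(
            reference_mesh, forehead_poi,
            (reference_surface.left_ear, reference_surface.right_ear),
            [10.0, 30.0])
        curve = layout.curve
        for det in layout.detectors:
            # oracle: locate source/detector arc coordinates and re-sum
            s_src = curve.cumulative_arc_mm[np.argmin(
                np.linalg.norm(curve.vertices - layout.source_pos, axis=1))]
            s_det = curve.cumulative_arc_mm[np.argmin(
                np.linalg.norm(curve.vertices - det.pos, axis=1))]
            brute = _arc_between(curve, s_src, s_det)
            assert det.achieved_mm == pytest.approx(brute, abs=0.2)

    def test_optodes_adhere_to_surface(self, reference_mesh,
                                       reference_surface, forehead_poi):
        layout = place_optodes(
            reference_mesh, forehead_poi,
            (reference_surface.left_ear, reference_surface.right_ear),
            [5.0, 25.0, 30.0])
        loc = SurfaceLocator(reference_mesh.nodes, reference_mesh.scalp_faces)
        pts = np.vstack([layout.source_pos]
                        + [d.pos for d in layout.detectors])
        _, dist, _ = loc.closest(pts)
        assert dist.max() <= 0.5

    def test_source_direction_points_inward(self, reference_mesh,
                                            reference_surface, forehead_poi):
        layout = place_optodes(
            reference_mesh, forehead_poi,
            (reference_surface.left_ear, reference_surface.right_ear), [30.0])
        center = reference_mesh.nodes.mean(axis=0)
        assert np.dot(layout.source_dir, center - layout.source_pos) > 0
        probe = layout.source_pos + 2.0 * layout.source_dir
        # 2 mm along the inward normal lands strictly inside the head
        loc = SurfaceLocator(reference_mesh.nodes, reference_mesh.scalp_faces)
        _, dist, _ = loc.closest(probe[None])
        assert dist[0] > 0.1

    def test_nonpositive_distance_raises(self, reference_mesh,
                                         reference_surface, forehead_poi):
        with pytest.raises(ValueError, match="positive"):
            place_optodes(reference_mesh, forehead_poi,
                          (reference_surface.left_ear,
                           reference_surface.right_ear), [-5.0, 10.0])

    def test_layout_json_roundtrip(self, tmp_path, reference_mesh,
                                   reference_surface, forehead_poi):
        from headmc.placement import OptodeLayout

        layout = place_optodes(
            reference_mesh, forehead_poi,
            (reference_surface.left_ear, reference_surface.right_ear),
            [5.0, 50.0])
        p = tmp_path / "layout.json"
        layout.to_json(p)
        back = OptodeLayout.from_json(p)
        np.testing.assert_allclose(back.source_pos, layout.source_pos)
        assert [d.achieved_mm for d in back.detectors] == \
            layout.achieved_distances_mm()
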