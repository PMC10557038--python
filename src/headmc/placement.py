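"""Automated arc-length optode placement on head meshes.

The placement pipeline mirrors how a flat probe strip is wrapped around
the head: a cutting plane through the point of interest (POI) and the
two ear fiducials slices the scalp surface; the intersection perimeter
is extracted, a segment around the POI is resampled at sub-millimetre
resolution and smoothed; the source and detectors are then placed at
user-requested *arc-length* separations along this curve (not Euclidean
chords), with the POI centered between the source and the farthest
detector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import SurfaceLocator
from .meshing import HeadMesh

__all__ = [
    "CuttingPlane", "IntersectionCurve", "Optode", "OptodeLayout",
    "cutting_plane", "mesh_plane_intersection", "extract_segment",
    "resample_smooth", "place_optodes",
]

#: placement tolerances (mm)
ARC_TOL_MM = 0.1
TOL_SURFACE_MM = 0.5

DEFAULT_STEP_MM = 0.1
DEFAULT_WINDOW_MM = 5.0
DEFAULT_DETECTOR_RADIUS_MM = 0.7
SEGMENT_MARGIN_MM = 20.0


@dataclass
class CuttingPlane:
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-9):
            self.normal = self.normal / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass
class IntersectionCurve:
    """Ordered planar polyline with cumulative arc length."""

    vertices: np.ndarray          # (K, 3) mm
    closed: bool
    cumulative_arc_mm: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.cumulative_arc_mm is None:
            seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
            self.cumulative_arc_mm = np.concatenate([[0.0], np.cumsum(seg)])
        self.cumulative_arc_mm = np.asarray(self.cumulative_arc_mm, dtype=float)

    @property
    def length_mm(self) -> float:
        return float(self.cumulative_arc_mm[-1])

    def point_at_arc(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation at arc coordinate(s) ``s`` in [0, length]."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        x = np.interp(s, self.cumulative_arc_mm, self.vertices[:, 0])
        y = np.interp(s, self.cumulative_arc_mm, self.vertices[:, 1])
        z = np.interp(s, self.cumulative_arc_mm, self.vertices[:, 2])
        return np.stack([x, y, z], axis=-1)


@dataclass
class Optode:
    pos: np.ndarray
    direction: np.ndarray         # inward unit normal
    radius_mm: float
    requested_mm: float           # requested arc distance from the source
    achieved_mm: float            # measured arc distance from the source

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)


@dataclass
class OptodeLayout:
    source_pos: np.ndarray
    source_dir: np.ndarray
    detectors: list[Optode]
    poi: np.ndarray
    curve: IntersectionCurve

    def __post_init__(self) -> None:
        self.source_pos = np.asarray(self.source_pos, dtype=float)
        self.source_dir = np.asarray(self.source_dir, dtype=float)
        self.poi = np.asarray(self.poi, dtype=float)

    def achieved_distances_mm(self) -> list[float]:
        return [d.achieved_mm for d in self.detectors]

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str | Path, meta: dict | None = None) -> None:
        doc = {
            "source": {"pos": self.source_pos.tolist(),
                       "dir": self.source_dir.tolist()},
            "detectors": [
                {"pos": d.pos.tolist(), "dir": d.direction.tolist(),
                 "radius_mm": d.radius_mm, "requested_mm": d.requested_mm,
                 "achieved_mm": d.achieved_mm}
                for d in self.detectors],
            "poi": self.poi.tolist(),
            "curve": {"vertices": np.round(self.curve.vertices, 9).tolist(),
                      "closed": self.curve.closed},
            "meta": meta or {},
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "OptodeLayout":
        doc = json.loads(Path(path).read_text())
        dets = [Optode(pos=d["pos"], direction=d["dir"],
                       radius_mm=d["radius_mm"], requested_mm=d["requested_mm"],
                       achieved_mm=d["achieved_mm"]) for d in doc["detectors"]]
        curve = IntersectionCurve(np.asarray(doc["curve"]["vertices"]),
                                  closed=doc["curve"]["closed"])
        return cls(source_pos=np.asarray(doc["source"]["pos"]),
                   source_dir=np.asarray(doc["source"]["dir"]),
                   detectors=dets, poi=np.asarray(doc["poi"]), curve=curve)

    def curve_to_ply(self, path: str | Path) -> None:
        v = self.curve.vertices
        lines = ["ply", "format ascii 1.0", f"element vertex {len(v)}",
                 "property float x", "property float y", "property float z",
                 f"element edge {len(v) - 1}",
                 "property int vertex1", "property int vertex2", "end_header"]
        lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in v]
        lines += [f"{i} {i + 1}" for i in range(len(v) - 1)]
        Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------- operations
def cutting_plane(poi: np.ndarray, left_ear: np.ndarray,
                  right_ear: np.ndarray) -> CuttingPlane:
    """Plane through the POI and the two ear fiducials.

    The normal is the unit cross product of the two in-plane directions,
    signed so its superior (+z) component is non-negative.
    """
    poi = np.asarray(poi, dtype=float)
    u = np.asarray(left_ear, dtype=float) - poi
    v = np.asarray(right_ear, dtype=float) - poi
    n = np.cross(u, v)
    scale = max(np.linalg.norm(u), np.linalg.norm(v), 1.0)
    if np.linalg.norm(n) < 1e-9 * scale**2:
        raise ValueError("POI and ear fiducials are collinear; "
                         "the cutting plane is undefined")
    n = n / np.linalg.norm(n)
    if n[2] < 0 or (n[2] == 0 and (n[1] < 0 or (n[1] == 0 and n[0] < 0))):
        n = -n
    return CuttingPlane(point=poi, normal=n)


def mesh_plane_intersection(mesh: HeadMesh,
                            plane: CuttingPlane) -> list[IntersectionCurve]:
    """Closed intersection loops of the scalp surface with a plane.

    Every scalp triangle crossed by the plane contributes one segment
    whose endpoints are edge-plane crossings; segments are chained into
    loops via their shared mesh edges.  Loops are ordered by descending
    total length.  Vertices exactly on the plane are perturbed by an
    infinitesimal positive offset (simulation of simplicity).
    """
    nodes, faces = mesh.nodes, mesh.scalp_faces
    d = plane.signed_distance(nodes)
    scale = float(np.abs(d).max()) or 1.0
    d = np.where(d == 0.0, 1e-12 * scale, d)

    fd = d[faces]
    sign = fd > 0
    crossing = (sign.any(axis=1)) & (~sign.all(axis=1))
    if not np.any(crossing):
        return []
    cf = faces[crossing]
    cfd = fd[crossing]

    # per triangle: the two edges with a sign change
    edge_pairs = [(0, 1), (1, 2), (2, 0)]
    seg_pts = np.empty((len(cf), 2, 3))
    seg_keys = np.empty((len(cf), 2), dtype=np.int64)
    n_nodes = len(nodes)
    for t in range(len(cf)):
        hits = []
        for i, j in edge_pairs:
            di, dj = cfd[t, i], cfd[t, j]
            if (di > 0) != (dj > 0):
                # canonical node order so shared edges yield bit-identical
                # crossing points in both adjacent triangles
                a, b = sorted((int(cf[t, i]), int(cf[t, j])))
                w = d[a] / (d[a] - d[b])
                p = nodes[a] + w * (nodes[b] - nodes[a])
                hits.append((a * n_nodes + b, p))
        if len(hits) != 2:  # pragma: no cover - excluded by the perturbation
            raise ValueError(f"triangle {t} crosses the plane on "
                             f"{len(hits)} edges")
        seg_keys[t] = [hits[0][0], hits[1][0]]
        seg_pts[t] = [hits[0][1], hits[1][1]]

    # chain segments: each edge key is shared by exactly two triangles
    from collections import defaultdict

    edge_to_tris: dict[int, list[int]] = defaultdict(list)
    for t in range(len(cf)):
        edge_to_tris[seg_keys[t, 0]].append(t)
        edge_to_tris[seg_keys[t, 1]].append(t)
    for key, tris in edge_to_tris.items():
        if len(tris) != 2:
            raise ValueError(
                f"non-manifold intersection: edge key {key} is crossed by "
                f"triangles {tris}")

    used = np.zeros(len(cf), dtype=bool)
    loops: list[IntersectionCurve] = []
    for start in range(len(cf)):
        if used[start]:
            continue
        pts = [seg_pts[start, 0], seg_pts[start, 1]]
        used[start] = True
        cur_t, cur_key = start, seg_keys[start, 1]
        while True:
            a, b = edge_to_tris[cur_key]
            nxt = b if a == cur_t else a
            if used[nxt]:
                break  # loop closed
            k0, k1 = seg_keys[nxt]
            out_key = k1 if k0 == cur_key else k0
            out_pt = seg_pts[nxt, 1] if k0 == cur_key else seg_pts[nxt, 0]
            pts.append(out_pt)
            used[nxt] = True
            cur_t, cur_key = nxt, out_key
        if not np.array_equal(pts[-1], pts[0]):
            pts.append(pts[0])  # close the polyline
        loops.append(IntersectionCurve(np.array(pts), closed=True))
    loops.sort(key=lambda c: -c.length_mm)
    return loops


def extract_segment(curve: IntersectionCurve, poi: np.ndarray,
                    half_length_mm: float) -> IntersectionCurve:
    """Open sub-curve of arc length ``2*half_length_mm`` centered on the
    loop vertex nearest the POI (ties to the lower vertex index)."""
    if not curve.closed:
        raise ValueError("extract_segment expects a closed loop")
    L = curve.length_mm
    if 2 * half_length_mm >= L:
        raise ValueError(
            f"half_length {half_length_mm} mm too large for a loop of "
            f"length {L:.1f} mm")
    poi = np.asarray(poi, dtype=float)
    d = np.linalg.norm(curve.vertices[:-1] - poi, axis=1)
    i0 = int(np.argmin(d))  # argmin takes the lowest index on ties
    s0 = curve.cumulative_arc_mm[i0]

    # unwrap the loop to arc window [s0 - h, s0 + h]
    s_lo, s_hi = s0 - half_length_mm, s0 + half_length_mm
    base_s = curve.cumulative_arc_mm[:-1]
    all_s = np.concatenate([base_s - L, base_s, base_s + L])
    all_v = np.vstack([curve.vertices[:-1]] * 3)
    inside = (all_s > s_lo) & (all_s < s_hi)
    s_in = all_s[inside]
    v_in = all_v[inside]
    order = np.argsort(s_in, kind="stable")
    s_in, v_in = s_in[order], v_in[order]

    ends = curve.point_at_arc(np.mod([s_lo, s_hi], L))
    verts = np.vstack([ends[0], v_in, ends[1]])
    arc = np.concatenate([[s_lo], s_in, [s_hi]]) - s_lo
    # drop duplicate vertices created when an endpoint lands on a vertex
    keep = np.concatenate([[True], np.diff(arc) > 1e-12])
    return IntersectionCurve(verts[keep], closed=False,
                             cumulative_arc_mm=arc[keep])


def resample_smooth(curve: IntersectionCurve,
                    step_mm: float = DEFAULT_STEP_MM,
                    window_mm: float = DEFAULT_WINDOW_MM) -> IntersectionCurve:
    """Uniform arc-length resampling followed by moving-average smoothing.

    The polyline is resampled at ``step_mm`` by linear interpolation and
    smoothed with a centered moving average of extent ``window_mm``; the
    window shrinks symmetrically near the ends, so the endpoints are
    preserved and straight segments are left unchanged.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    if window_mm < step_mm:
        raise ValueError("window_mm must be >= step_mm")
    L = curve.length_mm
    n = int(np.floor(L / step_mm))
    s = np.arange(n + 1) * step_mm
    if s[-1] < L - 1e-9:
        s = np.concatenate([s, [L]])
    pts = curve.point_at_arc(s)

    if L < window_mm:
        warnings.warn("curve shorter than smoothing window; smoothing skipped")
        return IntersectionCurve(pts, closed=False)

    half = max(1, int(round(window_mm / (2 * step_mm))))
    sm = pts.copy()
    c = np.cumsum(np.vstack([np.zeros(3), pts]), axis=0)
    idx = np.arange(len(pts))
    h = np.minimum(np.minimum(idx, len(pts) - 1 - idx), half)
    lo, hi = idx - h, idx + h
    sm = (c[hi + 1] - c[lo]) / (hi - lo + 1)[:, None]
    return IntersectionCurve(sm, closed=False)


def _inward_directions(mesh: HeadMesh, locator: SurfaceLocator,
                       points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    snapped, _, fidx = locator.closest(points)
    tri = mesh.nodes[np.asarray(mesh.scalp_faces)[fidx]]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)  # outward by face winding
    return snapped, -n


def place_optodes(
    mesh: HeadMesh,
    poi: np.ndarray,
    ears: tuple[np.ndarray, np.ndarray],
    detector_distances_mm: list[float],
    detector_radius_mm: float = DEFAULT_DETECTOR_RADIUS_MM,
    step_mm: float = DEFAULT_STEP_MM,
    window_mm: float = DEFAULT_WINDOW_MM,
    segment_margin_mm: float = SEGMENT_MARGIN_MM,
) -> OptodeLayout:
    """Run the full placement pipeline at one POI.

    The source sits ``dmax/2`` before the POI along the placement curve
    and detector ``i`` sits at arc distance ``d_i`` beyond the source, so
    the POI is arc-centered between the source and the farthest
    detector.  Optode positions are snapped to the nearest scalp-surface
    point and carry inward unit-normal directions.
    """
    dists = [float(d) for d in detector_distances_mm]
    if not dists or any(d <= 0 for d in dists):
        raise ValueError("detector distances must be strictly positive")
    if sorted(dists) != dists:
        raise ValueError("detector distances must be sorted ascending")
    dmax = dists[-1]

    plane = cutting_plane(poi, ears[0], ears[1])
    loops = mesh_plane_intersection(mesh, plane)
    if not loops:
        raise ValueError("cutting plane does not intersect the scalp surface")
    poi = np.asarray(poi, dtype=float)
    loop = min(loops, key=lambda c: float(
        np.linalg.norm(c.vertices - poi, axis=1).min()))

    half = dmax / 2.0 + segment_margin_mm
    if 2 * half >= loop.length_mm:
        raise ValueError(
            f"intersection loop ({loop.length_mm:.1f} mm) too short for the "
            f"requested span; reduce distances or segment margin")
    segment = extract_segment(loop, poi, half)
    curve = resample_smooth(segment, step_mm=step_mm, window_mm=window_mm)

    # arc coordinate of the POI on the smoothed curve
    s_poi = curve.cumulative_arc_mm[
        int(np.argmin(np.linalg.norm(curve.vertices - poi, axis=1)))]
    s_src = s_poi - dmax / 2.0
    s_det = [s_src + d for d in dists]
    if s_src < 0 or max(s_det) > curve.length_mm:
        raise ValueError("placement span exceeds the extracted segment; "
                         "increase segment_margin_mm")

    raw = curve.point_at_arc(np.concatenate([[s_src], s_det]))
    locator = SurfaceLocator(mesh.nodes, mesh.scalp_faces)
    snapped, dirs = _inward_directions(mesh, locator, raw)

    # achieved separations re-measured along the dense placement curve
    achieved = [_arc_between(curve, s_src, s) for s in s_det]
    detectors = [
        Optode(pos=snapped[1 + i], direction=dirs[1 + i],
               radius_mm=float(detector_radius_mm), requested_mm=dists[i],
               achieved_mm=achieved[i])
        for i in range(len(dists))]
    return OptodeLayout(source_pos=snapped[0], source_dir=dirs[0],
                        detectors=detectors, poi=poi, curve=curve)


def _arc_between(curve: IntersectionCurve, s_a: float, s_b: float) -> float:
    """Arc length between two arc coordinates, re-summed over the polyline."""
    s_a, s_b = min(s_a, s_b), max(s_a, s_b)
    cum = curve.cumulative_arc_mm
    inner = (cum > s_a) & (cum < s_b)
    pts = np.vstack([curve.point_at_arc(s_a), curve.vertices[inner],
                     curve.point_at_arc(s_b)])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
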