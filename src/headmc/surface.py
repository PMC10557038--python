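"""Companion scalp surface locations and ear fiducials.

Candidate probe locations (points of interest, POIs) are distributed
quasi-uniformly over the scalp surface by Poisson-disk (dart-throwing)
sampling: uniformly sampled surface candidates are accepted greedily
whenever they keep at least ``spacing_mm`` from every already accepted
point.  Spherical exclusion zones emulate the face and ear regions that
MRI-derived models have removed for de-identification and placement
accuracy.  Two ear fiducials — the lateral extrema of the scalp pushed
5 mm inferior — anchor the optode-placement cutting plane.

The shipped default configuration (spacing, seed, exclusion zones) is
calibrated once against the reference phantom so that it yields exactly
805 locations, mirroring the density of published full-head location
sets, and is then frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import SurfaceLocator
from .meshing import HeadMesh

__all__ = [
    "ExclusionZone", "SurfaceSet", "distribute_surface_locations",
    "ear_fiducials", "default_exclusions", "forehead_index",
    "nearest_brain_distance",
    "DEFAULT_SPACING_MM", "DEFAULT_SEED",
]

#: Frozen default sampler configuration: calibrated once on the reference
#: phantom (1 mm voxels, 2 mm elements) to emit exactly 805 locations.
DEFAULT_SPACING_MM = 8.042188
DEFAULT_SEED = 1305

#: A sampled point may sit at most this far from the scalp surface (mm).
TOL_SURFACE_MM = 0.5

_INFERIOR_PUSH_MM = 5.0


@dataclass
class ExclusionZone:
    center: np.ndarray
    radius_mm: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius_mm <= 0:
            raise ValueError("exclusion radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.linalg.norm(pts - self.center, axis=1) < self.radius_mm


@dataclass
class SurfaceSet:
    """Scalp POI candidates plus the two ear fiducials."""

    points: np.ndarray                      # (P, 3) mm on the scalp
    left_ear: np.ndarray                    # (3,) mm
    right_ear: np.ndarray                   # (3,) mm
    excluded_zones: list[ExclusionZone] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.left_ear = np.asarray(self.left_ear, dtype=float)
        self.right_ear = np.asarray(self.right_ear, dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    def min_pairwise_distance(self) -> float:
        if len(self.points) < 2:
            return np.inf
        tree = cKDTree(self.points)
        d, _ = tree.query(self.points, k=2)
        return float(d[:, 1].min())

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Plain-text ``x y z`` table + JSON sidecar for fiducials/zones."""
        path = Path(path)
        lines = [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in self.points]
        path.write_text("\n".join(lines) + "\n")
        meta = {
            "left_ear": self.left_ear.tolist(),
            "right_ear": self.right_ear.tolist(),
            "excluded_zones": [
                {"center": z.center.tolist(), "radius_mm": z.radius_mm}
                for z in self.excluded_zones],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, sort_keys=True, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SurfaceSet":
        path = Path(path)
        points = np.loadtxt(path, ndmin=2)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        zones = [ExclusionZone(z["center"], z["radius_mm"])
                 for z in meta["excluded_zones"]]
        return cls(points=points, left_ear=np.asarray(meta["left_ear"]),
                   right_ear=np.asarray(meta["right_ear"]),
                   excluded_zones=zones)


def ear_fiducials(mesh: HeadMesh) -> tuple[np.ndarray, np.ndarray]:
    """Left/right ear points: lateral extrema of the scalp, 5 mm inferior.

    +x is the subject's left.  The pushed points are snapped back onto
    the scalp surface.
    """
    verts = mesh.nodes[mesh.scalp_vertex_ids()]
    center = verts.mean(axis=0)
    u = verts - center
    align = u[:, 0] / np.linalg.norm(u, axis=1)
    left = verts[np.argmax(align)].copy()
    right = verts[np.argmin(align)].copy()
    left[2] -= _INFERIOR_PUSH_MM
    right[2] -= _INFERIOR_PUSH_MM
    loc = SurfaceLocator(mesh.nodes, mesh.scalp_faces)
    snapped, _, _ = loc.closest(np.vstack([left, right]))
    return snapped[0], snapped[1]


def default_exclusions(mesh: HeadMesh) -> list[ExclusionZone]:
    """Face + two ear spherical exclusion zones derived from the scalp."""
    verts = mesh.nodes[mesh.scalp_vertex_ids()]
    left, right = ear_fiducials(mesh)
    center = verts.mean(axis=0)
    face_center = verts[np.argmax(verts[:, 1])].copy()  # anterior pole
    face_center[2] = center[2] - 0.2 * (verts[:, 2].max() - center[2])
    return [
        ExclusionZone(face_center, 45.0),
        ExclusionZone(left, 20.0),
        ExclusionZone(right, 20.0),
    ]


def distribute_surface_locations(
    mesh: HeadMesh,
    spacing_mm: float = DEFAULT_SPACING_MM,
    exclusions: list[ExclusionZone] | None = None,
    seed: int = DEFAULT_SEED,
    candidates_per_mm2: float = 1.0,
) -> SurfaceSet:
    """Poisson-disk sample of the scalp surface honoring exclusion zones.

    Candidates are drawn uniformly by area on the scalp triangles with a
    seeded generator and accepted greedily with a minimum separation of
    ``spacing_mm``; the result is deterministic for fixed inputs.  The
    candidate stream depends only on the mesh, the seed and the density,
    never on ``spacing_mm``, so the accepted count varies predictably
    with the spacing.

    Raises if no point can be placed.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    if exclusions is None:
        exclusions = default_exclusions(mesh)

    import trimesh

    surf = trimesh.Trimesh(vertices=mesh.nodes, faces=mesh.scalp_faces,
                           process=False)
    area = surf.area
    n_cand = max(1000, int(candidates_per_mm2 * area))
    cand, _ = trimesh.sample.sample_surface(surf, n_cand, seed=int(seed))
    cand = np.asarray(cand, dtype=float)

    keep = np.ones(len(cand), dtype=bool)
    for zone in exclusions:
        keep &= ~zone.contains(cand)
    cand = cand[keep]
    if len(cand) == 0:
        raise ValueError("all candidate locations fall inside exclusion zones")

    # greedy dart throwing on a uniform spatial hash
    cell = spacing_mm
    grid: dict[tuple[int, int, int], list[int]] = {}
    accepted: list[int] = []
    keys = np.floor(cand / cell).astype(np.int64)
    sp2 = spacing_mm**2
    for i in range(len(cand)):
        kx, ky, kz = keys[i]
        ok = True
        p = cand[i]
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((kx + dx, ky + dy, kz + dz), ()):
                        q = cand[j]
                        d2 = ((p[0] - q[0])**2 + (p[1] - q[1])**2
                              + (p[2] - q[2])**2)
                        if d2 < sp2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((kx, ky, kz), []).append(i)
            accepted.append(i)
    if not accepted:
        raise ValueError(
            f"spacing {spacing_mm} mm too large: no location could be placed")

    left, right = ear_fiducials(mesh)
    return SurfaceSet(points=cand[accepted], left_ear=left, right_ear=right,
                      excluded_zones=list(exclusions))


def forehead_index(points: np.ndarray) -> int:
    """Index of the location best aligned with the anterior-superior
    (brow) direction — a convenient default POI for placement demos."""
    pts = np.asarray(points, dtype=float)
    u = pts - pts.mean(axis=0)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    target = np.array([0.0, np.sin(np.radians(40.0)), np.cos(np.radians(40.0))])
    return int(np.argmax(u @ target))


def nearest_brain_distance(poi: np.ndarray, mesh: HeadMesh) -> float:
    """Minimum Euclidean distance (mm) from ``poi`` to gray/white nodes."""
    brain = np.isin(mesh.elem_label, (4, 5))
    if not np.any(brain):
        raise ValueError("mesh contains no gray (4) or white (5) elements")
    nodes = mesh.nodes[np.unique(mesh.tets[brain])]
    tree = cKDTree(nodes)
    d, _ = tree.query(np.asarray(poi, dtype=float))
    return float(d)
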