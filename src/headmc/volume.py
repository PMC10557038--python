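"""Labeled tissue volumes.

A :class:`LabeledVolume` is a 3-D integer grid of tissue labels on an
isotropic voxel lattice.  Labels follow the five-tissue head convention:

====  ====================
label tissue
====  ====================
0     background (air)
1     scalp
2     skull
3     cerebrospinal fluid
4     gray matter
5     white matter
====  ====================

World coordinates are millimetres, right-handed; ``origin_mm`` is the world
position of the center of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

TISSUE_LABELS = {1: "scalp", 2: "skull", 3: "csf", 4: "gray", 5: "white"}
N_TISSUES = 5


@dataclass
class LabeledVolume:
    grid: np.ndarray
    voxel_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be a 3-D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("grid must hold integer labels")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        labels = np.unique(self.grid)
        bad = set(labels.tolist()) - {0, 1, 2, 3, 4, 5}
        if bad:
            raise ValueError(f"unexpected labels {sorted(bad)}; expected 0..5")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def label_counts(self) -> dict[int, int]:
        """Voxel count per label (0..5)."""
        counts = np.bincount(self.grid.ravel(), minlength=6)
        return {int(k): int(v) for k, v in enumerate(counts)}

    def tissue_volumes_mm3(self) -> dict[int, float]:
        """Voxel-counted volume in mm^3 per tissue label 1..5."""
        counts = self.label_counts()
        v = self.voxel_mm**3
        return {t: counts.get(t, 0) * v for t in range(1, 6)}

    def voxel_centers_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel-center(s) at integer indices."""
        return np.asarray(idx, dtype=float) * self.voxel_mm + self.origin_mm

    def label_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel label lookup at world points; 0 outside the grid."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = np.rint((pts - self.origin_mm) / self.voxel_mm).astype(int)
        out = np.zeros(len(idx), dtype=self.grid.dtype)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        ii = idx[inside]
        out[inside] = self.grid[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(self.grid.astype(np.int16), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabeledVolume":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        voxel = float(np.linalg.norm(affine[:3, 0]))
        grid = np.asarray(img.dataobj).astype(np.int16)
        return cls(grid=grid, voxel_mm=voxel, origin_mm=affine[:3, 3].copy())

    def to_npy(self, path: str | Path) -> None:
        """Raw ``.npy`` grid with a JSON sidecar carrying the geometry."""
        path = Path(path)
        np.save(path, self.grid)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"voxel_mm": self.voxel_mm, "origin_mm": self.origin_mm.tolist()},
                sort_keys=True,
            )
        )

    @classmethod
    def from_npy(cls, path: str | Path) -> "LabeledVolume":
        path = Path(path)
        grid = np.load(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(grid=grid, voxel_mm=float(meta["voxel_mm"]),
                   origin_mm=np.asarray(meta["origin_mm"], dtype=float))


def validate_head_volume(vol: LabeledVolume) -> None:
    """Raise if any of the five tissue classes is empty."""
    counts = vol.label_counts()
    for t, name in TISSUE_LABELS.items():
        if counts.get(t, 0) == 0:
            raise ValueError(f"tissue layer {t} ({name}) is empty")
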