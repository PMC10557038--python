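"""Synthetic five-tissue head phantoms.

Concentric ellipsoidal shells stand in for MRI-derived head models: an
outer scalp shell, then skull, a thin cerebrospinal-fluid gap, a cortical
gray-matter ribbon, and a white-matter core.  An optional sinusoidal
perturbation of the gray/white interface gives a crude gyral texture.

Axis convention (world mm, right-handed):

* ``x`` — left/right (lateral), +x is the subject's left
* ``y`` — posterior/anterior, +y is anterior (the face)
* ``z`` — inferior/superior, +z is up

The reference phantom (semiaxes 80 x 95 x 70 mm, scalp 6 / skull 7 /
CSF 2 mm) is the fixture all frozen defaults are calibrated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import LabeledVolume, validate_head_volume

__all__ = ["PhantomSpec", "build_phantom", "reference_spec"]

_DEFAULT_THICKNESS = {"scalp": 6.0, "skull": 7.0, "csf": 2.0, "gray": 4.0}


@dataclass
class PhantomSpec:
    """Geometry of a concentric-shell head phantom.

    Parameters
    ----------
    head_semiaxes_mm:
        Outer scalp ellipsoid semiaxes ``(x, y, z)`` in mm.
    layer_thickness_mm:
        Shell thickness in mm for ``scalp``, ``skull``, ``csf`` and
        (optionally) ``gray``; white matter fills the remaining interior.
    gyri_amplitude_mm, gyri_frequency:
        Amplitude (mm) and angular frequency of a sinusoidal radial
        perturbation of the gray/white interface; 0 disables it.
    seed:
        Reserved for stochastic texture; the default phantom is fully
        deterministic but the seed is recorded for provenance.
    """

    head_semiaxes_mm: tuple[float, float, float] = (80.0, 95.0, 70.0)
    layer_thickness_mm: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_THICKNESS))
    gyri_amplitude_mm: float = 0.0
    gyri_frequency: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.head_semiaxes_mm = tuple(float(s) for s in self.head_semiaxes_mm)
        if len(self.head_semiaxes_mm) != 3 or min(self.head_semiaxes_mm) <= 0:
            raise ValueError("head_semiaxes_mm must be three positive values")
        thick = dict(_DEFAULT_THICKNESS)
        thick.update(self.layer_thickness_mm)
        self.layer_thickness_mm = thick
        for name in ("scalp", "skull", "csf", "gray"):
            if thick[name] <= 0:
                raise ValueError(f"layer thickness for {name!r} must be > 0")

    def shell_semiaxes(self) -> list[np.ndarray]:
        """Semiaxes of the five nested boundary ellipsoids, outermost first.

        Element ``i`` is the outer boundary of tissue label ``i+1``; the
        white-matter core is the innermost ellipsoid.
        """
        t = self.layer_thickness_mm
        outer = np.asarray(self.head_semiaxes_mm, dtype=float)
        cum = np.cumsum([0.0, t["scalp"], t["skull"], t["csf"], t["gray"]])
        shells = [outer - c for c in cum]
        for label, s in enumerate(shells, start=1):
            if np.any(s <= 0):
                name = {1: "scalp", 2: "skull", 3: "csf", 4: "gray", 5: "white"}
                raise ValueError(
                    f"shell for tissue {label} ({name[label]}) has zero volume: "
                    f"semiaxes {tuple(np.round(s, 2))}; enlarge head_semiaxes_mm "
                    "or reduce layer thicknesses")
        return shells


def reference_spec() -> PhantomSpec:
    """The frozen reference phantom all default calibrations refer to."""
    return PhantomSpec()


def build_phantom(spec: PhantomSpec, voxel_mm: float = 1.0) -> LabeledVolume:
    """Voxelize a :class:`PhantomSpec` into a :class:`LabeledVolume`.

    Each voxel center is classified against the nested boundary
    ellipsoids; labels run 1 (scalp, outermost) to 5 (white matter,
    innermost).  Deterministic for a fixed spec.
    """
    if not (0.5 <= voxel_mm <= 2.0):
        raise ValueError("voxel_mm must lie in [0.5, 2] mm")
    shells = spec.shell_semiaxes()
    outer = shells[0]
    pad = 2.0 * voxel_mm
    n = np.ceil(2 * (outer + pad) / voxel_mm).astype(int) + 1
    # grid centered on the ellipsoid center
    center = (n - 1) / 2.0 * voxel_mm
    origin = -center
    ax = [origin[i] + voxel_mm * np.arange(n[i]) for i in range(3)]
    X = ax[0][:, None, None]
    Y = ax[1][None, :, None]
    Z = ax[2][None, None, :]

    grid = np.zeros(tuple(n), dtype=np.int16)
    for label, semi in enumerate(shells, start=1):
        semi_eff = semi
        if label == 5 and spec.gyri_amplitude_mm > 0:
            # wavy gray/white interface: modulate the normalized radius
            theta = np.arctan2(np.sqrt(X**2 + Y**2), Z)
            phi = np.arctan2(Y, X)
            wave = np.sin(spec.gyri_frequency * phi) * np.sin(
                spec.gyri_frequency * theta)
            r2 = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2
            bump = spec.gyri_amplitude_mm / np.mean(semi)
            inside = r2 <= (1.0 + bump * wave) ** 2
            grid[inside] = label
            continue
        r2 = (X / semi_eff[0]) ** 2 + (Y / semi_eff[1]) ** 2 + (Z / semi_eff[2]) ** 2
        grid[r2 <= 1.0] = label

    vol = LabeledVolume(grid=grid, voxel_mm=float(voxel_mm), origin_mm=origin)
    validate_head_volume(vol)
    return vol
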