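"""Tissue optical properties and MMC-dialect simulation input files.

``write_session_json`` emits a mesh-based Monte Carlo session document
(session / forward / mesh / optode blocks) and ``write_optical_properties_dat``
the companion whitespace-delimited media table, one line per tissue:
``index mua mus g n`` (1/mm, 1/mm, -, -).  Both writers are byte-deterministic
(sorted keys, fixed float formatting) so outputs can be diffed and frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .placement import OptodeLayout, Optode
from .volume import N_TISSUES, TISSUE_LABELS

__all__ = [
    "TissueOptics", "SimulationConfig",
    "write_session_json", "read_session_json",
    "write_optical_properties_dat", "read_optical_properties_dat",
]


@dataclass
class TissueOptics:
    """Per-tissue optical and dynamic properties, label order 1..5.

    ``alpha_Db`` is the DCS blood-flow index (effective Brownian
    diffusion coefficient, mm^2/s); 0 marks static tissue.
    """

    mua: np.ndarray                      # absorption, 1/mm
    mus: np.ndarray                      # scattering, 1/mm
    g: np.ndarray                        # anisotropy
    n: np.ndarray                        # refractive index
    alpha_Db: np.ndarray = field(default=None)  # mm^2/s

    def __post_init__(self) -> None:
        for name in ("mua", "mus", "g", "n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_TISSUES,):
                raise ValueError(f"{name} must have {N_TISSUES} entries "
                                 f"(tissues {sorted(TISSUE_LABELS)})")
            setattr(self, name, arr)
        if self.alpha_Db is None:
            self.alpha_Db = np.zeros(N_TISSUES)
        self.alpha_Db = np.asarray(self.alpha_Db, dtype=float)
        if np.any(self.mua < 0):
            raise ValueError("mua must be >= 0")
        if np.any(self.mus <= 0):
            raise ValueError("mus must be > 0")
        if np.any(np.abs(self.g) > 1):
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if np.any(self.n < 1):
            raise ValueError("refractive index must be >= 1")
        if np.any(self.alpha_Db < 0):
            raise ValueError("alpha_Db must be >= 0")
        if np.any(self.musp <= 0):
            raise ValueError("reduced scattering mus*(1-g) must be > 0")

    @property
    def musp(self) -> np.ndarray:
        """Reduced scattering coefficient mus' = mus*(1-g), 1/mm."""
        return self.mus * (1.0 - self.g)

    @classmethod
    def typical_head(cls) -> "TissueOptics":
        """Literature-typical adult head values at ~785 nm."""
        return cls(
            mua=np.array([0.0164, 0.0115, 0.0026, 0.0186, 0.0186]),
            mus=np.array([0.74, 0.94, 0.01, 1.11, 1.11]) / (1 - 0.01),
            g=np.full(5, 0.01),
            n=np.full(5, 1.37),
            alpha_Db=np.array([1e-8, 0.0, 0.0, 6e-6, 6e-6]),
        )

    def to_json(self, path: str | Path) -> None:
        doc = {k: getattr(self, k).tolist()
               for k in ("mua", "mus", "g", "n", "alpha_Db")}
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TissueOptics":
        doc = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v) for k, v in doc.items()})


@dataclass
class SimulationConfig:
    """Everything a forward photon simulation needs."""

    photon_count: int
    layout: OptodeLayout
    optics: TissueOptics
    mesh_ref: str
    seed: int = 0
    time_gates: tuple[float, float, float] = (0.0, 5e-9, 5e-9)
    wavelength_nm: float = 785.0
    session_name: str = "headmc"

    def __post_init__(self) -> None:
        if self.photon_count <= 0:
            raise ValueError("photon_count must be positive")
        start, end, step = self.time_gates
        if not start < end:
            raise ValueError("time gate start must precede end")
        if step <= 0:
            raise ValueError("time gate step must be positive")
        if not (600.0 <= self.wavelength_nm <= 1100.0):
            raise ValueError("wavelength_nm must lie in [600, 1100] nm")

    @property
    def k0_per_mm(self) -> float:
        """Optical wavenumber in the medium of tissue 1: 2*pi*n/lambda."""
        return 2 * np.pi * self.optics.n[0] / (self.wavelength_nm * 1e-6)


def write_session_json(config: SimulationConfig, path: str | Path) -> None:
    """Serialize a :class:`SimulationConfig` as an MMC-dialect session.

    Parsing the document back (:func:`read_session_json`) reproduces
    every field bit-exactly.
    """
    lay = config.layout
    doc = {
        "Session": {
            "ID": config.session_name,
            "Photons": int(config.photon_count),
            "RNGSeed": int(config.seed),
        },
        "Forward": {
            "T0": config.time_gates[0],
            "T1": config.time_gates[1],
            "Dt": config.time_gates[2],
            "WavelengthNm": config.wavelength_nm,
        },
        "Mesh": {"MeshID": config.mesh_ref},
        "Optode": {
            "Source": {
                "Pos": lay.source_pos.tolist(),
                "Dir": lay.source_dir.tolist(),
                "Type": "pencil",
            },
            "Detector": [
                {"Pos": d.pos.tolist(), "Dir": d.direction.tolist(),
                 "R": d.radius_mm, "RequestedMM": d.requested_mm,
                 "AchievedMM": d.achieved_mm}
                for d in lay.detectors],
        },
        "Media": [
            {"mua": config.optics.mua[t], "mus": config.optics.mus[t],
             "g": config.optics.g[t], "n": config.optics.n[t],
             "alphaDb": config.optics.alpha_Db[t]}
            for t in range(N_TISSUES)],
        "POI": lay.poi.tolist(),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))


def read_session_json(path: str | Path) -> SimulationConfig:
    doc = json.loads(Path(path).read_text())
    media = doc["Media"]
    optics = TissueOptics(
        mua=[m["mua"] for m in media], mus=[m["mus"] for m in media],
        g=[m["g"] for m in media], n=[m["n"] for m in media],
        alpha_Db=[m["alphaDb"] for m in media])
    dets = [Optode(pos=d["Pos"], direction=d["Dir"], radius_mm=d["R"],
                   requested_mm=d["RequestedMM"], achieved_mm=d["AchievedMM"])
            for d in doc["Optode"]["Detector"]]
    from .placement import IntersectionCurve

    layout = OptodeLayout(
        source_pos=np.asarray(doc["Optode"]["Source"]["Pos"]),
        source_dir=np.asarray(doc["Optode"]["Source"]["Dir"]),
        detectors=dets, poi=np.asarray(doc["POI"]),
        curve=IntersectionCurve(np.array([doc["POI"], doc["POI"]]),
                                closed=False))
    fwd = doc["Forward"]
    return SimulationConfig(
        photon_count=doc["Session"]["Photons"], layout=layout, optics=optics,
        mesh_ref=doc["Mesh"]["MeshID"], seed=doc["Session"]["RNGSeed"],
        time_gates=(fwd["T0"], fwd["T1"], fwd["Dt"]),
        wavelength_nm=fwd["WavelengthNm"], session_name=doc["Session"]["ID"])


def write_optical_properties_dat(optics: TissueOptics, path: str | Path) -> None:
    """Media table: ``index mua mus g n``, one line per tissue 1..5."""
    lines = ["1 5"]  # format tag, media count
    for t in range(N_TISSUES):
        lines.append(f"{t + 1} {optics.mua[t]:.6f} {optics.mus[t]:.6f} "
                     f"{optics.g[t]:.6f} {optics.n[t]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_optical_properties_dat(path: str | Path) -> TissueOptics:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    n_media = int(header[1])
    if len(lines) - 1 != n_media:
        raise ValueError(f"expected {n_media} media lines, got {len(lines) - 1}")
    rows = [ln.split() for ln in lines[1:]]
    return TissueOptics(
        mua=[float(r[1]) for r in rows], mus=[float(r[2]) for r in rows],
        g=[float(r[3]) for r in rows], n=[float(r[4]) for r in rows])
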