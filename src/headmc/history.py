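"""Detected-photon history records.

A :class:`PhotonHistory` stores, per detected photon: the detector id,
the partial pathlength traveled inside each of the five tissues (mm),
the dimensionless momentum transfer accumulated in each tissue, and the
survival weight.  Two on-disk dialects are supported:

* an internal HDF5 container (lossless round trip), and
* a read-oriented binary ``.mch`` dialect (little-endian): 4-byte magic
  ``MCXH``; seven uint32 header words (version, maxmedia, detnum,
  colcount, totalphoton, detectedphoton, savedphoton); float32 unitmm;
  uint32 seed-byte count; float32 normalizer; int32 respin; uint32
  srcnum; uint32 savedetflag; two reserved int32; then ``savedphoton x
  colcount`` float32 records.  The supported column layouts are
  ``[det_id, ppath*media, mom*media]`` and the same plus a trailing
  detected-weight column; pathlengths on disk are in ``unitmm`` units.

Detector ids are 1-based on disk and in memory (id 0 never occurs).
When the weight column is absent, weights are reconstructed at read
time as ``exp(-sum_t mua_t * L_t)`` from supplied optics (continuous
absorption weighting).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import N_TISSUES

__all__ = ["PhotonHistory", "write_photon_history", "read_photon_history",
           "write_mch", "read_mch"]

_MCH_MAGIC = b"MCXH"
_MCH_HEADER = "<4s7I f I f i I I 2i"  # 64 bytes


@dataclass
class PhotonHistory:
    det_id: np.ndarray                    # (R,) int, 1-based
    ppath: np.ndarray                     # (R, 5) mm per tissue
    mom: np.ndarray                       # (R, 5) dimensionless
    weight: np.ndarray                    # (R,) in (0, 1]
    unit_mm: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.det_id = np.asarray(self.det_id, dtype=np.int32)
        self.ppath = np.asarray(self.ppath, dtype=float).reshape(-1, N_TISSUES)
        self.mom = np.asarray(self.mom, dtype=float).reshape(-1, N_TISSUES)
        self.weight = np.asarray(self.weight, dtype=float)
        r = len(self.det_id)
        if self.ppath.shape[0] != r or self.mom.shape[0] != r \
                or len(self.weight) != r:
            raise ValueError("record arrays disagree on length")
        if r:
            if self.det_id.min() < 1:
                raise ValueError("detector ids must be >= 1")
            if self.ppath.min() < 0 or self.mom.min() < 0:
                raise ValueError("pathlengths and momentum transfer "
                                 "must be non-negative")
            if self.weight.min() <= 0 or self.weight.max() > 1 + 1e-12:
                raise ValueError("weights must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.det_id)

    def select_detector(self, det_id: int) -> "PhotonHistory":
        m = self.det_id == det_id
        return PhotonHistory(self.det_id[m], self.ppath[m], self.mom[m],
                             self.weight[m], self.unit_mm, dict(self.meta))


def mean_partial_pathlengths(hist: PhotonHistory) -> np.ndarray:
    """Weight-weighted mean partial pathlength per tissue (mm)."""
    if len(hist) == 0:
        raise ValueError("empty photon history")
    w = hist.weight
    return (hist.ppath * w[:, None]).sum(axis=0) / w.sum()


# -------------------------------------------------------- internal dialect
def write_photon_history(hist: PhotonHistory, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["unit_mm"] = hist.unit_mm
        for k, v in hist.meta.items():
            f.attrs[f"meta_{k}"] = v
        f.create_dataset("det_id", data=hist.det_id)
        f.create_dataset("ppath", data=hist.ppath)
        f.create_dataset("mom", data=hist.mom)
        f.create_dataset("weight", data=hist.weight)


def _read_internal(path: str | Path) -> PhotonHistory:
    import h5py

    with h5py.File(path, "r") as f:
        meta = {k[5:]: (v.item() if hasattr(v, "item") and v.shape == () else v)
                for k, v in f.attrs.items() if k.startswith("meta_")}
        return PhotonHistory(
            det_id=f["det_id"][()], ppath=f["ppath"][()], mom=f["mom"][()],
            weight=f["weight"][()], unit_mm=float(f.attrs["unit_mm"]),
            meta=meta)


# ------------------------------------------------------------- mch dialect
def write_mch(hist: PhotonHistory, path: str | Path, *,
              include_weight: bool = True, total_photons: int | None = None,
              n_detectors: int | None = None) -> None:
    """Write the binary ``.mch`` dialect (ppath stored in unit_mm units)."""
    media = N_TISSUES
    cols = 1 + 2 * media + (1 if include_weight else 0)
    r = len(hist)
    data = np.empty((r, cols), dtype=np.float32)
    data[:, 0] = hist.det_id
    data[:, 1:1 + media] = hist.ppath / hist.unit_mm
    data[:, 1 + media:1 + 2 * media] = hist.mom
    if include_weight:
        data[:, -1] = hist.weight
    ndet = n_detectors if n_detectors is not None else \
        (int(hist.det_id.max()) if r else 1)
    header = struct.pack(
        _MCH_HEADER, _MCH_MAGIC, 1, media, ndet, cols,
        int(total_photons if total_photons is not None else r), r, r,
        float(hist.unit_mm), 0, 1.0, 1, 1, 0, 0, 0)
    with open(path, "wb") as f:
        f.write(header)
        f.write(data.tobytes())


def read_mch(path: str | Path, optics=None) -> PhotonHistory:
    """Decode the ``.mch`` dialect.

    If the weight column is absent, ``optics`` (a
    :class:`~headmc.optics.TissueOptics`) must be supplied so weights can
    be reconstructed from the partial pathlengths.
    """
    raw = Path(path).read_bytes()
    size = struct.calcsize(_MCH_HEADER)
    if len(raw) < size or raw[:4] != _MCH_MAGIC:
        raise ValueError(f"{path}: not an mch-dialect file (bad magic)")
    (_, version, media, ndet, cols, totalphoton, detected, saved,
     unitmm, seedbytes, normalizer, respin, srcnum, savedetflag,
     _r1, _r2) = struct.unpack(_MCH_HEADER, raw[:size])
    if media != N_TISSUES:
        raise ValueError(f"{path}: {media} media declared; this reader "
                         f"supports exactly {N_TISSUES}")
    has_weight = cols == 1 + 2 * media + 1
    if not has_weight and cols != 1 + 2 * media:
        raise ValueError(
            f"{path}: column count {cols} inconsistent with {media} media; "
            f"expected {1 + 2 * media} (det, ppath, mom) or "
            f"{2 + 2 * media} (plus weight)")
    data = np.frombuffer(raw[size:], dtype="<f4")
    if data.size != saved * cols:
        raise ValueError(f"{path}: payload holds {data.size} floats, header "
                         f"declares {saved} x {cols}")
    data = data.reshape(saved, cols).astype(float)
    det_id = data[:, 0].astype(np.int32)
    ppath = data[:, 1:1 + media] * unitmm
    mom = data[:, 1 + media:1 + 2 * media]
    if has_weight:
        weight = data[:, -1]
    else:
        if optics is None:
            raise ValueError(f"{path}: no weight column; supply optics to "
                             "reconstruct weights from pathlengths")
        weight = np.exp(-(ppath * optics.mua[None, :]).sum(axis=1))
    if saved == 0:
        weight = np.empty(0)
    return PhotonHistory(det_id=det_id, ppath=ppath, mom=mom, weight=weight,
                         unit_mm=float(unitmm),
                         meta={"totalphoton": int(totalphoton),
                               "normalizer": float(normalizer),
                               "dialect": "mch"})


def read_photon_history(path: str | Path, dialect: str = "internal",
                        optics=None) -> PhotonHistory:
    """Read a history file in the ``internal`` or ``mch`` dialect."""
    if dialect == "internal":
        return _read_internal(path)
    if dialect == "mch":
        return read_mch(path, optics=optics)
    raise ValueError(f"unknown dialect {dialect!r}; expected internal or mch")
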