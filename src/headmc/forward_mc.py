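"""Layered semi-infinite photon Monte Carlo.

A desk-scale random-walk engine that produces the same per-photon
observables a mesh-based transport code would (partial pathlengths,
momentum transfer, survival weight), on a planar layered half-space:

* isotropic scattering similarity walk (g = 0, so ``mus == musp``) with
  exponential step sampling at the local ``musp``;
* pencil beam launched at the origin, pointing into the medium (+z);
* continuous absorption: the survival weight is ``exp(-sum mua_l L_l)``,
  accumulated from the per-layer pathlengths;
* per-layer momentum transfer accumulated as the scattering-event
  count (for an isotropic walk ``E[1 - cos theta] = 1`` per event, so
  the count is the natural estimator of ``sum(1 - cos theta)``);
* unpolarized Fresnel reflection at the top surface (index step
  ``n_in -> n_outside``), internal layer interfaces index-matched;
* Russian roulette below weight 1e-4 with survival factor 10 (the
  roulette compensation is folded into the stored weight, so the
  ``exp(-sum mua L)`` identity holds exactly for every photon that never
  triggered roulette, i.e. all weights >= 1e-3);
* photons escaping the surface inside a detector annulus are recorded.

Everything is reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .history import PhotonHistory
from .volume import N_TISSUES

__all__ = ["Layer", "LayeredMedium", "DetectorRing", "simulate_histories",
           "mean_partial_pathlengths"]

from .history import mean_partial_pathlengths  # noqa: F401  (re-export)

_ROULETTE_WEIGHT = 1e-4
_ROULETTE_SURVIVAL = 10.0
_MAX_STEPS = 10_000_000


@dataclass
class Layer:
    thickness_mm: float          # np.inf for the terminal layer
    mua: float                   # 1/mm
    musp: float                  # 1/mm
    n: float = 1.37

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be positive")
        if self.mua < 0 or self.musp <= 0:
            raise ValueError("need mua >= 0 and musp > 0")


@dataclass
class LayeredMedium:
    layers: list[Layer]
    n_outside: float = 1.0

    def __post_init__(self) -> None:
        if not self.layers or len(self.layers) > N_TISSUES:
            raise ValueError(f"need 1..{N_TISSUES} layers")
        for lay in self.layers[:-1]:
            if np.isinf(lay.thickness_mm):
                raise ValueError("only the last layer may be semi-infinite")
        if not np.isinf(self.layers[-1].thickness_mm):
            raise ValueError("the last layer must be semi-infinite")

    @classmethod
    def homogeneous(cls, mua: float, musp: float, n: float = 1.37,
                    n_outside: float = 1.0) -> "LayeredMedium":
        return cls([Layer(np.inf, mua, musp, n)], n_outside=n_outside)

    def to_json(self, path: str | Path) -> None:
        doc = {"n_outside": self.n_outside,
               "layers": [{"thickness_mm": (None if np.isinf(l.thickness_mm)
                                            else l.thickness_mm),
                           "mua": l.mua, "musp": l.musp, "n": l.n}
                          for l in self.layers]}
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LayeredMedium":
        doc = json.loads(Path(path).read_text())
        layers = [Layer(np.inf if l["thickness_mm"] is None
                        else l["thickness_mm"], l["mua"], l["musp"], l["n"])
                  for l in doc["layers"]]
        return cls(layers, n_outside=doc["n_outside"])


@dataclass
class DetectorRing:
    rho_mm: float                # source-detector separation
    radius_mm: float = 1.0       # capture annulus half-width

    def __post_init__(self) -> None:
        if self.rho_mm <= 0 or self.radius_mm <= 0:
            raise ValueError("rho_mm and radius_mm must be positive")


@njit(cache=False)
def _walk(n_photons, seed, z_top, mua, musp, n_in, n_out,
          rho, halfw, n_det,
          out_det, out_ppath, out_mom, out_weight):  # pragma: no cover
    np.random.seed(seed)
    n_layers = len(mua)
    n_rec = 0
    rel = n_in / n_out           # n_in > n_out -> total internal reflection
    cos_crit2 = 0.0
    if rel > 1.0:
        cos_crit2 = 1.0 - 1.0 / (rel * rel)
    for _ in range(n_photons):
        x = 0.0; y = 0.0; z = 1e-9
        ux = 0.0; uy = 0.0; uz = 1.0
        layer = 0
        ppath = np.zeros(n_layers)
        mom = np.zeros(n_layers)
        logw = 0.0               # log of the absorption survival
        wmult = 1.0              # roulette compensation
        alive = True
        steps = 0
        while alive and steps < _MAX_STEPS:
            steps += 1
            s = -np.log(np.random.random()) / musp[layer]
            while True:
                # distance to the nearest z-boundary of the current layer
                if uz < 0.0:
                    zb = z_top[layer]
                    t = (zb - z) / uz
                elif uz > 0.0:
                    zb = z_top[layer + 1]
                    t = (zb - z) / uz
                else:
                    t = np.inf
                if t >= s:
                    # step completes inside the layer: scatter
                    x += ux * s; y += uy * s; z += uz * s
                    ppath[layer] += s
                    logw -= mua[layer] * s
                    mom[layer] += 1.0
                    cost = 2.0 * np.random.random() - 1.0
                    sint = np.sqrt(1.0 - cost * cost)
                    phi = 2.0 * np.pi * np.random.random()
                    ux = sint * np.cos(phi)
                    uy = sint * np.sin(phi)
                    uz = cost
                    break
                # move to the boundary
                x += ux * t; y += uy * t; z += uz * t
                ppath[layer] += t
                logw -= mua[layer] * t
                if uz < 0.0 and layer == 0:
                    # top surface: Fresnel
                    ci = -uz
                    refl = 1.0
                    if ci * ci > cos_crit2:
                        st2 = (1.0 - ci * ci) * rel * rel
                        ct = np.sqrt(1.0 - st2)
                        rs = (rel * ci - ct) / (rel * ci + ct)
                        rp = (rel * ct - ci) / (rel * ct + ci)
                        refl = 0.5 * (rs * rs + rp * rp)
                    if np.random.random() < refl:
                        uz = -uz
                        z = 1e-12
                        s = -np.log(np.random.random()) / musp[layer]
                        continue
                    # escape: detect?
                    r = np.sqrt(x * x + y * y)
                    for k in range(n_det):
                        if np.abs(r - rho[k]) <= halfw[k]:
                            out_det[n_rec] = k + 1
                            for l in range(n_layers):
                                out_ppath[n_rec, l] = ppath[l]
                                out_mom[n_rec, l] = mom[l]
                            w = wmult * np.exp(logw)
                            if w > 1.0:
                                w = 1.0
                            out_weight[n_rec] = w
                            n_rec += 1
                            break
                    alive = False
                    break
                # internal interface: index-matched, continue in neighbor
                if uz < 0.0:
                    layer -= 1
                else:
                    layer += 1
                z = zb + (1e-12 if uz > 0.0 else -1e-12)
                s = -np.log(np.random.random()) / musp[layer]
            if not alive:
                break
            # Russian roulette on the absorption survival
            if wmult * np.exp(logw) < _ROULETTE_WEIGHT:
                if np.random.random() < 1.0 / _ROULETTE_SURVIVAL:
                    wmult *= _ROULETTE_SURVIVAL
                else:
                    alive = False
    return n_rec


def simulate_histories(medium: LayeredMedium, detectors: list[DetectorRing],
                       n_photons: int, seed: int = 0) -> PhotonHistory:
    """Run the layered random walk and collect detected-photon records.

    Layer ``i`` of the medium maps to tissue column ``i`` of the
    returned :class:`PhotonHistory` (remaining columns stay zero);
    detector ids are 1-based in the order given.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if not detectors:
        raise ValueError("need at least one detector ring")
    n_layers = len(medium.layers)
    z_top = np.zeros(n_layers + 1)
    z_top[1:] = np.cumsum([l.thickness_mm for l in medium.layers])
    mua = np.array([l.mua for l in medium.layers])
    musp = np.array([l.musp for l in medium.layers])
    rho = np.array([d.rho_mm for d in detectors])
    halfw = np.array([d.radius_mm for d in detectors])

    out_det = np.zeros(n_photons, dtype=np.int32)
    out_ppath = np.zeros((n_photons, n_layers))
    out_mom = np.zeros((n_photons, n_layers))
    out_weight = np.zeros(n_photons)
    n_rec = _walk(n_photons, seed, z_top, mua, musp,
                  float(medium.layers[0].n), float(medium.n_outside),
                  rho, halfw, len(detectors),
                  out_det, out_ppath, out_mom, out_weight)

    ppath = np.zeros((n_rec, N_TISSUES))
    mom = np.zeros((n_rec, N_TISSUES))
    ppath[:, :n_layers] = out_ppath[:n_rec]
    mom[:, :n_layers] = out_mom[:n_rec]
    return PhotonHistory(
        det_id=out_det[:n_rec], ppath=ppath, mom=mom,
        weight=out_weight[:n_rec], unit_mm=1.0,
        meta={"n_photons": int(n_photons), "seed": int(seed),
              "n_layers": int(n_layers)})
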