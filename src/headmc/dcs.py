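"""Diffuse correlation spectroscopy post-processing.

From detected-photon histories the normalized field autocorrelation is
estimated with the momentum-transfer estimator

    g1(tau) = sum_p w_p exp(-(1/3) k0^2 sum_t Y_pt <dr_t^2(tau)>) / sum_p w_p

with Brownian dynamics ``<dr^2> = 6 alpha_Db tau`` and ``k0 = 2 pi n /
lambda``.  The forward model for fitting is the semi-infinite
correlation-diffusion Green's function with an extrapolated zero
boundary:

    K(tau)^2 = 3 mua musp' + 6 musp'^2 k0^2 alpha_Db tau
    G1 ~ exp(-K r1)/r1 - exp(-K rb)/rb,
    r1 = sqrt(rho^2 + z0^2),  rb = sqrt(rho^2 + (z0 + 2 zb)^2),
    z0 = 1/musp',  zb = 2/(3 musp') (1 + Reff)/(1 - Reff),

normalized to 1 at tau = 0.  ``Reff`` follows the standard polynomial
approximation in the relative refractive index.  Intensity correlations
follow the Siegert relation ``g2 = 1 + beta g1^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .history import PhotonHistory
from .optics import TissueOptics

__all__ = ["CorrelationCurve", "DcsFitResult", "compute_g1", "siegert_g2",
           "semi_infinite_g1", "fit_dcs", "default_tau_grid"]

DEFAULT_TAU_RANGE_S = (1e-7, 1e-2)
DEFAULT_FIT_WINDOW_S = (1e-7, 1e-3)
DEFAULT_BETA = 0.5
_ALPHA_STARTS = (1e-7, 1e-6, 1e-5)  # mm^2/s


def default_tau_grid(n: int = 50) -> np.ndarray:
    """50 log-spaced lags covering typical scalp/brain decay at 785 nm."""
    return np.logspace(np.log10(DEFAULT_TAU_RANGE_S[0]),
                       np.log10(DEFAULT_TAU_RANGE_S[1]), n)


@dataclass
class CorrelationCurve:
    tau_s: np.ndarray
    g1: np.ndarray
    g2: np.ndarray | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        self.tau_s = np.asarray(self.tau_s, dtype=float)
        self.g1 = np.asarray(self.g1, dtype=float)
        if np.any(np.diff(self.tau_s) <= 0):
            raise ValueError("tau grid must be strictly increasing")
        if np.any(self.tau_s < 0):
            raise ValueError("lags must be non-negative")
        if self.g2 is not None:
            self.g2 = np.asarray(self.g2, dtype=float)

    def to_csv(self, path: str | Path) -> None:
        cols = [self.tau_s, self.g1]
        header = "tau_s,g1"
        if self.g2 is not None:
            cols.append(self.g2)
            header += ",g2"
        np.savetxt(path, np.column_stack(cols), delimiter=",",
                   header=header, comments="", fmt="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationCurve":
        with open(path) as f:
            names = f.readline().strip().split(",")
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        kw = {"tau_s": data[:, 0], "g1": data[:, names.index("g1")]}
        if "g2" in names:
            kw["g2"] = data[:, names.index("g2")]
        return cls(**kw)


@dataclass
class DcsFitResult:
    alpha_Db: float              # mm^2/s
    beta: float
    residual_rms: float
    converged: bool
    tau_window: tuple[float, float]
    n_points: int = 0


def compute_g1(hist: PhotonHistory, optics: TissueOptics,
               wavelength_nm: float, tau_s: np.ndarray) -> CorrelationCurve:
    """Momentum-transfer estimate of g1(tau) from a photon history.

    Per-tissue Brownian dynamics come from ``optics.alpha_Db``; static
    tissues (alpha_Db = 0) contribute nothing to the decay.  g1(0) = 1
    exactly by normalization.
    """
    if len(hist) == 0:
        raise ValueError("empty photon history")
    if np.any(optics.alpha_Db < 0):
        raise ValueError("alpha_Db must be >= 0")
    tau = np.asarray(tau_s, dtype=float)
    k0 = 2 * np.pi * optics.n[0] / (wavelength_nm * 1e-6)  # 1/mm
    # exponent rate per photon: (1/3) k0^2 sum_t Y_t * 6 alpha_t  [1/s]
    rate = 2.0 * k0**2 * (hist.mom * optics.alpha_Db[None, :]).sum(axis=1)
    w = hist.weight
    g1 = (w[None, :] * np.exp(-np.outer(tau, rate))).sum(axis=1) / w.sum()
    return CorrelationCurve(tau_s=tau, g1=g1)


def siegert_g2(curve: CorrelationCurve, beta: float) -> CorrelationCurve:
    """Intensity autocorrelation via the Siegert relation g2 = 1 + beta g1^2."""
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    return CorrelationCurve(tau_s=curve.tau_s, g1=curve.g1,
                            g2=1.0 + beta * curve.g1**2, beta=beta)


def _effective_reflection_coefficient(n_rel: float) -> float:
    # polynomial approximation in the relative refractive index
    return -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel


def _semi_infinite_G1(rho_mm, tau_s, mua, musp, n, wavelength_nm, alpha_Db,
                      n_outside=1.0):
    k0 = 2 * np.pi * n / (wavelength_nm * 1e-6)
    K = np.sqrt(3 * mua * musp + 6 * musp**2 * k0**2 * alpha_Db * tau_s)
    z0 = 1.0 / musp
    Reff = _effective_reflection_coefficient(n / n_outside)
    zb = (2.0 / (3.0 * musp)) * (1 + Reff) / (1 - Reff)
    r1 = np.sqrt(rho_mm**2 + z0**2)
    rb = np.sqrt(rho_mm**2 + (z0 + 2 * zb)**2)
    return np.exp(-K * r1) / r1 - np.exp(-K * rb) / rb


def semi_infinite_g1(rho_mm: float, tau_s: np.ndarray, mua: float, musp: float,
                     n: float, wavelength_nm: float, alpha_Db: float,
                     n_outside: float = 1.0) -> CorrelationCurve:
    """Normalized semi-infinite correlation-diffusion solution g1(tau)."""
    if musp <= 0 or rho_mm <= 0:
        raise ValueError("need musp > 0 and rho_mm > 0")
    if mua < 0 or alpha_Db < 0:
        raise ValueError("need mua >= 0 and alpha_Db >= 0")
    tau = np.asarray(tau_s, dtype=float)
    G = _semi_infinite_G1(rho_mm, tau, mua, musp, n, wavelength_nm, alpha_Db,
                          n_outside)
    G0 = _semi_infinite_G1(rho_mm, 0.0, mua, musp, n, wavelength_nm, alpha_Db,
                           n_outside)
    return CorrelationCurve(tau_s=tau, g1=G / G0)


def fit_dcs(curve: CorrelationCurve, rho_mm: float, mua: float, musp: float,
            n: float, wavelength_nm: float, fit_beta: bool = False,
            tau_window: tuple[float, float] = DEFAULT_FIT_WINDOW_S,
            beta: float = DEFAULT_BETA) -> DcsFitResult:
    """Least-squares fit of the semi-infinite model to a measured curve.

    Fits ``alpha_Db >= 0`` (log-parameterized, multi-start) against g1;
    with ``fit_beta`` the model ``1 + beta g1^2`` is fitted against the
    curve's g2 and beta is estimated jointly.  Never raises on
    non-convergence; the ``converged`` flag is honest.
    """
    lo, hi = tau_window
    m = (curve.tau_s >= lo) & (curve.tau_s <= hi)
    if m.sum() < 10:
        raise ValueError(f"need >= 10 lags inside tau_window {tau_window}, "
                         f"have {int(m.sum())}")
    tau = curve.tau_s[m]
    if fit_beta:
        if curve.g2 is None:
            raise ValueError("fit_beta requires a curve with g2")
        target = curve.g2[m]
    else:
        target = curve.g1[m]

    def model(theta):
        a = 10.0 ** theta[0]
        g1 = semi_infinite_g1(rho_mm, tau, mua, musp, n, wavelength_nm, a).g1
        if fit_beta:
            return 1.0 + theta[1] * g1**2
        return g1

    best = None
    for a0 in _ALPHA_STARTS:
        x0 = [np.log10(a0)] + ([beta] if fit_beta else [])
        bounds = ([-12] + ([1e-6] if fit_beta else []),
                  [0] + ([1.0] if fit_beta else []))
        try:
            res = least_squares(lambda th: model(th) - target, x0,
                                bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return DcsFitResult(alpha_Db=np.nan, beta=beta, residual_rms=np.inf,
                            converged=False, tau_window=tau_window,
                            n_points=int(m.sum()))
    alpha = float(10.0 ** best.x[0])
    beta_out = float(best.x[1]) if fit_beta else beta
    rms = float(np.sqrt(2 * best.cost / len(tau)))
    return DcsFitResult(alpha_Db=alpha, beta=beta_out, residual_rms=rms,
                        converged=bool(best.success), tau_window=tau_window,
                        n_points=int(m.sum()))
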