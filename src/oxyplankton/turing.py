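"""Linear spatial stability of a homogeneous coexistence state.

Perturbing a spatially uniform coexistence state with a mode ``cos(kx)``
turns the temporal characteristic polynomial into a k-dependent cubic

    lam^3 + p2(k^2) lam^2 + p1(k^2) lam + p0(k^2) = 0,

whose coefficients follow from the Jacobian J of the temporal model (the
third row carrying the epsilon factor) and the diffusivity matrix
diag(1, 1, D): oxygen and phytoplankton ride the same turbulent
diffusivity while zooplankton self-motion gives a ratio D != 1.  Turing
instability requires temporal stability (p2(0) > 0, p0(0) > 0,
p1(0) p2(0) > p0(0)) together with p0(k^2) < 0 for some k; the critical
wavenumber where p0 first touches zero has the closed form

    kT^2 = (J11 + J22)/3 + (J33 + sqrt(Lambda)) / (3 D),

with a discriminant Lambda quadratic in D.  The closed form is always
cross-checked against direct numerical minimization of p0 over k^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .model import ModelParams, jacobian, rhs
from .equilibria import routh_hurwitz

__all__ = [
    "DispersionData",
    "dispersion",
    "p0_of_k2",
    "critical_wavenumber",
    "turing_check",
]


@dataclass
class DispersionData:
    k2_grid: np.ndarray
    p2: np.ndarray
    p1: np.ndarray
    p0: np.ndarray
    max_re_lambda: np.ndarray
    kT2: Optional[float]  # None when no real positive critical wavenumber
    Lambda: float
    D: float

    def to_csv(self, path: str):
        import pandas as pd

        pd.DataFrame({"k2": self.k2_grid, "p2": self.p2, "p1": self.p1,
                      "p0": self.p0, "max_re_lambda": self.max_re_lambda}
                     ).to_csv(path, index=False)


def _check_equilibrium(equilibrium, p: ModelParams) -> np.ndarray:
    z = np.asarray(equilibrium, dtype=float)
    if np.any(z[:3] <= 0) or np.max(np.abs(rhs(z, p))) > 1e-9:
        raise ValueError("dispersion analysis requires a coexistence equilibrium "
                         "(all components positive, residual < 1e-9)")
    return z


def _coefficients(J: np.ndarray, D: float, k2):
    """p2, p1, p0 as polynomials in k^2 (vectorized over k2)."""
    J11, J22, J33 = J[0, 0], J[1, 1], J[2, 2]
    tr = J11 + J22 + J33
    M1 = J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1]  # cofactor of J11
    M2 = J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
    M3 = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    det = np.linalg.det(J)
    k2 = np.asarray(k2, dtype=float)
    p2 = (2.0 + D) * k2 - tr
    p1 = (1.0 + 2.0 * D) * k2 ** 2 \
        - ((J22 + J33) + (J11 + J33) + D * (J11 + J22)) * k2 \
        + (M1 + M2 + M3)
    p0 = D * k2 ** 3 - ((J11 + J22) * D + J33) * k2 ** 2 \
        + (M1 + M2 + M3 * D) * k2 - det
    return p2, p1, p0


def p0_of_k2(params_or_J, D: float, equilibrium=None):
    """Constant-term coefficient p0 as a function of k^2 (scalar callable)."""
    if isinstance(params_or_J, ModelParams):
        z = _check_equilibrium(equilibrium, params_or_J)
        J = jacobian(z, params_or_J)
    else:
        J = np.asarray(params_or_J)

    def f(k2):
        return float(_coefficients(J, D, k2)[2])

    return f


def dispersion(p: ModelParams, D: float, equilibrium,
               k2_grid: Optional[np.ndarray] = None) -> DispersionData:
    """Dispersion relation of the linearized reaction-diffusion system.

    ``max_re_lambda`` is the largest real part among the roots of the
    k-dependent cubic at each grid point.  The default grid is 2000
    log-spaced values of k^2 on [1e-4, 10].
    """
    if D <= 0:
        raise ValueError("diffusivity ratio D must be positive")
    z = _check_equilibrium(equilibrium, p)
    J = jacobian(z, p)
    if k2_grid is None:
        k2_grid = np.logspace(-4, 1, 2000)
    p2, p1, p0 = _coefficients(J, D, k2_grid)
    mre = np.empty_like(k2_grid)
    for i, (a2, a1, a0) in enumerate(zip(p2, p1, p0)):
        mre[i] = np.max(np.roots([1.0, a2, a1, a0]).real)
    kT2, Lam = _closed_form_kT2(J, D)
    # keep kT2 only when it marks a genuine zero/negative excursion of p0
    if kT2 is not None:
        p0_at = _coefficients(J, D, kT2)[2]
        if not (p0_at <= 1e-8):
            kT2 = None
    return DispersionData(k2_grid=k2_grid, p2=p2, p1=p1, p0=p0,
                          max_re_lambda=mre, kT2=kT2, Lambda=Lam, D=D)


def _closed_form_kT2(J: np.ndarray, D: float):
    J11, J22, J33 = J[0, 0], J[1, 1], J[2, 2]
    Lam = (J11 ** 2 + J22 ** 2 - J11 * J22 + 3.0 * J[0, 1] * J[1, 0]) * D ** 2 \
        + D * (3.0 * J[0, 2] * J[2, 0] + 3.0 * J[1, 2] * J[2, 1]
               - J11 * J33 - J22 * J33) + J33 ** 2
    if Lam < 0:
        return None, float(Lam)
    kT2 = (J11 + J22) / 3.0 + (J33 + np.sqrt(Lam)) / (3.0 * D)
    if not (np.isfinite(kT2) and kT2 > 0):
        return None, float(Lam)
    return float(kT2), float(Lam)


def critical_wavenumber(p: ModelParams, D: float, equilibrium,
                        cross_check_tol: float = 1e-6) -> Optional[float]:
    """kT^2 from the closed form, cross-validated against numerical
    minimization of p0 over k^2 in (0, 10].

    Returns None when the discriminant is negative, kT^2 is not a
    positive real, or p0(kT^2) is not <= 1e-8 (no instability).  If the
    closed form and the numerical minimizer disagree beyond
    ``cross_check_tol`` the numerical minimizer is preferred.
    """
    z = _check_equilibrium(equilibrium, p)
    J = jacobian(z, p)
    kT2, _ = _closed_form_kT2(J, D)
    if kT2 is None or kT2 > 10.0:
        return None
    f = p0_of_k2(J, D)
    if f(kT2) > 1e-8:
        return None
    res = minimize_scalar(f, bounds=(1e-6, 10.0), method="bounded",
                          options={"xatol": 1e-12})
    if abs(res.x - kT2) > cross_check_tol:
        return float(res.x)
    return kT2


def turing_check(p: ModelParams, D: float, equilibrium) -> str:
    """'turing', 'turing_hopf' or 'none'.

    'turing': the uniform state is temporally stable but some k-mode has
    p0(k^2) < 0.  'turing_hopf': a k-mode is unstable while the temporal
    Routh-Hurwitz conditions already fail (spatio-temporal interplay).
    """
    z = _check_equilibrium(equilibrium, p)
    J = jacobian(z, p)
    p0t, p1t, p2t = routh_hurwitz(J)
    temporal_ok = (p2t > 0) and (p0t > 0) and (p1t * p2t > p0t)
    f = p0_of_k2(J, D)
    res = minimize_scalar(f, bounds=(1e-6, 10.0), method="bounded")
    spatial_unstable = res.fun < 0
    if spatial_unstable and temporal_ok:
        return "turing"
    if spatial_unstable and not temporal_ok:
        return "turing_hopf"
    return "none"
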