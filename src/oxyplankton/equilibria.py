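"""Steady states of the temporal model and their linear stability.

Three families of equilibria exist:

* the total-extinction state ``E0 = (0, 0, 0)``, always stable;
* zooplankton-free states ``(cbar, ubar, 0)`` where ``cbar`` solves a
  quartic in the oxygen level and ``ubar`` follows from a rational formula
  (these are independent of the mortality rates and of epsilon);
* coexistence states ``(c*, u*, v*)`` with all components positive, found
  numerically from ``F = G = H = 0``.

Stability is classified both through the eigenvalues of the analytic
Jacobian and through the Routh-Hurwitz coefficients ``(p0, p1, p2)`` of
the characteristic polynomial ``lam^3 + p2 lam^2 + p1 lam + p0``; the two
verdicts must agree and are cross-checked in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import optimize

from .model import ModelParams, H, jacobian, rhs

__all__ = [
    "Equilibrium",
    "MarginalEquilibriumError",
    "DegenerateEquilibriumError",
    "quartic_coefficients",
    "ubar_from_cbar",
    "find_extinction",
    "find_zooplankton_free",
    "find_coexistence",
    "classify",
    "routh_hurwitz",
    "saddle_node_mu2",
    "equilibria_table",
]

RESIDUAL_TOL = 1e-9


class MarginalEquilibriumError(RuntimeError):
    """An eigenvalue real part is numerically zero: a bifurcation point."""


class DegenerateEquilibriumError(RuntimeError):
    """mu1 = mu2 = 0 makes H proportional to v: coexistence roots not isolated."""


@dataclass
class Equilibrium:
    """A steady state together with its linearization summary."""

    coords: np.ndarray
    kind: str  # extinction | zooplankton_free | coexistence
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(3, complex))
    rh: tuple = (np.nan, np.nan, np.nan)  # (p0, p1, p2)
    stability: str = ""  # stable | saddle | unstable

    @property
    def c(self) -> float:
        return float(self.coords[0])

    @property
    def u(self) -> float:
        return float(self.coords[1])

    @property
    def v(self) -> float:
        return float(self.coords[2])


def routh_hurwitz(J: np.ndarray) -> tuple:
    """(p0, p1, p2) of ``lam^3 + p2 lam^2 + p1 lam + p0 = det(lam I - J)``.

    p2 = -tr(J), p1 = sum of principal 2x2 minors, p0 = -det(J).
    """
    p2 = -np.trace(J)
    p1 = (
        J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1]
        + J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
        + J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    )
    p0 = -np.linalg.det(J)
    return (float(p0), float(p1), float(p2))


def classify(coords, p: ModelParams, kind: str = "coexistence",
             marginal_tol: float = 1e-8, on_marginal: str = "raise") -> Equilibrium:
    """Fill in eigenvalues, Routh-Hurwitz coefficients and a stability label.

    ``coords`` must already satisfy the equilibrium conditions to 1e-6.
    If some eigenvalue has ``|Re| < marginal_tol`` the point sits on a
    bifurcation; with ``on_marginal='raise'`` (default) this raises
    :class:`MarginalEquilibriumError`, with ``'label'`` the stability is
    reported as ``'marginal'``.
    """
    z = np.asarray(coords, dtype=float)
    if np.max(np.abs(rhs(z, p))) > 1e-6:
        raise ValueError(f"point {z} is not an equilibrium (residual > 1e-6)")
    J = jacobian(z, p)
    ev = np.linalg.eigvals(J)
    re = ev.real
    if np.min(np.abs(re)) < marginal_tol:
        if on_marginal == "raise":
            raise MarginalEquilibriumError(
                f"eigenvalue with |Re| < {marginal_tol} at {z}: bifurcation point")
        stability = "marginal"
    elif np.all(re < 0):
        stability = "stable"
    elif np.all(re > 0):
        stability = "unstable"
    else:
        stability = "saddle"
    return Equilibrium(coords=z, kind=kind, eigenvalues=ev,
                       rh=routh_hurwitz(J), stability=stability)


def find_extinction(p: ModelParams) -> Equilibrium:
    """The total-extinction state E0 = (0,0,0)."""
    return classify(np.zeros(3), p, kind="extinction", on_marginal="label")


# ---------------------------------------------------------------------------
# zooplankton-free states
# ---------------------------------------------------------------------------

def quartic_coefficients(p: ModelParams) -> np.ndarray:
    """Coefficients (highest order first) of the quartic whose positive roots
    are the oxygen components of the zooplankton-free equilibria."""
    A, B, s, c1, c2, d = p.A, p.B, p.sigma, p.c1, p.c2, p.delta
    return np.array([
        1.0,
        -(d * (s - B) - (c1 + c2 + 1.0)),
        -(A * (B - s) + (d * s - c2 - 1.0) * c1 - B * d + d * s - c2),
        -(((B - s) * c2 - s * c1) * A + d * s * c1 - c1 * c2),
        A * s * c1 * c2,
    ])


def ubar_from_cbar(cbar: float, p: ModelParams) -> float:
    """Phytoplankton level accompanying a zooplankton-free oxygen root."""
    return (cbar * (p.B - p.sigma) - p.c1 * p.sigma) / (cbar + p.c1)


def find_zooplankton_free(p: ModelParams) -> List[Equilibrium]:
    """All feasible states ``(cbar, ubar, 0)``, sorted by the oxygen level.

    Real positive quartic roots with positive ``ubar`` are polished by a
    2-D Newton iteration on ``(F, G)`` restricted to the ``v = 0`` plane,
    so that small inaccuracies in the quartic coefficients cannot
    propagate.  Independent of mu1, mu2 and epsilon by construction.
    """
    if p.B < p.sigma:
        return []  # ubar < 0 for every cbar > 0
    roots = np.roots(quartic_coefficients(p))
    out: List[Equilibrium] = []
    for r in roots:
        if abs(r.imag) > 1e-9 or r.real <= 0:
            continue
        cbar = float(r.real)
        ubar = ubar_from_cbar(cbar, p)
        if ubar <= 0:
            continue
        sol = optimize.root(
            lambda x: rhs(np.array([x[0], x[1], 0.0]), p)[:2], [cbar, ubar], tol=1e-13)
        if not sol.success:
            continue
        cbar, ubar = sol.x
        eq = classify(np.array([cbar, ubar, 0.0]), p,
                      kind="zooplankton_free", on_marginal="label")
        if not any(abs(e.c - cbar) < 1e-8 for e in out):
            out.append(eq)
    out.sort(key=lambda e: e.c)
    return out


# ---------------------------------------------------------------------------
# coexistence states
# ---------------------------------------------------------------------------

def _v_elimination(c: float, u: float, p: ModelParams) -> float:
    """v* from H = 0 when mu2 > 0 (divides by mu2)."""
    g = p.eta * c * c / (c * c + p.c4 * p.c4) * u / (u + p.h)
    return (g - p.mu1) / p.mu2


def find_coexistence(p: ModelParams, grid: int = 40,
                     c_range=(0.05, 5.0), u_range=(0.05, 5.0),
                     dedupe_tol: float = 1e-7) -> List[Equilibrium]:
    """All distinct admissible roots of ``F = G = H = 0`` with c,u,v > 0.

    A ``grid x grid`` multi-start in the (c, u) plane seeds a 3-D Newton
    iteration; for mu2 > 0 the zooplankton seed comes from the explicit
    elimination of v in H = 0, for mu2 = 0 a small set of v seeds is used
    instead.  Duplicates are merged at Euclidean tolerance ``dedupe_tol``
    and strict positivity (> 1e-10) is required of every component.
    """
    if p.mu1 == 0.0 and p.mu2 == 0.0:
        raise DegenerateEquilibriumError(
            "with mu1 = mu2 = 0, H = v * g(c, u) and coexistence roots are not isolated")

    def sys3(x):
        c, u, v = x
        return [
            rhs(np.array([max(c, 0.0), max(u, 0.0), max(v, 0.0)]), p)[0],
            rhs(np.array([max(c, 0.0), max(u, 0.0), max(v, 0.0)]), p)[1],
            H(max(c, 0.0), max(u, 0.0), max(v, 0.0), p),
        ]

    found: List[np.ndarray] = []
    cs = np.linspace(c_range[0], c_range[1], grid)
    us = np.linspace(u_range[0], u_range[1], grid)
    for c0 in cs:
        for u0 in us:
            if p.mu2 > 0:
                v0 = _v_elimination(c0, u0, p)
                if v0 <= 0:
                    continue
                seeds = [v0]
            else:
                seeds = [0.2, 0.8, 2.0]
            for v0 in seeds:
                sol = optimize.root(sys3, [c0, u0, v0], tol=1e-13)
                if not sol.success:
                    continue
                x = sol.x
                if np.any(x <= 1e-10):
                    continue
                if np.max(np.abs(sys3(x))) > RESIDUAL_TOL:
                    continue
                if not any(np.linalg.norm(x - y) < dedupe_tol for y in found):
                    found.append(x)
    found.sort(key=lambda x: x[0])
    return [classify(x, p, kind="coexistence", on_marginal="label") for x in found]


def saddle_node_mu2(p: ModelParams, bracket=(0.005, 0.05), tol: float = 1e-6,
                    grid: int = 25) -> float:
    """Saddle-node threshold mu2_SL of the coexistence pair (mu1 = 0 branch):
    below it no coexistence state is feasible, above it two exist.  Located
    by bisection on the count of :func:`find_coexistence` results; the
    search window is refined toward small (c, u) because the colliding
    roots sit at low oxygen and plankton levels."""

    def n_coex(mu2: float) -> int:
        return len(find_coexistence(p.replace(mu2=mu2), grid=grid,
                                    c_range=(0.005, 2.0), u_range=(0.002, 2.0)))

    lo, hi = bracket
    if n_coex(lo) != 0 or n_coex(hi) < 2:
        raise ValueError("bracket does not straddle the saddle-node of coexistence states")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if n_coex(mid) == 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def equilibria_table(eqs: Sequence[Equilibrium], path: Optional[str] = None):
    """Tabulate equilibria (CSV columns: kind, coordinates, eigenvalues,
    Routh-Hurwitz coefficients, stability).  Returns the DataFrame."""
    import pandas as pd

    rows = []
    for e in eqs:
        ev = np.asarray(e.eigenvalues, dtype=complex)
        rows.append({
            "kind": e.kind, "c": e.c, "u": e.u, "v": e.v,
            "re_l1": ev[0].real, "re_l2": ev[1].real, "re_l3": ev[2].real,
            "im_l1": ev[0].imag, "im_l2": ev[1].imag, "im_l3": ev[2].imag,
            "p0": e.rh[0], "p1": e.rh[1], "p2": e.rh[2],
            "stability": e.stability,
        })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
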