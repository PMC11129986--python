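"""Slow-fast decomposition: fast subsystem, critical manifold, fold point.

For small epsilon the zooplankton density v is a slow variable.  Freezing
``v = v0`` gives the planar fast subsystem in (c, u); its equilibria swept
over v0 trace the critical manifold

    C0 = {(c,u,v) : F = 0 and G = 0} = C0^0  U  C0^1,

where ``C0^0`` is the trivial line {c = u = 0} (always attracting) and
``C0^1`` is the nontrivial curve carrying at most two fast equilibria per
v0 slice: a saddle (low u, the repelling sheet) and a stable node/focus
(high u, the attracting sheet), which merge in a saddle-node of the fast
subsystem.  That saddle-node is the *fold* of the critical manifold; the
reduced (slow) flow on the manifold is singular there, and the fold is a
jump point or a canard point according to whether the discriminants
``d1 = Fv*Gu - Fu*Gv`` and ``d2 = Fv*Gc - Fc*Gv`` vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import optimize

from .model import ModelParams, F, G, partials, rhs_unscaled_H

__all__ = [
    "FastSlice",
    "FoldPoint",
    "CriticalManifold",
    "NoFoldError",
    "SingularSlowFlowError",
    "oxygen_nullcline_u",
    "fast_equilibria",
    "fold_point",
    "classify_fold",
    "build_manifold",
    "slow_flow",
]

C_MAX = 20.0  # upper bound of the oxygen scan; dynamics live in c ~ [0, 2]


class NoFoldError(RuntimeError):
    """The fast-equilibrium count never drops from two to zero in v0."""


class SingularSlowFlowError(RuntimeError):
    """The reduced flow is evaluated at (or numerically on top of) the fold."""


@dataclass
class FastSlice:
    """Interior equilibria of the frozen-v0 fast subsystem with stability."""

    v0: float
    equilibria: List[np.ndarray]  # (c, u) pairs sorted by u
    stability: List[str]  # 'saddle' | 'stable' | 'unstable' per point


@dataclass
class FoldPoint:
    c_s: float
    u_s: float
    v_s: float
    H_value: float  # unscaled H at the fold (depends on mu1, mu2)
    d1: float  # Fv*Gu - Fu*Gv
    d2: float  # Fv*Gc - Fc*Gv
    classification: str  # 'jump' | 'canard'

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.c_s, self.u_s, self.v_s])


@dataclass
class CriticalManifold:
    """Sampled nontrivial branch C0^1 plus a record of the trivial line C0^0."""

    samples: np.ndarray  # (n, 3) rows (c, u, v0), ordered along the curve
    branch: List[str]  # 'attracting' | 'repelling' per sample
    fold: FoldPoint
    trivial_v: np.ndarray  # v grid of the C0^0 record
    trivial_eigs: np.ndarray  # (n, 2): [-1 - nu v/c3, -v/h - sigma]


# ---------------------------------------------------------------------------
# fast subsystem
# ---------------------------------------------------------------------------

def oxygen_nullcline_u(c: float, v0: float, p: ModelParams) -> float:
    """Explicit u(c) on the oxygen nullcline F(c, u, v0) = 0."""
    num = c * (1.0 + c) * (c + p.c2) * (c + p.c3 + p.nu * v0)
    den = (c + p.c3) * (p.A * (c + p.c2) - p.delta * c * (1.0 + c))
    return num / den


def _fast_jacobian(c: float, u: float, v0: float, p: ModelParams) -> np.ndarray:
    d = partials(np.array([c, u, v0]), p)
    return np.array([[d["Fc"], d["Fu"]], [d["Gc"], d["Gu"]]])


def fast_equilibria(v0: float, p: ModelParams, c_max: float = C_MAX,
                    n_scan: int = 4000) -> FastSlice:
    """Interior equilibria of the fast subsystem at frozen zooplankton v0.

    The explicit oxygen nullcline u(c) is substituted into G = 0 and the
    resulting scalar function of c is scanned for sign changes on
    (0, c_max]; each bracket is refined by Brent's method and polished by
    a 2-D Newton iteration on (F, G).  Stability comes from the 2x2 fast
    Jacobian.
    """
    if v0 < 0:
        raise ValueError("v0 must be non-negative")
    # restrict the scan to where the nullcline denominator is positive
    cs = np.linspace(1e-6, c_max, n_scan)
    den = (cs + p.c3) * (p.A * (cs + p.c2) - p.delta * cs * (1.0 + cs))
    valid = den > 1e-12

    def g_of_c(c):
        u = oxygen_nullcline_u(c, v0, p)
        return G(c, u, v0, p)

    vals = np.full(n_scan, np.nan)
    u_null = oxygen_nullcline_u(cs[valid], v0, p)
    vals[valid] = G(cs[valid], u_null, v0, p)
    roots: List[np.ndarray] = []
    for i in range(n_scan - 1):
        a, b = vals[i], vals[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)) or a * b > 0:
            continue
        c_root = optimize.brentq(g_of_c, cs[i], cs[i + 1], xtol=1e-13)
        u_root = oxygen_nullcline_u(c_root, v0, p)
        sol = optimize.root(
            lambda x: [F(x[0], x[1], v0, p), G(x[0], x[1], v0, p)],
            [c_root, u_root], tol=1e-13)
        if not sol.success:
            continue
        c_r, u_r = sol.x
        if u_r <= 1e-10 or c_r <= 1e-10:
            continue
        if not any(abs(c_r - r[0]) < 1e-8 for r in roots):
            roots.append(np.array([c_r, u_r]))
    roots.sort(key=lambda r: r[1])
    stab = []
    for c_r, u_r in roots:
        ev = np.linalg.eigvals(_fast_jacobian(c_r, u_r, v0, p))
        re = ev.real
        if np.all(re < 0):
            stab.append("stable")
        elif np.all(re > 0):
            stab.append("unstable")
        else:
            stab.append("saddle")
    return FastSlice(v0=float(v0), equilibria=roots, stability=stab)


# ---------------------------------------------------------------------------
# fold point
# ---------------------------------------------------------------------------

def _det_fast(c, u, v, p: ModelParams) -> float:
    d = partials(np.array([c, u, v]), p)
    return d["Fc"] * d["Gu"] - d["Fu"] * d["Gc"]


def fold_point(p: ModelParams, v0_hi: float = 10.0, tol: float = 1e-9) -> FoldPoint:
    """The saddle-node of the fast subsystem = fold of the critical manifold.

    v0 is bisected on the interior-equilibrium count (2 -> 0) to seed a
    3-D Newton solve of ``F = 0, G = 0, det(J_fast) = 0``; residuals at the
    returned point are below ``tol``.  ``H_value`` is evaluated with the
    mortality rates carried by ``p``.
    """
    lo, hi = 0.0, v0_hi
    if len(fast_equilibria(lo, p).equilibria) < 2:
        raise NoFoldError("no two-equilibria slice at v0 = 0")
    if len(fast_equilibria(hi, p).equilibria) >= 2:
        raise NoFoldError(f"fast equilibria persist at v0 = {v0_hi}")
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if len(fast_equilibria(mid, p).equilibria) >= 2:
            lo = mid
        else:
            hi = mid
    slice_lo = fast_equilibria(lo, p)
    c0, u0 = np.mean([e for e in slice_lo.equilibria], axis=0)

    def sys3(x):
        c, u, v = x
        return [F(c, u, v, p), G(c, u, v, p), _det_fast(c, u, v, p)]

    sol = optimize.root(sys3, [c0, u0, 0.5 * (lo + hi)], tol=1e-14)
    if np.max(np.abs(sys3(sol.x))) > tol:
        raise NoFoldError(f"Newton failed to converge on the fold ({sol.message})")
    c_s, u_s, v_s = sol.x
    d = partials(sol.x, p)
    d1 = d["Fv"] * d["Gu"] - d["Fu"] * d["Gv"]
    d2 = d["Fv"] * d["Gc"] - d["Fc"] * d["Gv"]
    fp = FoldPoint(c_s=float(c_s), u_s=float(u_s), v_s=float(v_s),
                   H_value=rhs_unscaled_H(sol.x, p), d1=float(d1), d2=float(d2),
                   classification="")
    fp.classification = classify_fold(fp, p)
    return fp


def classify_fold(fold: FoldPoint, p: ModelParams, tol: float = 1e-6) -> str:
    """'canard' iff both discriminants d1 and d2 vanish below ``tol``,
    else 'jump' (the generic case: the slow trajectory leaves the fold
    along a fast fiber)."""
    d = partials(fold.coords, p)
    d1 = d["Fv"] * d["Gu"] - d["Fu"] * d["Gv"]
    d2 = d["Fv"] * d["Gc"] - d["Fc"] * d["Gv"]
    return "canard" if (abs(d1) < tol and abs(d2) < tol) else "jump"


# ---------------------------------------------------------------------------
# critical manifold
# ---------------------------------------------------------------------------

def build_manifold(p: ModelParams, v0_grid: Optional[np.ndarray] = None,
                   n_grid: int = 400) -> CriticalManifold:
    """Sample C0^1 over a v0 grid and label the attracting/repelling sheets.

    The default grid has ``n_grid`` uniform points on [0, 1.1 v_s] with a
    tenfold density refinement over the final 5 percent before the fold,
    where the two sheets approach each other.  The trivial branch C0^0 is
    recorded with its exact eigenvalues ``-1 - nu v / c3`` and
    ``-v/h - sigma`` (negative for all v >= 0).
    """
    fp = fold_point(p)
    if v0_grid is None:
        base = np.linspace(0.0, 1.1 * fp.v_s, n_grid)
        fine = np.linspace(0.95 * fp.v_s, fp.v_s, int(0.05 * n_grid * 10))
        v0_grid = np.unique(np.concatenate([base, fine]))
    samples = []
    branch = []
    for v0 in v0_grid:
        sl = fast_equilibria(v0, p)
        for (c, u) in sl.equilibria:
            samples.append([c, u, v0])
            branch.append("attracting" if u > fp.u_s else "repelling")
    samples = np.array(samples)
    # order along the curve: repelling sheet by ascending u then attracting
    order = np.lexsort((samples[:, 2], samples[:, 1]))
    samples = samples[order]
    branch = [branch[i] for i in order]
    tv = np.linspace(0.0, 1.1 * fp.v_s, 50)
    te = np.column_stack([-1.0 - p.nu * tv / p.c3, -tv / p.h - p.sigma])
    return CriticalManifold(samples=samples, branch=branch, fold=fp,
                            trivial_v=tv, trivial_eigs=te)


def manifold_table(m: CriticalManifold, path: Optional[str] = None):
    import pandas as pd

    df = pd.DataFrame({"v0": m.samples[:, 2], "c": m.samples[:, 0],
                       "u": m.samples[:, 1], "branch": m.branch})
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# reduced (slow) flow on the manifold
# ---------------------------------------------------------------------------

def slow_flow(point, p: ModelParams, singular_tol: float = 1e-10) -> np.ndarray:
    """Reduced dynamics (dc/dtau, du/dtau, dv/dtau) on C0^1.

    Obtained by implicit differentiation of F = 0, G = 0 along the
    manifold::

        dc/dtau = -(Fv Gu - Fu Gv) / (Fc Gu - Fu Gc) * H
        du/dtau = -(Fv Gc - Fc Gv) / (Gc Fu - Gu Fc) * H
        dv/dtau = H

    Raises :class:`SingularSlowFlowError` when the denominator
    ``Fc Gu - Fu Gc`` (the fast-subsystem determinant) vanishes -- the
    fold, where the reduced solution blows up.
    """
    z = np.asarray(point, dtype=float)
    c, u, v = z
    if max(abs(F(c, u, v, p)), abs(G(c, u, v, p))) > 1e-8:
        raise ValueError(f"{z} is not on the critical manifold (|F|,|G| > 1e-8)")
    d = partials(z, p)
    den = d["Fc"] * d["Gu"] - d["Fu"] * d["Gc"]
    if abs(den) < singular_tol:
        raise SingularSlowFlowError("fold point: reduced flow is singular")
    Hv = rhs_unscaled_H(z, p)
    dc = -(d["Fv"] * d["Gu"] - d["Fu"] * d["Gv"]) / den * Hv
    du = -(d["Fv"] * d["Gc"] - d["Fc"] * d["Gv"]) / (-den) * Hv
    return np.array([dc, du, Hv])
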