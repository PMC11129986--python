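"""One-parameter bifurcation analysis in the zooplankton mortality rates.

Hopf thresholds are located by bisection of the Routh-Hurwitz test
function ``p1*p2 - p0`` along a continued coexistence branch (the Hopf
condition for a cubic characteristic polynomial).  The criticality of a
Hopf point is decided by the first Lyapunov coefficient ``l1``, computed
with the standard projection (normal form) formula for n-dimensional
systems; only the *sign* of ``l1`` is contract-tested, since its magnitude
depends on the normalization convention.

Global events -- the heteroclinic destruction of the large stable cycle
and the canard-explosion collapse -- have no local test function and are
detected operationally: a trajectory started near the coexistence state
either sustains oscillations or collapses to the extinction state, and the
boundary in parameter space is bisected on that outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy import optimize

from .model import ModelParams, rhs, jacobian
from .equilibria import find_coexistence, routh_hurwitz, classify

__all__ = [
    "HopfPoint",
    "BifurcationBranch",
    "NoHopfError",
    "BranchLostError",
    "NoThresholdError",
    "DegenerateHopfError",
    "hopf_threshold",
    "lyapunov_coefficient",
    "lyapunov_sign",
    "branch_diagram",
    "extinction_threshold",
    "integrate",
    "collapses",
    "count_large_oscillations",
]

#: integration accuracy: slow-fast trajectories passing near the repelling
#: sheet of the critical manifold are exponentially sensitive
RTOL, ATOL = 1e-9, 1e-11
COLLAPSE_U = 1e-6
COLLAPSE_HOLD = 50.0


class NoHopfError(RuntimeError):
    """The Hopf test function does not change sign on the bracket."""


class BranchLostError(RuntimeError):
    """The continued equilibrium branch disappeared inside the bracket."""


class NoThresholdError(RuntimeError):
    """Both bracket ends give the same simulation outcome."""


class DegenerateHopfError(RuntimeError):
    """omega ~ 0 at the critical point (fold-Hopf degeneracy)."""


@dataclass
class HopfPoint:
    varied_parameter: str
    threshold: float
    omega: float
    equilibrium: np.ndarray
    l1: Optional[float] = None
    criticality: Optional[str] = None  # supercritical (l1<0) | subcritical (l1>0)


@dataclass
class BifurcationBranch:
    """Equilibrium branch with limit-cycle envelopes from long integration."""

    varied_parameter: str
    parameter: np.ndarray
    c_eq: np.ndarray
    stability: List[str]
    cycle_min: np.ndarray  # NaN where no sustained cycle
    cycle_max: np.ndarray
    collapsed: np.ndarray  # True where the probing trajectory reached E0

    def to_csv(self, path: str):
        import pandas as pd

        pd.DataFrame({
            self.varied_parameter: self.parameter,
            "c_eq": self.c_eq,
            "stability": self.stability,
            "cycle_min": self.cycle_min,
            "cycle_max": self.cycle_max,
            "collapsed": self.collapsed,
        }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# equilibrium continuation helpers
# ---------------------------------------------------------------------------

def _coexistence_at(p: ModelParams, guess: Optional[np.ndarray] = None,
                    grid: int = 30) -> np.ndarray:
    """One coexistence equilibrium: Newton from ``guess`` if given, else the
    largest-oxygen point of a fresh multi-start search (the non-saddle
    upper branch when two coexistence states exist)."""
    if guess is not None:
        sol = optimize.root(lambda x: rhs(np.abs(x), p), guess, tol=1e-13)
        x = np.abs(sol.x)
        if sol.success and np.all(x > 1e-10) and np.max(np.abs(rhs(x, p))) < 1e-9:
            return x
    eqs = find_coexistence(p, grid=grid)
    if not eqs:
        raise BranchLostError(f"no coexistence equilibrium at {p.mu1=}, {p.mu2=}")
    return eqs[-1].coords


def _track(p: ModelParams, vary: str, start: float, target: float,
           guess: np.ndarray, max_step: float = 0.01) -> np.ndarray:
    """Natural-parameter continuation of one equilibrium from start to target."""
    x = guess
    val = start
    step = np.sign(target - start) * min(max_step, abs(target - start))
    while val != target:
        nxt = val + step
        if (step > 0 and nxt > target) or (step < 0 and nxt < target):
            nxt = target
        try:
            x = _coexistence_at(p.replace(**{vary: nxt}), guess=x)
            val = nxt
        except BranchLostError:
            step *= 0.5
            if abs(step) < 1e-6:
                raise
    return x


def _hopf_test(p: ModelParams, x: np.ndarray) -> tuple:
    J = jacobian(x, p)
    p0, p1, p2 = routh_hurwitz(J)
    return p1 * p2 - p0, (p0, p1, p2)


def hopf_threshold(p: ModelParams, vary: str, bracket: tuple,
                   tol: float = 1e-7, guess: Optional[np.ndarray] = None) -> HopfPoint:
    """Hopf bifurcation threshold in ``vary`` (``'mu1'`` or ``'mu2'``).

    Bisects ``p1*p2 - p0 = 0`` along the continued coexistence branch to
    parameter tolerance ``tol`` and verifies ``p0 > 0``, ``p2 > 0`` at the
    root; the eigenvalues of the Jacobian there independently confirm a
    conjugate pair crossing the imaginary axis.
    """
    if vary not in ("mu1", "mu2"):
        raise ValueError("vary must be 'mu1' or 'mu2'")
    lo, hi = bracket
    x_lo = _coexistence_at(p.replace(**{vary: lo}), guess=guess)
    x_hi = _track(p, vary, lo, hi, x_lo)
    f_lo, _ = _hopf_test(p.replace(**{vary: lo}), x_lo)
    f_hi, _ = _hopf_test(p.replace(**{vary: hi}), x_hi)
    if f_lo * f_hi > 0:
        raise NoHopfError(f"p1*p2-p0 has no sign change on {bracket} (got {f_lo}, {f_hi})")
    a, fa, xa = lo, f_lo, x_lo
    b, fb = hi, f_hi
    while b - a > tol:
        m = 0.5 * (a + b)
        xm = _track(p, vary, a, m, xa)
        fm, _ = _hopf_test(p.replace(**{vary: m}), xm)
        if fa * fm <= 0:
            b, fb = m, fm
        else:
            a, fa, xa = m, fm, xm
    thr = 0.5 * (a + b)
    pc = p.replace(**{vary: thr})
    xc = _track(p, vary, a, thr, xa)
    _, (p0, p1, p2) = _hopf_test(pc, xc)
    if not (p0 > 0 and p2 > 0):
        raise NoHopfError(f"p0, p2 not both positive at candidate threshold ({p0=}, {p2=})")
    ev = np.linalg.eigvals(jacobian(xc, pc))
    i = int(np.argmin(np.abs(ev.real)))
    omega = abs(float(ev[i].imag))
    return HopfPoint(varied_parameter=vary, threshold=thr, omega=omega, equilibrium=xc)


# ---------------------------------------------------------------------------
# first Lyapunov coefficient (projection / normal form formula)
# ---------------------------------------------------------------------------

def lyapunov_coefficient(p: ModelParams, equilibrium: np.ndarray,
                         omega_tol: float = 1e-4) -> tuple:
    """First Lyapunov coefficient ``l1`` at a Hopf point.

    Uses the projection formula

        l1 = Re[ <q*, C(q,q,qb)> - 2 <q*, B(q, A^-1 B(q,qb))>
                 + <q*, B(qb, (2 i w I - A)^-1 B(q,q))> ] / (2 w)

    with ``A q = i w q``, ``A^T p = -i w p``, ``<p, q> = 1``.  The
    bilinear/trilinear forms B and C are directional second and third
    derivatives of the vector field, evaluated by central differences
    (the field is rational, so complex directions are admissible).
    Returns ``(l1, omega)``.  The magnitude of l1 is
    normalization-dependent; only its sign is contractually meaningful.
    """
    z0 = np.asarray(equilibrium, dtype=float)
    A = jacobian(z0, p)
    ev, V = np.linalg.eig(A)
    i = int(np.argmin(np.abs(ev.real)))
    omega = abs(float(ev[i].imag))
    if omega < omega_tol:
        raise DegenerateHopfError(f"omega = {omega} ~ 0: fold-Hopf degeneracy")
    lam = 1j * omega
    q = V[:, int(np.argmin(np.abs(ev - lam)))]
    evl, W = np.linalg.eig(A.T)
    pvec = W[:, int(np.argmin(np.abs(evl + lam)))]
    pvec = pvec / np.vdot(pvec, q).conj()  # <p, q> = sum conj(p_i) q_i = 1

    def f(z):
        c, u, v = z
        fc = p.A * u / (c + 1.0) - p.delta * u * c / (c + p.c2) - p.nu * c * v / (c + p.c3) - c
        fu = (p.B * c / (c + p.c1) - u) * u - u * v / (u + p.h) - p.sigma * u
        fv = p.epsilon * (p.eta * c * c / (c * c + p.c4 ** 2) * u * v / (u + p.h)
                          - p.mu1 * v - p.mu2 * v * v)
        return np.array([fc, fu, fv])

    h2 = 1e-3

    def Bf(x, y):
        return (f(z0 + h2 * (x + y)) - f(z0 + h2 * (x - y))
                - f(z0 - h2 * (x - y)) + f(z0 - h2 * (x + y))) / (4 * h2 * h2)

    h3 = 5e-3

    def Cf(x, y, w):
        s = np.zeros(3, dtype=complex)
        for s1 in (-1.0, 1.0):
            for s2 in (-1.0, 1.0):
                for s3 in (-1.0, 1.0):
                    s += s1 * s2 * s3 * f(z0 + h3 * (s1 * x + s2 * y + s3 * w))
        return s / (8 * h3 ** 3)

    qb = q.conj()
    t1 = np.vdot(pvec, Cf(q, q, qb))
    t2 = -2.0 * np.vdot(pvec, Bf(q, np.linalg.solve(A, Bf(q, qb))))
    t3 = np.vdot(pvec, Bf(qb, np.linalg.solve(2j * omega * np.eye(3) - A, Bf(q, q))))
    l1 = float((t1 + t2 + t3).real / (2.0 * omega))
    return l1, omega


def lyapunov_sign(p: ModelParams, hopf: HopfPoint) -> HopfPoint:
    """Fill ``l1`` and the criticality label of a located Hopf point."""
    pc = p.replace(**{hopf.varied_parameter: hopf.threshold})
    l1, _ = lyapunov_coefficient(pc, hopf.equilibrium)
    hopf.l1 = l1
    hopf.criticality = "supercritical" if l1 < 0 else "subcritical"
    return hopf


# ---------------------------------------------------------------------------
# trajectory probes
# ---------------------------------------------------------------------------

def integrate(p: ModelParams, z0, T: float, dense: bool = False,
              stop_on_collapse: bool = False):
    """Integrate the temporal model with a stiff-capable adaptive method."""
    events = None
    if stop_on_collapse:
        def ev(t, z):
            return z[1] - COLLAPSE_U
        ev.terminal = True
        ev.direction = -1
        events = ev
    return solve_ivp(lambda t, z: rhs(np.maximum(z, 0.0), p), (0.0, T),
                     np.asarray(z0, float), method="LSODA", rtol=RTOL, atol=ATOL,
                     events=events, dense_output=dense)


def collapses(p: ModelParams, z0, T: float = 5000.0) -> bool:
    """True if the trajectory reaches phytoplankton extinction (u below
    1e-6, held for 50 time units) before time T."""
    sol = integrate(p, z0, T, stop_on_collapse=True)
    if sol.t[-1] >= T * 0.9999 and sol.y[1, -1] >= COLLAPSE_U:
        return False
    tail = integrate(p, sol.y[:, -1], COLLAPSE_HOLD)
    return bool(np.all(tail.y[1] < 10 * COLLAPSE_U))


def count_large_oscillations(p: ModelParams, z0, T: float = 3000.0,
                             u_peak: float = 0.5) -> int:
    """Number of large phytoplankton oscillations (peaks of u above
    ``u_peak``) before the trajectory collapses or T is reached."""
    from scipy.signal import find_peaks

    sol = integrate(p, z0, T, dense=True, stop_on_collapse=True)
    t = np.linspace(sol.t[0], sol.t[-1], max(2000, int(sol.t[-1] - sol.t[0]) * 4))
    u = sol.sol(t)[1]
    peaks, _ = find_peaks(u, height=u_peak)
    return int(len(peaks))


# ---------------------------------------------------------------------------
# branch diagram with cycle envelopes
# ---------------------------------------------------------------------------

def _cycle_envelope(p: ModelParams, eq: np.ndarray, transient: float = 2000.0,
                    record: float = 1000.0, offset: float = 0.01,
                    max_doublings: int = 2) -> tuple:
    """(cycle_min, cycle_max, collapsed) of the oxygen component on the
    attractor reached from the equilibrium plus a small offset.

    The transient is discarded and extrema of c recorded; the times are
    doubled (up to ``max_doublings``) if the envelope has not converged
    (peak drift above 1 percent between the two halves of the window).
    """
    z0 = eq + offset
    for _ in range(max_doublings + 1):
        sol = integrate(p, z0, transient, stop_on_collapse=True)
        if sol.t[-1] < transient * 0.9999:
            return (np.nan, np.nan, True)
        rec = integrate(p, sol.y[:, -1], record, dense=True, stop_on_collapse=True)
        if rec.t[-1] < record * 0.9999:
            return (np.nan, np.nan, True)
        t = np.linspace(0, record, max(4000, int(record) * 4))
        c = rec.sol(t)[0]
        half = len(t) // 2
        hi1, hi2 = c[:half].max(), c[half:].max()
        lo1, lo2 = c[:half].min(), c[half:].min()
        scale = max(abs(hi2), 1e-12)
        if abs(hi1 - hi2) / scale < 0.01 and abs(lo1 - lo2) / scale < 0.01:
            break
        transient *= 2.0
        record *= 2.0
    if hi2 - lo2 < 1e-6:  # converged to the equilibrium: no sustained cycle
        return (np.nan, np.nan, False)
    return (float(min(lo1, lo2)), float(max(hi1, hi2)), False)


def branch_diagram(p: ModelParams, vary: str, grid: Sequence[float],
                   transient: float = 2000.0, record: float = 1000.0,
                   guess: Optional[np.ndarray] = None) -> BifurcationBranch:
    """Continue one coexistence branch over ``grid`` (sorted) and attach
    limit-cycle envelopes at the unstable points.

    Newton is seeded from the previous grid point; a Newton failure after
    step halving terminates the branch (candidate fold) and the remaining
    grid points are reported as NaN.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    n = len(grid)
    c_eq = np.full(n, np.nan)
    cmin = np.full(n, np.nan)
    cmax = np.full(n, np.nan)
    collapsed = np.zeros(n, dtype=bool)
    stability: List[str] = ["lost"] * n
    x = None
    for i, val in enumerate(grid[::-1]):  # continue from the high end
        j = n - 1 - i
        pv = p.replace(**{vary: val})
        try:
            x = _coexistence_at(pv, guess=x)
        except BranchLostError:
            break
        eq = classify(x, pv, on_marginal="label")
        c_eq[j] = eq.c
        stability[j] = eq.stability
        if eq.stability != "stable":
            cmin[j], cmax[j], collapsed[j] = _cycle_envelope(
                pv, x, transient=transient, record=record)
    return BifurcationBranch(varied_parameter=vary, parameter=grid, c_eq=c_eq,
                             stability=stability, cycle_min=cmin, cycle_max=cmax,
                             collapsed=collapsed)


# ---------------------------------------------------------------------------
# simulation-based global thresholds
# ---------------------------------------------------------------------------

def extinction_threshold(p: ModelParams, vary: str, bracket: tuple,
                         ic_offset=(0.01, 0.01, 0.01), T: float = 5000.0,
                         tol: float = 1e-5) -> float:
    """Parameter value separating sustained dynamics from collapse to E0.

    At each probe the trajectory starts at the coexistence equilibrium plus
    ``ic_offset`` and is integrated up to ``T``; the outcome (collapse =
    final u < 1e-6) is bisected to parameter tolerance ``tol``.  Raises
    :class:`NoThresholdError` when both bracket ends agree.
    """
    lo, hi = bracket

    def outcome(val: float) -> bool:
        pv = p.replace(**{vary: val})
        eq = _coexistence_at(pv)
        return collapses(pv, eq + np.asarray(ic_offset, float), T=T)

    o_lo, o_hi = outcome(lo), outcome(hi)
    if o_lo == o_hi:
        raise NoThresholdError(
            f"same outcome (collapse={o_lo}) at both ends of {bracket}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if outcome(mid) == o_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
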