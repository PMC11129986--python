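"""1-D reaction-diffusion simulator and pattern/regime diagnostics.

The spatial model adds turbulent diffusion to the temporal system on a
transect x in [0, L] with zero-flux (Neumann) boundaries::

    c_t = c_xx + F(c,u,v)
    u_t = u_xx + G(c,u,v)
    v_t = D v_xx + eps H(c,u,v)

Space is non-dimensionalized by the turbulent diffusivity, so oxygen and
phytoplankton carry unit diffusivity and zooplankton the ratio D.  The
scheme is the explicit one used for all reference computations: forward
Euler in time and the three-point central Laplacian in space, with
mirrored ghost nodes implementing the zero-flux condition (second-order
consistent and exactly conservative for the trapezoidal mass).  Default
discretization: L = 500, dx = 1, dt = 0.01.

Runs start from a localized perturbation of the homogeneous coexistence
state and are classified into regimes -- homogeneous, localized
oscillation, stationary (Turing) pattern, dynamic irregular pattern, or
global anoxia -- and scanned for oxygen minimum zones (OMZ): contiguous
stretches where oxygen falls well below its steady-state value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .model import ModelParams

__all__ = [
    "Grid1D",
    "FieldState",
    "SimulationOutput",
    "OMZReport",
    "make_initial",
    "laplacian",
    "step",
    "simulate",
    "detect_omz",
    "classify_regime",
    "dominant_mode",
]


class StabilityError(ValueError):
    """The explicit scheme's diffusive stability constraint is violated."""


class NumericalFailureError(RuntimeError):
    """A field went significantly negative during an update."""


@dataclass(frozen=True)
class Grid1D:
    """Uniform node-centered grid on [0, L] with n = L/dx + 1 nodes."""

    L: float = 500.0
    dx: float = 1.0

    def __post_init__(self):
        if self.L <= 0 or self.dx <= 0:
            raise ValueError("L and dx must be positive")
        if self.n < 16:
            raise ValueError("grid must have at least 16 nodes")

    @property
    def n(self) -> int:
        return int(round(self.L / self.dx)) + 1

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n)


@dataclass
class FieldState:
    c: np.ndarray
    u: np.ndarray
    v: np.ndarray
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.c.copy(), self.u.copy(), self.v.copy(), self.t)


@dataclass
class SimulationOutput:
    grid: Grid1D
    times: np.ndarray  # snapshot times
    snapshots: List[FieldState]
    mean_c: np.ndarray  # spatial averages at snapshot times
    mean_u: np.ndarray
    mean_v: np.ndarray
    params: ModelParams
    D: float
    dt: float
    equilibrium: np.ndarray  # homogeneous reference state (c*, u*, v*)
    clamped_nodes: int = 0  # round-off clamps applied during the run

    def save(self, path: str):
        """Self-describing array container (compressed npz) + run metadata."""
        np.savez_compressed(
            path,
            x=self.grid.x, times=self.times,
            c=np.array([s.c for s in self.snapshots]),
            u=np.array([s.u for s in self.snapshots]),
            v=np.array([s.v for s in self.snapshots]),
            mean_c=self.mean_c, mean_u=self.mean_u, mean_v=self.mean_v,
            params_json=np.array(self.params.to_json()),
            D=self.D, dt=self.dt, equilibrium=self.equilibrium,
        )

    def averages_to_csv(self, path: str):
        import pandas as pd

        pd.DataFrame({"t": self.times, "mean_c": self.mean_c,
                      "mean_u": self.mean_u, "mean_v": self.mean_v}
                     ).to_csv(path, index=False)


@dataclass
class OMZReport:
    """Contiguous low-oxygen intervals relative to the steady state c*."""

    intervals: List[Tuple[float, float]]  # (x_start, x_end), disjoint, sorted
    theta: float
    c_star: float

    @property
    def total_width(self) -> float:
        return sum(b - a for a, b in self.intervals)


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def make_initial(grid: Grid1D, equilibrium, variant: str = "eq_bump",
                 half_width: float = 10.0) -> FieldState:
    """Localized perturbation of the homogeneous coexistence state.

    ``eq_bump``: c and u are *raised* by 0.1 and 0.2 on |x - L/2| < half_width.
    ``dip``: c and u are *lowered* by 0.5 and 0.2 on the same window (the
    variant probing robustness of OMZ formation to the perturbation sign).
    Zooplankton starts at v* everywhere.
    """
    cs, us, vs = np.asarray(equilibrium, dtype=float)
    x = grid.x
    w = np.abs(x - grid.L / 2.0) < half_width
    c = np.full(grid.n, cs)
    u = np.full(grid.n, us)
    v = np.full(grid.n, vs)
    if variant in ("eq_bump", "eq17"):
        c[w] += 0.1
        u[w] += 0.2
    elif variant in ("dip", "fig9"):
        if cs < 0.5:
            raise ValueError("dip variant would make the oxygen field negative")
        c[w] -= 0.5
        u[w] -= 0.2
    else:
        raise ValueError(f"unknown initial-condition variant {variant!r}")
    return FieldState(c, u, v, 0.0)


# ---------------------------------------------------------------------------
# explicit scheme
# ---------------------------------------------------------------------------

def laplacian(f: np.ndarray, dx: float, out: Optional[np.ndarray] = None) -> np.ndarray:
    """Three-point Laplacian with mirrored ghost nodes (zero flux)."""
    if out is None:
        out = np.empty_like(f)
    out[1:-1] = f[2:] - 2.0 * f[1:-1] + f[:-2]
    out[0] = 2.0 * (f[1] - f[0])
    out[-1] = 2.0 * (f[-2] - f[-1])
    out /= dx * dx
    return out


def _check_stability(D: float, dt: float, dx: float):
    if max(1.0, D) * dt / (dx * dx) > 0.5:
        raise StabilityError(
            f"explicit scheme unstable: max(1, D) * dt / dx^2 = "
            f"{max(1.0, D) * dt / (dx * dx):.3f} > 0.5")


def _reaction(c, u, v, p: ModelParams):
    Fv = p.A * u / (c + 1.0) - p.delta * u * c / (c + p.c2) - p.nu * c * v / (c + p.c3) - c
    Gv = (p.B * c / (c + p.c1) - u) * u - u * v / (u + p.h) - p.sigma * u
    Hv = p.epsilon * (p.eta * c * c / (c * c + p.c4 ** 2) * u * v / (u + p.h)
                      - p.mu1 * v - p.mu2 * v * v)
    return Fv, Gv, Hv


def step(field: FieldState, p: ModelParams, D: float, dt: float, dx: float,
         include_reaction: bool = True) -> FieldState:
    """One forward-Euler update of all three fields.

    Values driven into (-1e-8, 0) by round-off are clamped to zero (the
    clamp count is tracked by :func:`simulate`); anything below -1e-8
    raises :class:`NumericalFailureError`.  Setting
    ``include_reaction=False`` gives the pure-diffusion scheme, whose
    trapezoidal mass is conserved exactly.
    """
    _check_stability(D, dt, dx)
    c, u, v = field.c, field.u, field.v
    lc, lu, lv = laplacian(c, dx), laplacian(u, dx), laplacian(v, dx)
    if include_reaction:
        Fr, Gr, Hr = _reaction(c, u, v, p)
    else:
        Fr = Gr = Hr = 0.0
    cn = c + dt * (lc + Fr)
    un = u + dt * (lu + Gr)
    vn = v + dt * (D * lv + Hr)
    new = FieldState(cn, un, vn, field.t + dt)
    for f in (cn, un, vn):
        low = f.min()
        if low < -1e-8:
            raise NumericalFailureError(f"field went negative ({low}) at t = {new.t}")
        np.clip(f, 0.0, None, out=f)
    return new


def simulate(p: ModelParams, D: float, grid: Optional[Grid1D] = None,
             dt: float = 0.01, T: float = 5000.0, ic_variant: str = "eq_bump",
             save_every: float = 10.0, equilibrium=None,
             initial: Optional[FieldState] = None) -> SimulationOutput:
    """Full run: localized perturbation -> snapshots and average series.

    ``equilibrium`` (the homogeneous reference state) is located
    automatically when not supplied: the temporally stable coexistence
    state if one exists, else the largest-oxygen coexistence state.
    Snapshots (all three fields) are stored every ``save_every`` time
    units; spatial averages are recorded at the same cadence.
    """
    grid = grid or Grid1D()
    _check_stability(D, dt, grid.dx)
    if equilibrium is None:
        from .equilibria import find_coexistence

        eqs = find_coexistence(p, grid=25)
        if not eqs:
            raise ValueError("no coexistence equilibrium for these parameters")
        stable = [e for e in eqs if e.stability == "stable"]
        equilibrium = (stable[-1] if stable else eqs[-1]).coords
    equilibrium = np.asarray(equilibrium, dtype=float)
    state = initial.copy() if initial is not None else make_initial(grid, equilibrium, ic_variant)

    n_steps = int(round(T / dt))
    save_stride = max(1, int(round(save_every / dt)))
    c, u, v = state.c.copy(), state.u.copy(), state.v.copy()
    dx = grid.dx
    times, snaps, mc, mu_, mv = [], [], [], [], []
    clamped = 0
    lc = np.empty_like(c)
    lu = np.empty_like(u)
    lv = np.empty_like(v)
    for i in range(n_steps):
        laplacian(c, dx, lc)
        laplacian(u, dx, lu)
        laplacian(v, dx, lv)
        Fr, Gr, Hr = _reaction(c, u, v, p)
        c += dt * (lc + Fr)
        u += dt * (lu + Gr)
        v += dt * (D * lv + Hr)
        low = min(c.min(), u.min(), v.min())
        if low < 0:
            if low < -1e-8:
                raise NumericalFailureError(
                    f"field went negative ({low}) at t = {(i + 1) * dt}")
            clamped += int((c < 0).sum() + (u < 0).sum() + (v < 0).sum())
            np.clip(c, 0.0, None, out=c)
            np.clip(u, 0.0, None, out=u)
            np.clip(v, 0.0, None, out=v)
        if (i + 1) % save_stride == 0:
            t_now = (i + 1) * dt
            times.append(t_now)
            snaps.append(FieldState(c.copy(), u.copy(), v.copy(), t_now))
            mc.append(c.mean())
            mu_.append(u.mean())
            mv.append(v.mean())
    return SimulationOutput(grid=grid, times=np.array(times), snapshots=snaps,
                            mean_c=np.array(mc), mean_u=np.array(mu_),
                            mean_v=np.array(mv), params=p, D=D, dt=dt,
                            equilibrium=equilibrium, clamped_nodes=clamped)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def detect_omz(field: FieldState, c_star: float, theta: float = 0.5,
               grid: Optional[Grid1D] = None) -> OMZReport:
    """Maximal runs of >= 2 consecutive nodes with c below theta * c*."""
    if c_star <= 0:
        raise ValueError("c_star must be positive")
    if not (0 < theta < 1):
        raise ValueError("theta must lie in (0, 1)")
    grid = grid or Grid1D(L=float(len(field.c) - 1))
    x = grid.x
    below = field.c < theta * c_star
    intervals: List[Tuple[float, float]] = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if j - i + 1 >= 2:
                intervals.append((float(x[i]), float(x[j])))
            i = j + 1
        else:
            i += 1
    return OMZReport(intervals=intervals, theta=theta, c_star=c_star)


def dominant_mode(field_c: np.ndarray, L: float) -> Tuple[int, float]:
    """Dominant cosine mode of a snapshot under Neumann boundaries.

    Mode m corresponds to wavenumber k = m * pi / L.  Returns (m, k).
    """
    from scipy.fft import dct

    spectrum = np.abs(dct(field_c - field_c.mean(), type=1))
    m = int(np.argmax(spectrum[1:])) + 1
    return m, m * np.pi / L


def classify_regime(output: SimulationOutput, window: float = 500.0) -> str:
    """Decision tree over the final ``window`` time units of a run.

    * ``global_anoxia``: final mean oxygen below 0.01.
    * ``homogeneous_steady``: relative spatial std of c below 1e-4 and
      temporal std of the mean below 1e-4.
    * ``stationary_pattern``: spatial std >= 1e-2 and the L2 change
      between the last two snapshots below 1e-4 per node.
    * ``localized_oscillation``: temporal oscillation confined to less
      than 20 percent of the domain.
    * ``dynamic_irregular`` otherwise.
    """
    if output.times[-1] < 2.0 * window:
        raise ValueError(f"run shorter than twice the classification window {window}")
    t = output.times
    sel = t > t[-1] - window
    final = output.snapshots[-1]
    if output.mean_c[-1] < 0.01:
        return "global_anoxia"
    cbar = output.mean_c[sel]
    spat_std = final.c.std()
    rel_spat = spat_std / max(final.c.mean(), 1e-12)
    if rel_spat < 1e-4 and cbar.std() < 1e-4:
        return "homogeneous_steady"
    if spat_std >= 1e-2:
        delta = final.c - output.snapshots[-2].c
        l2_per_node = np.linalg.norm(delta) / len(delta)
        if l2_per_node < 1e-4:
            return "stationary_pattern"
    # fraction of nodes whose oxygen level oscillates over the window
    wins = [s.c for s, keep in zip(output.snapshots, sel) if keep]
    block = np.array(wins)
    node_range = block.max(axis=0) - block.min(axis=0)
    osc = node_range > 0.05 * max(output.equilibrium[0], 1e-12)
    if osc.mean() < 0.2:
        return "localized_oscillation"
    return "dynamic_irregular"
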