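"""Core plankton-oxygen model: right-hand sides, parameters, analytic Jacobian.

The model couples dissolved oxygen ``c``, phytoplankton ``u`` and
zooplankton ``v`` in dimensionless form::

    dc/dt = A*u/(c+1) - delta*u*c/(c+c2) - nu*c*v/(c+c3) - c        == F(c,u,v)
    du/dt = (B*c/(c+c1) - u)*u - u*v/(u+h) - sigma*u                == G(c,u,v)
    dv/dt = eps * ( eta*c^2/(c^2+c4^2) * u*v/(u+h)
                    - mu1*v - mu2*v^2 )                             == eps*H(c,u,v)

Oxygen is produced by phytoplankton photosynthesis (first term of F) and
consumed by both plankton compartments and by natural decay.  Phytoplankton
grows logistically with an oxygen-dependent rate and is grazed by
zooplankton.  Zooplankton converts grazing into growth with an
oxygen-dependent efficiency and dies both linearly (rate ``mu1``) and
quadratically (rate ``mu2``, a closure for intraspecific competition and
predation by higher trophic levels).  The factor ``eps`` (0 < eps <= 1) is
the ratio of the zooplankton to phytoplankton timescales, making the system
slow-fast for eps << 1.

Everything downstream (equilibrium finding, bifurcation analysis, the
slow-fast decomposition, Turing analysis and the PDE simulator) consumes
the functions defined here; the Jacobian entries are frozen closed forms,
regression-tested against finite differences.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "ModelParams",
    "InvalidStateError",
    "clamp_state",
    "rhs",
    "rhs_unscaled_H",
    "F",
    "G",
    "H",
    "partials",
    "jacobian",
    "BASELINE",
]

#: components of tiny magnitude below zero (from upstream floating point
#: arithmetic) are clamped to exactly zero; anything more negative is an error
NEGATIVE_CLAMP = -1e-12


class InvalidStateError(ValueError):
    """Raised when a state vector is non-finite or significantly negative."""


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless kinetic constants of the plankton-oxygen model.

    ``A``  per capita oxygen production rate of phytoplankton.
    ``B``  per capita phytoplankton growth rate.
    ``sigma`` phytoplankton natural mortality.
    ``c1..c4`` half-saturation constants of the Monod-type kinetics.
    ``eta`` zooplankton food assimilation coefficient.
    ``delta`` oxygen consumption rate by phytoplankton respiration.
    ``nu`` oxygen consumption rate by zooplankton respiration.
    ``h`` half-saturation of the grazing response.
    ``mu1`` linear zooplankton mortality, ``mu2`` quadratic (density
    dependent) zooplankton mortality; both may be zero.
    ``epsilon`` timescale ratio (zooplankton slow relative to
    phytoplankton/oxygen); ``epsilon = 1`` recovers the single-timescale
    model.
    """

    A: float = 4.0
    B: float = 3.0
    sigma: float = 0.1
    c1: float = 0.7
    c2: float = 1.0
    c3: float = 1.0
    c4: float = 1.0
    eta: float = 0.7
    delta: float = 1.0
    nu: float = 0.01
    h: float = 0.1
    mu1: float = 0.0
    mu2: float = 0.0
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        for name in ("A", "B", "sigma", "c1", "c2", "c3", "c4", "eta", "delta", "nu", "h"):
            val = getattr(self, name)
            if not (math.isfinite(val) and val > 0):
                raise ValueError(f"parameter {name} must be strictly positive, got {val}")
        for name in ("mu1", "mu2"):
            val = getattr(self, name)
            if not (math.isfinite(val) and val >= 0):
                raise ValueError(f"parameter {name} must be non-negative, got {val}")
        if not (0 < self.epsilon <= 1):
            raise ValueError(f"epsilon must lie in (0, 1], got {self.epsilon}")

    @classmethod
    def baseline(cls, mu1: float = 0.0, mu2: float = 0.0, epsilon: float = 1.0) -> "ModelParams":
        """The reference parameterization used throughout the analysis.

        A=4, B=3, sigma=0.1, c1=c2=c3=c4=1 except c1=0.7, eta=0.7, delta=1,
        nu=0.01, h=0.1.  The mortality rates ``mu1``, ``mu2`` and the
        timescale ratio ``epsilon`` are the quantities varied in all
        bifurcation studies and must be chosen per analysis.
        """
        return cls(mu1=mu1, mu2=mu2, epsilon=epsilon)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    # -- flat key/value JSON round trip ------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))


#: baseline constants with the mortality/timescale knobs at their neutral values
BASELINE = ModelParams.baseline()


def clamp_state(state: Iterable[float]) -> np.ndarray:
    """Validate a (c, u, v) state and clamp tiny negative round-off to zero."""
    z = np.asarray(state, dtype=float)
    if z.shape != (3,):
        raise InvalidStateError(f"state must have shape (3,), got {z.shape}")
    if not np.all(np.isfinite(z)):
        raise InvalidStateError(f"non-finite state {z}")
    if np.any(z < NEGATIVE_CLAMP):
        raise InvalidStateError(f"significantly negative state {z}")
    return np.where(z < 0, 0.0, z)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def F(c, u, v, p: ModelParams):
    """Oxygen budget: photosynthetic production minus consumption and decay."""
    return p.A * u / (c + 1.0) - p.delta * u * c / (c + p.c2) - p.nu * c * v / (c + p.c3) - c


def G(c, u, v, p: ModelParams):
    """Phytoplankton budget: oxygen-limited logistic growth, grazing, mortality."""
    return (p.B * c / (c + p.c1) - u) * u - u * v / (u + p.h) - p.sigma * u


def H(c, u, v, p: ModelParams):
    """Zooplankton budget *without* the timescale factor epsilon."""
    return p.eta * c * c / (c * c + p.c4 * p.c4) * u * v / (u + p.h) - p.mu1 * v - p.mu2 * v * v


def rhs(state, p: ModelParams) -> np.ndarray:
    """Fast-time vector field ``(F, G, eps*H)`` at a biologically admissible state.

    The third component carries the epsilon factor; use
    :func:`rhs_unscaled_H` when the bare zooplankton rate ``H`` is needed.
    """
    c, u, v = clamp_state(state)
    return np.array([F(c, u, v, p), G(c, u, v, p), p.epsilon * H(c, u, v, p)])


def rhs_unscaled_H(state, p: ModelParams) -> float:
    """The zooplankton reaction rate ``H`` without the epsilon factor."""
    c, u, v = clamp_state(state)
    return float(H(c, u, v, p))


# ---------------------------------------------------------------------------
# analytic partial derivatives (frozen closed forms)
# ---------------------------------------------------------------------------

def partials(state, p: ModelParams) -> dict:
    """All nine first partials of (F, G, H) -- H here is *unscaled*.

    Keys: ``Fc, Fu, Fv, Gc, Gu, Gv, Hc, Hu, Hv``.  These closed forms were
    derived symbolically once and are regression-tested against central
    finite differences of :func:`rhs`.
    """
    c, u, v = clamp_state(state)
    c2, c3, c4, h = p.c2, p.c3, p.c4, p.h
    gsat = p.eta * c * c / (c * c + c4 * c4)  # oxygen-dependent assimilation
    return {
        "Fc": -p.A * u / (c + 1.0) ** 2 - p.delta * u * c2 / (c + c2) ** 2
        - p.nu * v * c3 / (c + c3) ** 2 - 1.0,
        "Fu": p.A / (c + 1.0) - p.delta * c / (c + c2),
        "Fv": -p.nu * c / (c + c3),
        "Gc": p.B * p.c1 * u / (c + p.c1) ** 2,
        "Gu": p.B * c / (c + p.c1) - 2.0 * u - v * h / (u + h) ** 2 - p.sigma,
        "Gv": -u / (u + h),
        "Hc": p.eta * 2.0 * c * c4 * c4 / (c * c + c4 * c4) ** 2 * u * v / (u + h),
        "Hu": gsat * v * h / (u + h) ** 2,
        "Hv": gsat * u / (u + h) - p.mu1 - 2.0 * p.mu2 * v,
    }


def jacobian(state, p: ModelParams) -> np.ndarray:
    """3x3 Jacobian of the fast-time system ``(F, G, eps*H)``.

    Row 3 carries the epsilon factor, consistent with :func:`rhs`.
    """
    d = partials(state, p)
    e = p.epsilon
    return np.array(
        [
            [d["Fc"], d["Fu"], d["Fv"]],
            [d["Gc"], d["Gu"], d["Gv"]],
            [e * d["Hc"], e * d["Hu"], e * d["Hv"]],
        ]
    )
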