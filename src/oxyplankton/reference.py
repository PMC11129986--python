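"""Reference computations for the baseline parameterization.

``run_reference_suite`` recomputes, from scratch, the twelve headline
quantities of the baseline model -- zooplankton-free oxygen levels, the
fold of the critical manifold and the slow drift there, the six Hopf
thresholds, the Turing critical wavenumber and the stability window of
the upper zooplankton-free state -- and compares them against frozen
regression values.  The whole suite is deterministic: rerunning it
produces identical numbers.
"""

from __future__ import annotations

import json
from typing import List, Optional

import numpy as np

from .model import ModelParams, jacobian
from . import equilibria as eqmod
from . import bifurcation as bif
from . import slowfast
from . import turing as tur

__all__ = ["FOLD_CONTEXT_MU", "REFERENCE_VALUES", "run_reference_suite",
           "e2_instability_upper_mu1"]

#: mortality rates used when quoting the slow drift H at the fold point.
#: The fold itself is mortality-independent; the drift is evaluated in the
#: slow-fast study regime mu1 = 0.3 with mu2 chosen just above the singular
#: Hopf threshold, where the reduced flow still points toward the fold.
FOLD_CONTEXT_MU = {"mu1": 0.3, "mu2": 0.1018}

#: frozen regression values (computed by this package at the baseline
#: parameterization) with comparison tolerances
REFERENCE_VALUES = {
    "zf_lower_c": (0.0258, 1e-3),
    "zf_upper_c": (1.712, 1e-3),
    "fold_c": (1.26531, 1e-4),
    "fold_H": (0.001859, 1e-5),
    "hopf_mu2_mu1_0.05_eps1": (0.35405, 1e-3),
    "hopf_mu1_mu2_0_eps1": (0.398, 2e-3),
    "hopf_mu2_mu1_0_eps1": (0.408, 2e-3),
    "hopf_mu2_mu1_0.24_eps1": (0.1577, 2e-3),
    "hopf_mu2_mu1_0.24_eps0.5": (0.1638, 2e-3),
    "hopf_mu2_mu1_0.3_eps0.5": (0.1007, 2e-3),
    "turing_kT2_D5": (0.1095, 1e-3),
    "e2_unstable_mu1_upper": (0.497, 2e-3),
}


def e2_instability_upper_mu1(p: Optional[ModelParams] = None,
                             bracket=(0.3, 0.7), tol: float = 1e-7) -> float:
    """Upper endpoint of the mu1 interval on which the upper
    zooplankton-free state is unstable.

    The state itself is mortality-independent; only its leading eigenvalue
    (the zooplankton invasion rate) depends on mu1.  Located by bisecting
    the largest eigenvalue real part of the full Jacobian.
    """
    p = p or ModelParams.baseline(mu1=bracket[0], mu2=0.1, epsilon=1.0)
    e2 = eqmod.find_zooplankton_free(p)[-1]

    def lead(mu1: float) -> float:
        J = jacobian(e2.coords, p.replace(mu1=mu1))
        return float(np.max(np.linalg.eigvals(J).real))

    lo, hi = bracket
    if lead(lo) <= 0 or lead(hi) >= 0:
        raise ValueError("bracket does not straddle the stability change of E2")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if lead(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_reference_quantities() -> dict:
    """Recompute the twelve reference quantities from scratch."""
    out = {}
    base = ModelParams.baseline

    zf = eqmod.find_zooplankton_free(base(mu1=0.1, mu2=0.1))
    out["zf_lower_c"] = zf[0].c
    out["zf_upper_c"] = zf[-1].c

    fold = slowfast.fold_point(base(**FOLD_CONTEXT_MU))
    out["fold_c"] = fold.c_s
    out["fold_H"] = fold.H_value

    out["hopf_mu2_mu1_0.05_eps1"] = bif.hopf_threshold(
        base(mu1=0.05, epsilon=1.0), "mu2", (0.30, 0.40)).threshold
    out["hopf_mu1_mu2_0_eps1"] = bif.hopf_threshold(
        base(mu2=0.0, epsilon=1.0), "mu1", (0.35, 0.45)).threshold
    out["hopf_mu2_mu1_0_eps1"] = bif.hopf_threshold(
        base(mu1=0.0, epsilon=1.0), "mu2", (0.38, 0.45)).threshold
    out["hopf_mu2_mu1_0.24_eps1"] = bif.hopf_threshold(
        base(mu1=0.24, epsilon=1.0), "mu2", (0.13, 0.18)).threshold
    out["hopf_mu2_mu1_0.24_eps0.5"] = bif.hopf_threshold(
        base(mu1=0.24, epsilon=0.5), "mu2", (0.13, 0.19)).threshold
    out["hopf_mu2_mu1_0.3_eps0.5"] = bif.hopf_threshold(
        base(mu1=0.3, epsilon=0.5), "mu2", (0.09, 0.12)).threshold

    pt = base(mu1=0.0, mu2=0.41, epsilon=1.0)
    eqs = eqmod.find_coexistence(pt, grid=25)
    stable = [e for e in eqs if e.stability == "stable"][-1]
    out["turing_kT2_D5"] = tur.critical_wavenumber(pt, 5.0, stable.coords)

    out["e2_unstable_mu1_upper"] = e2_instability_upper_mu1()
    return out


def run_reference_suite(outdir: Optional[str] = None) -> List[dict]:
    """Compute all reference quantities and report pass/fail per row.

    Errors in one computation are captured in its row and do not abort
    the rest of the suite.  When ``outdir`` is given, a JSON report and a
    human-readable table are written there.
    """
    rows: List[dict] = []
    try:
        values = compute_reference_quantities()
    except Exception:  # recompute row by row on catastrophic failure
        values = {}
    for name, (expected, tol) in REFERENCE_VALUES.items():
        row = {"name": name, "expected": expected, "tolerance": tol}
        try:
            val = values.get(name)
            if val is None:
                raise RuntimeError("computation failed")
            row["value"] = float(val)
            row["pass"] = bool(abs(row["value"] - expected) <= tol)
        except Exception as exc:  # per-item capture
            row["value"] = None
            row["pass"] = False
            row["error"] = str(exc)
        rows.append(row)
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "reference_suite.json"), "w") as fh:
            json.dump(rows, fh, indent=2)
        with open(os.path.join(outdir, "reference_suite.txt"), "w") as fh:
            fh.write(f"{'quantity':34s} {'computed':>12s} {'expected':>10s} "
                     f"{'tol':>8s}  verdict\n")
            for r in rows:
                val = "failed" if r["value"] is None else f"{r['value']:.6g}"
                fh.write(f"{r['name']:34s} {val:>12s} {r['expected']:>10g} "
                         f"{r['tolerance']:>8g}  {'PASS' if r['pass'] else 'FAIL'}\n")
    return rows
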