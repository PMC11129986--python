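"""Fast subsystem, critical manifold, fold point and reduced flow."""

import numpy as np
import pytest
from scipy.interpolate import interp1d
from scipy.ndimage import label

from oxyplankton import ModelParams, fast_equilibria, fold_point, classify_fold
from oxyplankton.model import F, G, partials
from oxyplankton.slowfast import (
    NoFoldError,
    SingularSlowFlowError,
    build_manifold,
    slow_flow,
)
from oxyplankton.bifurcation import integrate

FOLD_MU = {"mu1": 0.3, "mu2": 0.1018}


@pytest.fixture(scope="module")
def params():
    return ModelParams.baseline(**FOLD_MU)


@pytest.fixture(scope="module")
def fold(params):
    return fold_point(params)


@pytest.fixture(scope="module")
def manifold(params):
    return build_manifold(params, n_grid=200)


def _attracting_interpolants(manifold):
    att = manifold.samples[[b == "attracting" for b in manifold.branch]]
    att = att[np.argsort(att[:, 2])]
    return (interp1d(att[:, 2], att[:, 0]), interp1d(att[:, 2], att[:, 1]),
            att[0, 2], att[-1, 2])


class TestFastSubsystem:
    def test_two_equilibria_below_fold(self, params):
        sl = fast_equilibria(0.6, params)
        assert len(sl.equilibria) == 2
        assert sl.stability == ["saddle", "stable"]  # sorted by u

    def test_no_equilibria_above_fold(self, params):
        assert fast_equilibria(1.0, params).equilibria == []

    def test_counts_match_sign_grid_oracle(self, params, rng):
        # brute-force 200x200 sign-grid scan of (F, G) on (0, 5]^2
        cs = np.linspace(1e-3, 5.0, 200)
        us = np.linspace(1e-3, 5.0, 200)
        C, U = np.meshgrid(cs, us, indexing="ij")
        for v0 in rng.uniform(0.0, 0.85, size=5):
            Fg = F(C, U, v0, params)
            Gg = G(C, U, v0, params)
            # cells whose corners straddle zero in both components
            fz = np.zeros((199, 199), bool)
            gz = np.zeros((199, 199), bool)
            for arr, out in ((Fg, fz), (Gg, gz)):
                corners = np.stack([arr[:-1, :-1], arr[1:, :-1],
                                    arr[:-1, 1:], arr[1:, 1:]])
                out[:] = (corners.min(axis=0) < 0) & (corners.max(axis=0) > 0)
            both = fz & gz
            _, n_clusters = label(both, structure=np.ones((3, 3), bool))
            eqs = fast_equilibria(v0, params)
            assert n_clusters == len(eqs.equilibria)
            cell = np.hypot(cs[1] - cs[0], us[1] - us[0])
            for c_eq, u_eq in eqs.equilibria:
                i = np.argmin(np.abs(cs - c_eq))
                j = np.argmin(np.abs(us - u_eq))
                window = both[max(i - 2, 0):i + 2, max(j - 2, 0):j + 2]
                assert window.any(), (v0, c_eq, u_eq, cell)


class TestFoldPoint:
    def test_coordinates(self, fold):
        assert fold.c_s == pytest.approx(1.26531, abs=1e-4)
        assert fold.u_s == pytest.approx(1.05229, abs=1e-4)
        assert fold.v_s == pytest.approx(0.89784, abs=1e-4)

    def test_fast_determinant_vanishes(self, fold, params):
        d = partials(fold.coords, params)
        assert abs(d["Fc"] * d["Gu"] - d["Fu"] * d["Gc"]) < 1e-9

    def test_slow_drift_at_fold(self, fold):
        # with the slow-fast study mortality rates the drift is small and
        # positive: the slow flow points toward the fold
        assert fold.H_value == pytest.approx(0.001859, abs=1e-5)
        assert fold.H_value > 0

    def test_equals_slice_count_transition(self, params, fold):
        # the fold is where the fast-equilibrium count drops from 2 to 0
        assert len(fast_equilibria(fold.v_s - 1e-4, params).equilibria) == 2
        assert len(fast_equilibria(fold.v_s + 1e-4, params).equilibria) == 0

    def test_no_fold_when_production_too_weak(self):
        with pytest.raises(NoFoldError):
            fold_point(ModelParams.baseline().replace(B=0.05, mu1=0.1, mu2=0.1))


class TestFoldClassification:
    def test_discriminants_match_finite_differences(self, fold, params):
        h = 1e-6
        z = fold.coords

        def fd(fun, idx):
            e = np.zeros(3)
            e[idx] = h
            a, b = z + e, z - e
            return (fun(a[0], a[1], a[2], params) - fun(b[0], b[1], b[2], params)) / (2 * h)

        d1 = fd(F, 2) * fd(G, 1) - fd(F, 1) * fd(G, 2)
        d2 = fd(F, 2) * fd(G, 0) - fd(F, 0) * fd(G, 2)
        assert fold.d1 == pytest.approx(d1, rel=1e-6)
        assert fold.d2 == pytest.approx(d2, rel=1e-6)

    def test_classification_robust_to_tolerance(self, fold, params):
        verdicts = {classify_fold(fold, params, tol=t)
                    for t in [1e-8, 1e-7, 1e-6, 1e-5, 1e-4]}
        assert len(verdicts) == 1

    def test_vanishing_respiration_kills_Fv_term(self, fold):
        # nu -> 0 makes Fv -> 0, so d1 reduces to -Fu*Gv
        p_tiny = ModelParams.baseline(**FOLD_MU).replace(nu=1e-12)
        fp = fold_point(p_tiny)
        d = partials(fp.coords, p_tiny)
        assert fp.d1 == pytest.approx(-d["Fu"] * d["Gv"], rel=1e-6)


class TestCriticalManifold:
    def test_trivial_branch_always_attracting(self, manifold):
        assert np.all(manifold.trivial_eigs < 0)

    def test_sheets_split_at_fold_u(self, manifold):
        u_s = manifold.fold.u_s
        for (c, u, v0), br in zip(manifold.samples, manifold.branch):
            if br == "attracting":
                assert u > u_s - 1e-8
            else:
                assert u < u_s + 1e-8

    def test_sheets_meet_at_fold(self, manifold):
        u_att = min(u for (c, u, v), b in zip(manifold.samples, manifold.branch)
                    if b == "attracting")
        u_rep = max(u for (c, u, v), b in zip(manifold.samples, manifold.branch)
                    if b == "repelling")
        assert u_att - u_rep < 0.05  # grid resolution near the fold

    def test_fast_eigenvalues_confirm_labels(self, manifold, params):
        for (c, u, v0), br in list(zip(manifold.samples, manifold.branch))[::10]:
            d = partials(np.array([c, u, v0]), params)
            ev = np.linalg.eigvals(np.array([[d["Fc"], d["Fu"]],
                                             [d["Gc"], d["Gu"]]]))
            if br == "attracting":
                assert np.all(ev.real < 0)
            else:
                assert ev.real.max() > 0 > ev.real.min()


class TestSlowFlow:
    def test_drift_sign_matches_H(self, manifold, params):
        for row in manifold.samples[::50]:
            if abs(row[2] - manifold.fold.v_s) < 0.02:
                continue
            flow = slow_flow(row, params)
            from oxyplankton.model import rhs_unscaled_H

            assert np.sign(flow[2]) == np.sign(rhs_unscaled_H(row, params))

    def test_singular_at_fold(self, manifold, params):
        with pytest.raises(SingularSlowFlowError):
            slow_flow(manifold.fold.coords, params)

    def test_oxygen_drift_blows_up_toward_fold(self, manifold, params):
        att = manifold.samples[[b == "attracting" for b in manifold.branch]]
        att = att[np.argsort(att[:, 2])]
        near = att[att[:, 2] < manifold.fold.v_s - 1e-4][-6:-1]
        vals = [abs(slow_flow(r, params)[0]) for r in near]
        assert all(np.diff(vals) > 0)

    def test_matches_manifold_differentiation(self, manifold, params):
        # (dc/dtau, du/dtau) = d(manifold)/dv * dv/dtau away from the fold
        dv = 1e-4

        def upper_point(v):
            return fast_equilibria(v, params).equilibria[-1]

        for v in np.linspace(0.3, manifold.fold.v_s - 0.1, 6):
            c, u = upper_point(v)
            flow = slow_flow(np.array([c, u, v]), params)
            (c_m, u_m), (c_p, u_p) = upper_point(v - dv), upper_point(v + dv)
            assert flow[0] == pytest.approx((c_p - c_m) / (2 * dv) * flow[2], rel=0.01)
            assert flow[1] == pytest.approx((u_p - u_m) / (2 * dv) * flow[2], rel=0.01)


class TestSingularLimitTracking:
    def test_trajectory_follows_attracting_sheet(self, manifold, params):
        # with eps = 0.001 a trajectory started on the attracting sheet
        # stays within 0.05 of it until it reaches the fold neighborhood
        cint, uint, vlo, vhi = _attracting_interpolants(manifold)
        from scipy.integrate import solve_ivp
        from oxyplankton.model import rhs

        v0 = 0.5
        z0 = np.array([float(cint(v0)), float(uint(v0)), v0])
        pe = params.replace(epsilon=0.001)

        def reach_fold(t, z):
            return z[2] - (manifold.fold.v_s - 0.05)

        reach_fold.terminal = True
        reach_fold.direction = 1
        sol = solve_ivp(lambda t, z: rhs(np.maximum(z, 0.0), pe), (0.0, 2e6),
                        z0, method="LSODA", rtol=1e-9, atol=1e-11,
                        events=reach_fold, dense_output=True)
        assert sol.t_events[0].size == 1  # the slow drift reaches the fold
        ts = np.linspace(0, sol.t[-1], 500)
        Z = sol.sol(ts)
        sel = (Z[2] > vlo) & (Z[2] < manifold.fold.v_s - 0.05)
        assert sel.sum() > 50
        dc = np.abs(Z[0, sel] - cint(Z[2, sel]))
        du = np.abs(Z[1, sel] - uint(Z[2, sel]))
        assert dc.max() < 0.05 and du.max() < 0.05
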