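"""Explicit reaction-diffusion scheme, OMZ detection and regime labels."""

import numpy as np
import pytest

from oxyplankton import (
    ModelParams,
    Grid1D,
    FieldState,
    SimulationOutput,
    find_coexistence,
    make_initial,
    step,
    simulate,
    detect_omz,
    classify_regime,
)
from oxyplankton.spatial import StabilityError, laplacian


@pytest.fixture(scope="module")
def stable_eq():
    p = ModelParams.baseline(mu1=0.0, mu2=0.41, epsilon=1.0)
    eq = [e for e in find_coexistence(p, grid=25) if e.stability == "stable"][-1]
    return p, eq.coords


class TestGridAndInitial:
    def test_default_grid(self):
        g = Grid1D()
        assert g.n == 501 and g.x[0] == 0.0 and g.x[-1] == 500.0

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            Grid1D(L=10.0, dx=1.0)

    def test_bump_perturbs_19_nodes(self, stable_eq):
        _, eq = stable_eq
        g = Grid1D()
        f = make_initial(g, eq, "eq_bump", half_width=10.0)
        perturbed = np.flatnonzero(f.c != eq[0])
        assert len(perturbed) == 19  # strict inequality |x - 250| < 10
        assert np.allclose(f.c[perturbed], eq[0] + 0.1)
        assert np.allclose(f.u[perturbed], eq[1] + 0.2)

    def test_zooplankton_starts_uniform(self, stable_eq):
        _, eq = stable_eq
        f = make_initial(Grid1D(), eq, "eq_bump")
        assert np.all(f.v == eq[2])

    def test_fields_equal_equilibrium_outside_window(self, stable_eq):
        _, eq = stable_eq
        g = Grid1D()
        f = make_initial(g, eq, "dip")
        outside = np.abs(g.x - 250.0) >= 10.0
        assert np.all(f.c[outside] == eq[0])
        assert np.all(f.u[outside] == eq[1])

    def test_dip_with_low_oxygen_rejected(self):
        with pytest.raises(ValueError):
            make_initial(Grid1D(), np.array([0.3, 1.0, 1.0]), "dip")


class TestStep:
    def test_stability_constraint_enforced(self, stable_eq):
        p, eq = stable_eq
        f = make_initial(Grid1D(L=50.0), eq, "eq_bump")
        with pytest.raises(StabilityError):
            step(f, p, D=5.0, dt=0.2, dx=1.0)

    def test_homogeneous_steady_state_is_fixed_point(self, stable_eq):
        p, eq = stable_eq
        g = Grid1D(L=50.0)
        f = FieldState(np.full(g.n, eq[0]), np.full(g.n, eq[1]), np.full(g.n, eq[2]))
        for _ in range(10_000):
            f = step(f, p, D=5.0, dt=0.01, dx=g.dx)
        assert np.max(np.abs(f.c - eq[0])) < 1e-10
        assert np.max(np.abs(f.u - eq[1])) < 1e-10
        assert np.max(np.abs(f.v - eq[2])) < 1e-10

    def test_zero_flux_keeps_uniform_fields_uniform(self, stable_eq):
        p, _ = stable_eq
        g = Grid1D(L=30.0)
        f = FieldState(np.full(g.n, 0.9), np.full(g.n, 1.1), np.full(g.n, 0.4))
        f = step(f, p, D=2.0, dt=0.01, dx=g.dx)
        for arr in (f.c, f.u, f.v):
            assert np.ptp(arr) == 0.0  # boundary nodes evolve like interior

    def test_pure_diffusion_conserves_trapezoidal_mass(self, stable_eq, rng):
        p, _ = stable_eq
        g = Grid1D(L=100.0)
        w = np.ones(g.n)
        w[0] = w[-1] = 0.5
        f = FieldState(rng.uniform(0.5, 1.5, g.n), rng.uniform(0.5, 1.5, g.n),
                       rng.uniform(0.5, 1.5, g.n))
        m0 = [w @ f.c, w @ f.u, w @ f.v]
        for i in range(100):
            f = step(f, p, D=5.0, dt=0.01, dx=g.dx, include_reaction=False)
            m = [w @ f.c, w @ f.u, w @ f.v]
            for a, b in zip(m0, m):
                assert abs(a - b) <= 1e-12 * (i + 1)

    def test_laplacian_of_linear_profile_vanishes_inside(self):
        x = np.linspace(0, 10, 21)
        lap = laplacian(2.0 * x + 1.0, dx=0.5)
        assert np.allclose(lap[1:-1], 0.0, atol=1e-12)


class TestDetectOMZ:
    def test_uniform_field_has_no_omz(self, stable_eq):
        _, eq = stable_eq
        g = Grid1D(L=100.0)
        f = FieldState(np.full(g.n, eq[0]), np.full(g.n, eq[1]), np.full(g.n, eq[2]))
        assert detect_omz(f, eq[0], grid=g).intervals == []

    def test_synthetic_dip_detected(self, stable_eq):
        _, eq = stable_eq
        g = Grid1D(L=100.0)
        c = np.full(g.n, eq[0])
        c[30:60] = 0.1 * eq[0]  # 30-node dip
        f = FieldState(c, np.full(g.n, eq[1]), np.full(g.n, eq[2]))
        rep = detect_omz(f, eq[0], grid=g)
        assert len(rep.intervals) == 1
        a, b = rep.intervals[0]
        assert b - a == pytest.approx(29.0, abs=1e-12)

    def test_anoxic_field_spans_domain(self):
        g = Grid1D(L=100.0)
        f = FieldState(np.zeros(g.n), np.zeros(g.n), np.zeros(g.n))
        rep = detect_omz(f, c_star=1.2, grid=g)
        assert rep.intervals == [(0.0, 100.0)]

    def test_parameter_validation(self):
        g = Grid1D(L=100.0)
        f = FieldState(np.zeros(g.n), np.zeros(g.n), np.zeros(g.n))
        with pytest.raises(ValueError):
            detect_omz(f, c_star=-1.0, grid=g)
        with pytest.raises(ValueError):
            detect_omz(f, c_star=1.0, theta=1.5, grid=g)


def _synthetic_output(c_blocks, eq, L=100.0, t_step=10.0):
    """Build a SimulationOutput from a list of oxygen snapshots."""
    g = Grid1D(L=L)
    snaps = [FieldState(c, np.full(g.n, eq[1]), np.full(g.n, eq[2]),
                        (i + 1) * t_step) for i, c in enumerate(c_blocks)]
    times = np.array([s.t for s in snaps])
    return SimulationOutput(
        grid=g, times=times, snapshots=snaps,
        mean_c=np.array([s.c.mean() for s in snaps]),
        mean_u=np.full(len(snaps), eq[1]), mean_v=np.full(len(snaps), eq[2]),
        params=ModelParams.baseline(mu1=0.1, mu2=0.1), D=1.0, dt=0.01,
        equilibrium=np.asarray(eq))


class TestClassifyRegime:
    EQ = np.array([1.2, 0.85, 0.86])

    def test_run_too_short_rejected(self):
        out = _synthetic_output([np.full(101, 1.2)] * 3, self.EQ)
        with pytest.raises(ValueError):
            classify_regime(out)

    def test_synthetic_labels(self):
        g = Grid1D(L=100.0)
        n, n_snap = g.n, 110
        x = g.x
        uniform = [np.full(n, 1.2) for _ in range(n_snap)]
        anoxic = [np.full(n, 1.2)] * (n_snap - 2) + [np.zeros(n)] * 2
        pattern = [1.2 + 0.5 * np.cos(0.3 * x) for _ in range(n_snap)]
        localized = [1.2 + 0.5 * np.cos(0.3 * x)
                     * np.exp(-((x - 50) / 5.0) ** 2) * (-1) ** i
                     for i in range(n_snap)]
        rng = np.random.default_rng(7)
        irregular = [1.2 + 0.5 * rng.standard_normal(n) for _ in range(n_snap)]
        assert classify_regime(_synthetic_output(uniform, self.EQ)) == "homogeneous_steady"
        assert classify_regime(_synthetic_output(anoxic, self.EQ)) == "global_anoxia"
        assert classify_regime(_synthetic_output(pattern, self.EQ)) == "stationary_pattern"
        assert classify_regime(_synthetic_output(localized, self.EQ)) == "localized_oscillation"
        assert classify_regime(_synthetic_output(irregular, self.EQ)) == "dynamic_irregular"


class TestSchemeConvergence:
    def test_halving_dt_changes_little(self, stable_eq):
        # short pattern-forming run: dt = 0.01 vs 0.005
        p, eq = stable_eq
        g = Grid1D(L=100.0)
        outs = [simulate(p, 5.0, g, dt=dt, T=100.0, save_every=100.0,
                         equilibrium=eq) for dt in (0.01, 0.005)]
        diff = np.max(np.abs(outs[0].snapshots[-1].c - outs[1].snapshots[-1].c))
        assert diff < 1e-3


class TestRegimeInvariants:
    def test_initial_condition_robustness(self):
        # sub-unity diffusivity ratio: raising or lowering the fields at the
        # center yields the same regime, the dip giving a wider early OMZ
        p = ModelParams.baseline(mu1=0.0, mu2=0.41, epsilon=1.0)
        g = Grid1D(L=200.0)
        results = {}
        for ic in ("eq_bump", "dip"):
            out = simulate(p, 0.5, g, T=1500.0, ic_variant=ic, save_every=10.0)
            i_early = int(np.argmin(np.abs(out.times - 50.0)))
            omz = detect_omz(out.snapshots[i_early], out.equilibrium[0], grid=g)
            results[ic] = (classify_regime(out), omz.total_width)
        assert results["eq_bump"][0] == results["dip"][0]
        assert results["dip"][1] >= results["eq_bump"][1]

    def test_sustainability_decreases_with_timescale_separation(self):
        # with both mortalities active, shrinking epsilon moves the system
        # from near-uniform dynamics through patterned states to anoxia,
        # never re-entering the homogeneous regime
        p = ModelParams.baseline(mu1=0.24, mu2=0.1575, epsilon=1.0)
        g = Grid1D(L=200.0)
        labels = []
        for eps in [1.0, 0.5, 0.2]:
            out = simulate(p.replace(epsilon=eps), 1.0, g, T=2000.0,
                           save_every=10.0)
            labels.append(classify_regime(out))
            if eps == 1.0:
                # no OMZ: only small fluctuations near the perturbation
                omz = detect_omz(out.snapshots[-1], out.equilibrium[0], grid=g)
                assert omz.total_width == 0.0
                outside = np.abs(g.x - 100.0) >= 15.0
                dev = np.abs(out.snapshots[-1].c[outside] / out.equilibrium[0] - 1.0)
                assert dev.max() < 0.10
        assert labels[-1] == "global_anoxia"
        left_homogeneous = False
        for lbl in labels:
            if lbl != "homogeneous_steady":
                left_homogeneous = True
            assert not (left_homogeneous and lbl == "homogeneous_steady")
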