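"""Mean-field model: vector field, nullclines, equilibria, Hopf scanning,
limit cycles, second-order reduction, and the Hill dose-response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syndrive import (MeanFieldParams, biphasic_detect, detect_limit_cycle,
                      find_equilibria, hill_probability, hopf_scan,
                      meanfield_rhs, nullclines, paper_fixture,
                      prop3_conditions, simulate_meanfield,
                      simulate_meanfield_second_order)

FIG3 = dict(a=10, b=9, c=6, d=1, vthE=-0.5, vthI=-2.5)

# Trace-zero (Hopf-candidate) locations for the reference parameter set,
# frozen from two independent oracles: Jacobian-trace bisection and
# long-horizon ODE integration of the flow (scipy and R/deSolve agree).
VTHE_CROSSINGS = (-1.2642, 0.2642)
LAMI_CROSSINGS = (0.8842, 1.8518)


def _p(**kw):
    return MeanFieldParams(**{**FIG3, **kw})


# ------------------------------------------------------------- vector field

def test_rhs_at_origin_is_pure_activation():
    p = _p()
    np.testing.assert_allclose(meanfield_rhs(p, (0.0, 0.0)),
                               [p.f(p.vthE), p.f(p.vthI)])


def test_rhs_matches_independent_evaluation():
    """Hand-coded logistic evaluation, independent of the package path."""
    p = _p()
    se, si = 0.5, 0.7
    f = lambda x: 1.0 / (1.0 + np.exp(-x))
    expected = [f(10 * se - 9 * si - 0.5) - se, f(6 * se - si - 2.5) - si]
    np.testing.assert_allclose(meanfield_rhs(p, (se, si)), expected, rtol=1e-12)


def test_rhs_vanishes_at_found_equilibria():
    for vthE in (-2.0, -0.5, 1.0):
        for eq in find_equilibria(_p(vthE=vthE)):
            assert np.max(np.abs(meanfield_rhs(_p(vthE=vthE), eq.point))) < 1e-10


# --------------------------------------------------------------- nullclines

def test_logistic_inverse_midpoint():
    assert nullclines(_p()).finv(0.5) == pytest.approx(0.0, abs=1e-14)


def test_inverse_domain_errors():
    nc = nullclines(_p())
    for bad in (0.0, 1.0, -0.1, 1.1):
        with pytest.raises(ValueError):
            nc.finv(bad)


def test_h_is_strictly_increasing():
    nc = nullclines(_p())
    s = np.linspace(1e-6, 1.0 - 1e-6, 1000)
    assert np.all(nc.hprime(s) > 0)


def test_g_slope_matches_finite_difference():
    nc = nullclines(_p())
    s = np.linspace(0.05, 0.95, 100)
    h = 1e-7
    fd = (nc.g(s + h) - nc.g(s - h)) / (2 * h)
    assert np.allclose(fd, nc.gprime(s), atol=1e-6, rtol=1e-6)


def test_hinv_inverts_h():
    nc = nullclines(_p())
    for si in (0.2, 0.5, 0.8):
        assert nc.hinv(float(nc.h(si))) == pytest.approx(si, abs=1e-10)


# -------------------------------------------------------------- equilibria

def test_unique_unstable_equilibrium_at_reference_parameters():
    eqs = find_equilibria(_p())
    assert len(eqs) == 1
    assert eqs[0].classification == "unstable"
    assert eqs[0].trace > 0 and eqs[0].det > 0


def test_low_threshold_gives_stable_equilibrium():
    eqs = find_equilibria(_p(vthE=-3.0))
    assert len(eqs) == 1
    assert eqs[0].classification == "stable"


def test_jacobian_matches_finite_differences():
    for vthE in (-3.0, -0.5, 1.0):
        p = _p(vthE=vthE)
        for eq in find_equilibria(p):
            h = 1e-7
            J_fd = np.empty((2, 2))
            for j in range(2):
                dx = np.zeros(2)
                dx[j] = h
                J_fd[:, j] = (meanfield_rhs(p, np.add(eq.point, dx))
                              - meanfield_rhs(p, np.subtract(eq.point, dx))) / (2 * h)
            assert np.allclose(eq.jacobian, J_fd, atol=1e-6)


def test_deep_suppression_fixed_point():
    """A very negative excitatory threshold pins the state near the
    fixed point of the decoupled iteration SE = lamE*f(...)."""
    p = _p(vthE=-20.0)
    traj = simulate_meanfield(p, (0.5, 0.5), (0, 60.0))
    se, si = traj.S[-1]
    # fixed-point iteration oracle
    xe, xi = 0.5, 0.5
    for _ in range(2000):
        xe, xi = p.lamE * p.f(p.a * xe - p.b * xi + p.vthE), \
                 p.lamI * p.f(p.c * xe - p.d * xi + p.vthI)
    assert se == pytest.approx(xe, abs=1e-6)
    assert si == pytest.approx(xi, abs=1e-6)
    assert se < 1e-6


# ------------------------------------------------------ closed-form conditions

def test_prop3_extrema_arithmetic():
    """a=10, gamma=f_max=lamE=1: extrema at (1 +/- sqrt(0.6))/2, where the
    E-nullcline slope vanishes."""
    p = _p()
    out = prop3_conditions(p)
    assert out["cond_a"]
    se_max, se_min = out["extrema"]
    assert se_max == pytest.approx((1 + np.sqrt(0.6)) / 2, abs=1e-12)
    assert se_min == pytest.approx((1 - np.sqrt(0.6)) / 2, abs=1e-12)
    nc = nullclines(p)
    assert abs(nc.gprime(se_max)) < 1e-8
    assert abs(nc.gprime(se_min)) < 1e-8


def test_prop3_cond_a_fails_for_weak_excitation():
    out = prop3_conditions(MeanFieldParams(a=1, b=9, c=6, d=1, vthE=0, vthI=0))
    assert not out["cond_a"] and out["extrema"] is None


def test_prop3_conditions_imply_unique_equilibrium(rng):
    """Across random parameter sets satisfying the three conditions, with
    thresholds centering the nullcline intersection, exactly one equilibrium
    exists and its determinant is positive."""
    checked = 0
    while checked < 100:
        a = rng.uniform(5, 15)
        b = rng.uniform(5, 12)
        c = rng.uniform(3, 9)
        d = rng.uniform(0.3, 2.0)
        # thresholds chosen so both nullclines pass through (0.5, 0.5)
        f_inv = lambda x: np.log(x / (1 - x))
        vthE = f_inv(0.5) - a * 0.5 + b * 0.5
        vthI = f_inv(0.5) - c * 0.5 + d * 0.5
        p = MeanFieldParams(a=a, b=b, c=c, d=d, vthE=vthE, vthI=vthI)
        out = prop3_conditions(p)
        if not (out["cond_a"] and out["cond_slope"] and out["cond_gap"]):
            continue
        checked += 1
        eqs = find_equilibria(p)
        assert len(eqs) == 1
        assert eqs[0].det > 0


# ------------------------------------------------------------- Hopf scanning

def test_hopf_scan_vthE_crossings():
    p = _p()
    scan = hopf_scan(p, "vthE", -3.0, 1.5)
    assert len(scan.crossings) == 2
    assert scan.crossings[0] == pytest.approx(VTHE_CROSSINGS[0], abs=1e-3)
    assert scan.crossings[1] == pytest.approx(VTHE_CROSSINGS[1], abs=1e-3)


def test_hopf_scan_lamI_crossings():
    scan = hopf_scan(_p(), "lamI", 0.5, 3.0)
    assert len(scan.crossings) == 2
    assert scan.crossings[0] == pytest.approx(LAMI_CROSSINGS[0], abs=1e-3)
    assert scan.crossings[1] == pytest.approx(LAMI_CROSSINGS[1], abs=1e-3)


def test_hopf_crossings_sit_on_the_stability_boundary():
    """At each reported crossing the trace vanishes, the determinant is
    positive, and the eigenvalues form a purely imaginary pair."""
    from dataclasses import replace
    p = _p()
    for name, lo, hi in (("vthE", -3.0, 1.5), ("lamI", 0.5, 3.0)):
        for v in hopf_scan(p, name, lo, hi).crossings:
            eq = find_equilibria(replace(p, **{name: v}))[0]
            assert abs(eq.trace) < 1e-6
            assert eq.det > 0
            assert np.all(np.abs(eq.eigenvalues.real) < 1e-6)
            assert np.all(np.abs(eq.eigenvalues.imag) > 0)


def test_scan_without_classification_change_reports_no_crossings():
    scan = hopf_scan(_p(), "vthE", -3.0, -2.0)
    assert scan.crossings == []
    assert all(c == "stable" for c in scan.classifications)


def test_classification_predicts_dynamics():
    """Stable grid points attract nearby trajectories; unstable ones (with
    positive determinant) produce a detectable limit cycle."""
    from dataclasses import replace
    p = _p()
    samples = ([("vthE", v) for v in (-2.5, -0.8, 0.0, 0.5, 1.0)]
               + [("lamI", v) for v in (0.6, 1.2, 1.6, 2.2, 2.8)])
    for name, v in samples:
        pv = replace(p, **{name: v})
        eq = find_equilibria(pv)[0]
        bx = pv.box
        start = np.clip(np.add(eq.point, 0.05), 0.01,
                        [bx[0] - 0.01, bx[1] - 0.01])
        traj = simulate_meanfield(pv, start, (0, 400.0), n_points=8001)
        cycle = detect_limit_cycle(traj)
        if eq.classification == "stable":
            assert not cycle["exists"]
            assert np.max(np.abs(traj.S[-1] - eq.point)) < 1e-3
        else:
            assert cycle["exists"]


# ------------------------------------------------------------ limit cycles

def test_reference_oscillation_detected():
    fx = paper_fixture("meanfield_fig3")
    traj = simulate_meanfield(fx["params"], fx["S0"], (0, 100.0))
    assert detect_limit_cycle(traj)["exists"]


def test_converging_trajectory_is_not_a_cycle():
    traj = simulate_meanfield(_p(vthE=-3.0), (0.5, 0.7), (0, 100.0))
    assert not detect_limit_cycle(traj)["exists"]


def test_period_of_synthetic_oscillation():
    t = np.linspace(0, 30.0, 6000)
    from syndrive import Trajectory
    S = np.stack([np.sin(2 * np.pi * t / 3.0), np.cos(2 * np.pi * t / 3.0)], axis=1)
    res = detect_limit_cycle(Trajectory(times=t, S=S))
    assert res["exists"] and res["period"] == pytest.approx(3.0, abs=0.02)


def test_box_invariance(rng):
    """Trajectories started inside [0, fmax*lamE] x [0, fmax*lamI] stay
    inside up to solver tolerance, for random parameters and starts."""
    for _ in range(20):
        p = MeanFieldParams(a=rng.uniform(0, 12), b=rng.uniform(0, 12),
                            c=rng.uniform(0, 12), d=rng.uniform(0, 4),
                            vthE=rng.uniform(-3, 2), vthI=rng.uniform(-3, 2),
                            lamE=rng.uniform(0.5, 2), lamI=rng.uniform(0.5, 2))
        bx = p.box
        S0 = [rng.uniform(0, bx[0]), rng.uniform(0, bx[1])]
        traj = simulate_meanfield(p, S0, (0, 30.0), n_points=601)
        assert traj.S[:, 0].min() >= -1e-7 and traj.S[:, 1].min() >= -1e-7
        assert traj.S[:, 0].max() <= bx[0] + 1e-7
        assert traj.S[:, 1].max() <= bx[1] + 1e-7


def test_corner_start_stays_inside_box():
    traj = simulate_meanfield(_p(), (0.0, 0.0), (0, 50.0))
    bx = _p().box
    assert traj.S.min() >= -1e-7
    assert traj.S[:, 0].max() <= bx[0] + 1e-7


# ------------------------------------------------- second-order mean field

def test_second_order_forced_to_zero_rate_is_critically_damped():
    """With the activation pinned at ~0 (deeply negative thresholds) each
    population follows the closed-form critically damped response."""
    p = MeanFieldParams(a=1, b=1, c=1, d=1, vthE=-700.0, vthI=-700.0,
                        lamE=2.0, lamI=3.0)
    t = np.linspace(0, 5.0, 501)
    traj = simulate_meanfield_second_order(p, (1.0, 0.5), (0.0, 0.2), (0, 5.0),
                                           t_eval=t)
    for j, (lam, s0, sd0) in enumerate([(2.0, 1.0, 0.0), (3.0, 0.5, 0.2)]):
        expected = (s0 + (sd0 + s0 / lam) * t) * np.exp(-t / lam)
        assert np.max(np.abs(traj.S[:, j] - expected)) < 1e-6


def test_second_order_reduction_matches_homogeneous_network():
    from syndrive import ActivationSpec, NeuronalNetwork, simulate_second_order
    nE, nI = 4, 3
    net = NeuronalNetwork(AEE=np.full((nE, nE), 0.6), AEI=np.full((nE, nI), -0.5),
                          AIE=np.full((nI, nE), 0.4), AII=np.full((nI, nI), -0.2),
                          lamE=[1.5] * nE, lamI=[2.0] * nI,
                          vthE=[-0.3] * nE, vthI=[-0.6] * nI,
                          activation=ActivationSpec("sigmoid", f_max=1.0, gamma=1.0))
    rng = np.random.default_rng(1)
    S0 = rng.uniform(0, 0.5, nE + nI)
    Sd0 = rng.uniform(-0.1, 0.3, nE + nI)
    traj_n = simulate_second_order(net, S0, Sd0, (0, 20.0), rtol=1e-10, atol=1e-12)
    p = MeanFieldParams(a=nE * 0.6, b=nI * 0.5, c=nE * 0.4, d=nI * 0.2,
                        vthE=-0.3, vthI=-0.6, lamE=1.5, lamI=2.0)
    traj_m = simulate_meanfield_second_order(
        p, [S0[:nE].mean(), S0[nE:].mean()], [Sd0[:nE].mean(), Sd0[nE:].mean()],
        (0, 20.0), rtol=1e-10, atol=1e-12, t_eval=traj_n.times)
    assert np.max(np.abs(traj_n.S[:, :nE].mean(axis=1) - traj_m.S[:, 0])) < 1e-5
    assert np.max(np.abs(traj_n.S[:, nE:].mean(axis=1) - traj_m.S[:, 1])) < 1e-5


def test_biphasic_mean_excitatory_response():
    """The second-order mean-field run shows the anesthetic biphasic
    signature: the mean excitatory drive overshoots, then is suppressed."""
    fx = paper_fixture("fig19")
    traj = simulate_meanfield_second_order(fx["params"], fx["S0"], fx["Sdot0"],
                                           (0, fx["t_end"]))
    res = biphasic_detect(traj, 0)
    assert res["overshoot"] and res["converged_to_zero"]
    assert res["peak_value"] > fx["S0"][0]


# ---------------------------------------------------------------- Hill curve

def test_hill_half_effect_concentration():
    assert hill_probability(2.0, 2.0, 6.0) == pytest.approx(0.5, abs=1e-15)
    assert hill_probability(0.0, 2.0, 6.0) == 0.0


def test_hill_log_domain_stability():
    """Steep curves match an independent log-domain evaluation."""
    C50, g = 3.0, 20.0
    C = 1.2 * C50
    expected = 1.0 / (1.0 + np.exp(-g * np.log(C / C50)))
    assert hill_probability(C, C50, g) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(c1=st.floats(0.0, 1e3), c2=st.floats(0.0, 1e3),
       c50=st.floats(1e-3, 1e3), g=st.floats(1.0, 25.0))
def test_hill_monotone_in_concentration(c1, c2, c50, g):
    lo, hi = sorted((c1, c2))
    assert hill_probability(lo, c50, g) <= hill_probability(hi, c50, g) + 1e-15


def test_hill_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        hill_probability(-1.0, 1.0, 6.0)
    with pytest.raises(ValueError):
        hill_probability(1.0, 0.0, 6.0)
    with pytest.raises(ValueError):
        hill_probability(1.0, 1.0, -2.0)
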