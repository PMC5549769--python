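import numpy as np
import pytest
from scipy.optimize import root

from isletburst import fastslow as fsm
from isletburst import model
from isletburst.params import ParameterSet, Variant


@pytest.fixture(scope="module")
def fs_kir(ko_kir):
    return fsm.FastSubsystem(ko_kir, "cinf", cer_clamp=200.0)


@pytest.fixture(scope="module")
def fs_leak(ko_leak):
    return fsm.FastSubsystem(ko_leak, "cer")


@pytest.fixture(scope="module")
def eq_branch(fs_kir):
    return fsm.equilibrium_continuation(fs_kir, (0.0, 1.0))


def test_mode_variant_contract(wt, ko_kir, ko_leak):
    with pytest.raises(ValueError):
        fsm.FastSubsystem(ko_leak, "cinf")
    with pytest.raises(ValueError):
        fsm.FastSubsystem(ko_kir, "cer")
    with pytest.raises(ValueError):
        fsm.FastSubsystem(wt, "orbit")


def test_equilibrium_branch_residuals(fs_kir, eq_branch):
    """Every continuation point is a genuine equilibrium."""
    assert len(eq_branch.p) > 20
    for x, pv in zip(eq_branch.X[::5], eq_branch.p[::5]):
        assert np.linalg.norm(fs_kir.rhs(x, pv)) < 1e-10


def test_equilibrium_branch_matches_voltage_parameterization(fs_kir, eq_branch):
    """Arclength continuation agrees with the closed-form branch."""
    pv, xv = fsm.equilibrium_curve_by_voltage(
        fs_kir, np.linspace(-74.5, -12, 1200))
    Vo = np.array([x[0] for x in xv])
    for x, p_c in zip(eq_branch.X[::7], eq_branch.p[::7]):
        if not 0.0 <= p_c <= 1.0 or x[0] < -73.5:
            continue  # skip the steep region near the K+ reversal asymptote
        k = np.argmin(np.abs(Vo - x[0]))
        assert abs(pv[k] - p_c) < 5e-3 * max(1.0, abs(p_c))


def test_brute_force_root_oracle(fs_kir, eq_branch, rng):
    """Continuation equilibria coincide with roots found by brute-force
    root-finding from many random seeds, to 1e-6 in V."""
    for pv in np.linspace(0.1, 0.9, 9):
        roots = []
        for _ in range(40):
            guess = np.array([rng.uniform(-75, -15), rng.uniform(0, 0.2),
                              rng.uniform(0, 0.6)])
            sol = root(lambda y: fs_kir.rhs(y, pv) * [1, 1e3, 1e3], guess,
                       method="hybr", tol=1e-13)
            if sol.success and np.linalg.norm(fs_kir.rhs(sol.x, pv)) < 1e-10:
                if not any(abs(r - sol.x[0]) < 1e-4 for r in roots):
                    roots.append(sol.x[0])
        near = np.abs(eq_branch.p - pv) < 5e-3
        branch_V = eq_branch.V[near]
        for rV in roots:
            if len(branch_V) and np.min(np.abs(branch_V - rV)) < 0.25:
                # same equilibrium: refine the branch point at exactly pv
                x0 = eq_branch.X[near][np.argmin(np.abs(branch_V - rV))]
                xs = fsm.find_equilibrium(fs_kir, pv, guess=x0)
                assert abs(xs[0] - rV) < 1e-6


def test_fold_detection_and_refinement(fs_kir, eq_branch):
    """Folds sit where dp/dV vanishes on the closed-form branch."""
    labels = fsm.detect_bifurcations(fs_kir, eq_branch)
    sns = [L for L in labels if L.kind == "SN"]
    assert len(sns) >= 1
    for L in sns:
        h = 1e-3
        p1, _ = fsm.equilibrium_curve_by_voltage(fs_kir, np.array([L.V - h]))
        p2, _ = fsm.equilibrium_curve_by_voltage(fs_kir, np.array([L.V + h]))
        pc, _ = fsm.equilibrium_curve_by_voltage(fs_kir, np.array([L.V]))
        # local extremum of the parameter along the branch
        assert (p1[0] - pc[0]) * (p2[0] - pc[0]) >= -1e-12


def test_stability_flags_agree_with_simulation(fs_kir, eq_branch):
    """Perturbed stable equilibria return; unstable ones depart."""
    stable_idx = np.where(eq_branch.stable)[0]
    unstable_idx = np.where(~eq_branch.stable)[0]
    checked = 0
    for idx_set, expect_return in ((stable_idx, True), (unstable_idx, False)):
        for i in idx_set[:: max(len(idx_set) // 3, 1)][:3]:
            x0, pv = eq_branch.X[i], eq_branch.p[i]
            # skip near-marginal points where either outcome is slow
            if abs(np.max(eq_branch.eigs[i].real)) < 1e-4:
                continue
            xp = x0 + np.array([0.5, 0, 0])
            d0 = np.linalg.norm((xp - x0) * [1 / 50, 1, 1])
            xT = fs_kir.flow(xp, pv, 60_000.0)
            dT = np.linalg.norm((xT - x0) * [1 / 50, 1, 1])
            if expect_return:
                assert dT < 0.3 * d0
            else:
                assert dT > 2.0 * d0
            checked += 1
    assert checked >= 2


@pytest.fixture(scope="module")
def cycle_branch(fs_kir):
    return fsm.periodic_continuation(fs_kir, (0.0, 1.0), 0.05, direction=+1,
                                     max_points=60)


def test_cycle_branch_closure_and_trivial_multiplier(fs_kir, cycle_branch):
    """Shooting orbits close up and carry the trivial Floquet multiplier."""
    br = cycle_branch
    assert len(br.p) > 5
    k = len(br.p) // 2
    x0, T, pv = br.X0[k], br.T[k], br.p[k]
    xT = fs_kir.flow(x0, pv, T, rtol=1e-12)
    assert np.linalg.norm((xT - x0) * [1 / 50, 1, 1]) < 1e-5
    # one multiplier equals 1 (flow direction) wherever the cycle is not
    # degenerating into the homoclinic limit
    checked = 0
    for T, mu in zip(br.T[1:-1], br.multipliers[1:-1]):
        if T < 2.2 * br.T[0]:
            assert np.min(np.abs(mu - 1.0)) < 1e-6
            checked += 1
    assert checked >= 3


def test_cycle_amplitudes_bracket_voltage(cycle_branch):
    assert np.all(cycle_branch.Vmax > cycle_branch.Vmin)
    assert np.all(cycle_branch.T > 0)


def test_classify_blowup_snic_vs_hc(fs_kir):
    """Classification logic: terminal parameter at a fold gives SNIC,
    interior to the fold interval gives a homoclinic label."""
    folds = [fsm.LabeledPoint("SN", 0.10, -66.0),
             fsm.LabeledPoint("SN", 0.80, -35.0)]
    p_tail = np.linspace(0.05, 0.0995, 12)
    T_tail = 100.0 / np.sqrt(0.1 - p_tail + 1e-4)
    mk = lambda p, T: fsm.PeriodicBranch(
        p, np.zeros((len(p), 3)), T, np.full(len(p), -60.0),
        np.full(len(p), -20.0), np.ones((len(p), 3), complex),
        np.ones(len(p), bool), "period_blowup")
    snic = fsm.classify_blowup(fs_kir, mk(p_tail, T_tail), folds)
    assert snic.kind == "SNIC"
    p_int = np.linspace(0.2, 0.45, 12)
    hc = fsm.classify_blowup(fs_kir, mk(p_int, T_tail), folds)
    assert hc.kind == "HC"


def test_cer_nullcline_identity(ko_leak):
    Vg = np.linspace(-70, -20, 40)
    cer, c = fsm.cer_nullcline(Vg, ko_leak)
    # along the curve the ER fluxes balance
    np.testing.assert_allclose(ko_leak.kleak * (cer - c),
                               ko_leak.kSERCA * c, rtol=1e-10)


def test_cinf_slow_curve_monotone_in_amp(ko_kir):
    Vg = np.linspace(-70, -30, 25)
    lo = fsm.cinf_slow_curve(Vg, 20.0, 200.0, ko_kir)
    hi = fsm.cinf_slow_curve(Vg, 200.0, 200.0, ko_kir)
    m = np.isfinite(lo) & np.isfinite(hi)
    assert m.sum() > 10
    assert np.all(hi[m] <= lo[m] + 1e-12)


def test_cinf_slow_curve_residuals(ko_kir):
    Vg = np.array([-65.0, -55.0, -45.0])
    for V in Vg:
        camp = model.camp_steady_state(V, 60.0, 200.0, ko_kir)
        ci = max(model.ciss(V, 200.0, ko_kir), 0.0)
        res = model.v_ac(ci, 60.0, ko_kir) - model.v_pde(ci, camp, ko_kir)
        assert abs(res) < 1e-10


def test_overlay_trajectory_projections(ko_trace):
    x, V = fsm.overlay_trajectory(ko_trace, "cinf")
    assert x.shape == V.shape == ko_trace["V"].shape
    assert np.all((x >= 0) & (x <= 1))
    with pytest.raises(ValueError):
        fsm.overlay_trajectory(ko_trace, "phase")
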