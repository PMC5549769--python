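import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq, root

from isletburst import model
from isletburst.model import StateVector
from isletburst.params import Variant


# ---------------------------------------------------------------------------
# gating / activation functions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("c, Kc, expected", [
    (0.5, 0.5, 0.5),           # half-activation by construction
    (0.0, 0.5, 0.0),
    (1.5, 0.5, 0.9),           # 9/(9+1)
])
def test_kca_activation_values(c, Kc, expected):
    assert model.kca_activation(c, Kc) == pytest.approx(expected)


def test_kca_activation_rejects_bad_input():
    with pytest.raises(ValueError):
        model.kca_activation(-0.1, 0.5)
    with pytest.raises(ValueError):
        model.kca_activation(0.1, 0.0)


def test_kir_block_values():
    assert model.kir_block(-50.0, -50.0, 10.0) == pytest.approx(0.5)
    assert model.kir_block(-500.0, -50.0, 10.0) == pytest.approx(1.0, abs=1e-12)
    # algebraic inversion: V = VKir + sKir ln 9 gives 10% conduction
    assert model.kir_block(-50.0 + 10.0 * np.log(9), -50.0, 10.0) == pytest.approx(0.1)


def test_kir_camp_activation_values():
    a, b, K = 0.08, 0.9, 0.5
    assert model.kir_camp_activation(0.0, a, b, K) == pytest.approx(a)
    assert model.kir_camp_activation(K, a, b, K) == pytest.approx(a + b / 2)
    assert model.kir_camp_activation(10 * K, a, b, K) == pytest.approx(
        a + b, abs=1.01e-4 * b)


@settings(max_examples=100, deadline=None)
@given(V=st.floats(-120, 40), c=st.floats(0, 10), camp=st.floats(0, 50))
def test_gating_functions_bounded(V, c, camp):
    assert 0.0 <= model.kca_activation(c, 0.5) < 1.0
    assert 0.0 < model.kir_block(V, -50.0, 10.0) < 1.0
    ci = model.kir_camp_activation(camp, 0.08, 0.9, 0.5)
    assert 0.08 <= ci < 0.98 + 1e-12


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def test_currents_vanish_at_reversal(wt, ko_kir, ko_leak):
    VK = wt.VK
    assert model.current_k(VK, 0.3, wt) == 0.0
    assert model.current_kca(VK, 0.3, wt) == 0.0
    assert model.current_kir(VK, 1.0, ko_kir) == 0.0
    assert model.current_leak(VK, ko_leak) == 0.0
    ATP, AMP = model.atp_amp_from_adp(500.0, wt)
    assert model.current_katp(VK, ATP, 500.0, wt) == 0.0
    assert model.current_ca(wt.VCa, wt) == 0.0


def test_kir_current_composition(ko_kir):
    V, camp = -55.0, 0.6
    p = ko_kir
    expected = (p.gKir * model.kir_block(V, p.VKir, p.sKir)
                * model.kir_camp_activation(camp, p.alpha_camp, p.beta_camp, p.Kcamp)
                * (V - p.VK))
    assert model.current_kir(V, camp, p) == pytest.approx(expected, rel=1e-14)


def test_kir_magnitude_monotone_in_camp_below_vk(ko_kir):
    V = ko_kir.VK - 10.0
    camps = np.linspace(0, 5, 30)
    mags = np.abs(model.current_kir(V, camps, ko_kir))
    assert np.all(np.diff(mags) > 0)


def test_leak_current_linear(ko_leak):
    V = np.array([-80.0, -60.0, -40.0])
    I = model.current_leak(V, ko_leak)
    assert np.allclose(I, ko_leak.gleak * (V - ko_leak.VK))


def test_katp_conductance_strictly_positive(wt, rng):
    ADP = rng.uniform(1, 990, 200)
    ATP, _ = model.atp_amp_from_adp(ADP, wt)
    assert np.all(model.katp_open_fraction(ATP, ADP, wt) > 0)


def test_variant_contract_violations(wt, ko_kir, ko_leak):
    with pytest.raises(ValueError):
        model.current_kir(-60.0, 0.5, wt)
    with pytest.raises(ValueError):
        model.current_katp(-60.0, 2000.0, 500.0, ko_kir)
    with pytest.raises(ValueError):
        model.current_leak(-60.0, ko_kir)
    with pytest.raises(ValueError):
        model.current_kir(-60.0, 0.5, ko_leak)


# ---------------------------------------------------------------------------
# nucleotides
# ---------------------------------------------------------------------------

def test_nucleotide_conservation_and_equilibrium(wt, rng):
    ADP = rng.uniform(1.0, wt.Atot / 3.0 - 1.0, 1000)
    ATP, AMP = model.atp_amp_from_adp(ADP, wt)
    assert np.all(ATP >= 0) and np.all(AMP >= 0)
    np.testing.assert_allclose(ATP + ADP + AMP, wt.Atot, rtol=1e-12)
    np.testing.assert_allclose(AMP * ATP, ADP ** 2, rtol=1e-10)


# ---------------------------------------------------------------------------
# cAMP turnover
# ---------------------------------------------------------------------------

def test_vpde_zero_without_camp(wt):
    assert model.v_pde(0.2, 0.0, wt) == 0.0


def test_vac_amp_half_inhibition(wt):
    c = 0.15
    full = model.v_ac(c, 0.0, wt)
    half = model.v_ac(c, wt.Kamp, wt)
    assert half == pytest.approx(full / 2, rel=1e-12)


def test_vpde_calcium_factor_half_saturation(wt):
    # at c = KPDEca the Ca2+ factor equals alphaPDE + betaPDE/2
    camp = 1.0
    v = model.v_pde(wt.KPDEca, camp, wt)
    base = wt.vPDE_bar * camp / (camp + wt.KPDEcamp)
    assert v / base == pytest.approx(wt.alphaPDE + wt.betaPDE / 2, rel=1e-12)


def test_vac_monotone_decreasing_in_amp(wt):
    amps = np.linspace(0, 500, 50)
    vals = model.v_ac(0.2, amps, wt)
    assert np.all(np.diff(vals) < 0)


def test_camp_steady_state_is_balance_point(wt):
    camp_ss = model.camp_steady_state(-60.0, 80.0, 150.0, wt)
    ci = model.ciss(-60.0, 150.0, wt)
    residual = model.v_ac(ci, 80.0, wt) - model.v_pde(ci, camp_ss, wt)
    assert abs(residual) < 1e-10 * model.v_ac(ci, 80.0, wt)


def test_camp_steady_state_matches_root_finder(wt, rng):
    """Closed-form steady state equals a bracketed root of the cAMP balance."""
    for _ in range(20):
        V = rng.uniform(-75, -20)
        AMP = rng.uniform(5, 400)
        cer = rng.uniform(50, 300)
        ss = model.camp_steady_state(V, AMP, cer, wt)
        ci = max(model.ciss(V, cer, wt), 0.0)
        f = lambda ca: model.v_ac(ci, AMP, wt) - model.v_pde(ci, ca, wt)
        oracle = brentq(f, 0.0, 1e4, xtol=1e-14, rtol=1e-14)
        assert ss == pytest.approx(oracle, rel=1e-8)


def test_ciss_independent_of_cer_without_leak(wt):
    p0 = wt.replace(kleak=1e-300)  # kleak must stay positive; effectively zero
    a = model.ciss(-55.0, 50.0, p0)
    b = model.ciss(-55.0, 400.0, p0)
    assert a == pytest.approx(b, rel=1e-9)


# ---------------------------------------------------------------------------
# the vector field
# ---------------------------------------------------------------------------

def _random_state(rng):
    return np.array([
        rng.uniform(-80, -10), rng.uniform(0, 1), rng.uniform(0.01, 1.0),
        rng.uniform(5, 500), rng.uniform(10, 15000), rng.uniform(0.01, 120),
        rng.uniform(5, 900), rng.uniform(0.01, 5.0)])


def test_rhs_finite_on_random_states(wt, ko_kir, ko_leak, rng):
    for p in (wt, ko_kir, ko_leak):
        for _ in range(300):
            dy = model.rhs(0.0, _random_state(rng), p)
            assert np.all(np.isfinite(dy))


def test_rhs_rejects_bad_state(wt):
    with pytest.raises(ValueError):
        model.rhs(0.0, np.full(8, np.nan), wt)
    with pytest.raises(ValueError):
        model.rhs(0.0, np.ones(5), wt)


def test_calcium_decay_with_pumps_only(wt):
    """With ER fluxes removed and no Ca2+ entry, dc/dt = -fcyt*kpmca*c."""
    p = wt.replace(kleak=1e-300, kSERCA=1e-300, gCa=1e-300)
    y = np.array([-60.0, 0.1, 0.3, 100.0, 1000.0, 1.0, 500.0, 0.5])
    dy = model.rhs(0.0, y, p)
    assert dy[2] == pytest.approx(-p.fcyt * p.kpmca * 0.3, rel=1e-6)
    assert dy[2] < 0


def test_ciss_is_calcium_balance_fixed_point(wt, rng):
    """Setting c to its steady state makes the cytosolic flux sum vanish."""
    for _ in range(10):
        V = rng.uniform(-75, -20)
        cer = rng.uniform(20, 400)
        c = model.ciss(V, cer, wt)
        if c < 0:
            continue
        y = np.array([V, 0.1, c, cer, 1000.0, 1.0, 500.0, 0.5])
        dy = model.rhs(0.0, y, wt)
        # dc/dt contains exactly the bracketed flux sum scaled by fcyt
        assert abs(dy[2]) < 1e-12
        assert abs(dy[3]) > 0 or True  # cer need not balance here


def test_er_balance_zeroes_dcer(wt):
    cer = 300.0
    c = cer * wt.kleak / (wt.kleak + wt.kSERCA)
    y = np.array([-60.0, 0.1, c, cer, 1000.0, 1.0, 500.0, 0.5])
    dy = model.rhs(0.0, y, wt)
    assert dy[3] == pytest.approx(0.0, abs=1e-15)


def test_pfk_flux_positive_and_bounded(wt, rng):
    F6P = rng.uniform(1, 20000, 200)
    FBP = rng.uniform(0.001, 200, 200)
    ATP, AMP = model.atp_amp_from_adp(rng.uniform(10, 900, 200), wt)
    J = model.pfk_flux(F6P, FBP, ATP, AMP, wt)
    assert np.all(J > 0)
    assert np.all(J < wt.vPFK)


def test_state_vector_invariants():
    with pytest.raises(ValueError):
        StateVector(-60, 1.2, 0.1, 100, 100, 1, 500, 0.5)
    with pytest.raises(ValueError):
        StateVector(-60, 0.5, -0.1, 100, 100, 1, 500, 0.5)
    sv = StateVector(-60, 0.5, 0.1, 100, 100, 1, 500, 0.5)
    assert StateVector.from_array(sv.to_array()) == sv
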