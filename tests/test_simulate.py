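import numpy as np
import pytest
from scipy.optimize import root

from isletburst import (Protocol, Variant, apply_tg, camp_clamp_event,
                        integrate, model, param_set_event, tg_event)
from isletburst.simulate import ProtocolEvent, default_initial_state


def test_apply_tg_divides_serca(wt):
    p = wt.replace(kSERCA=0.4)
    assert apply_tg(p, 4.0).kSERCA == pytest.approx(0.1)
    assert apply_tg(p, 1.0).kSERCA == pytest.approx(0.4)  # identity
    with pytest.raises(ValueError):
        apply_tg(p, 0.5)


def test_protocol_validation():
    with pytest.raises(ValueError):
        Protocol([tg_event(30.0), tg_event(20.0)])  # not increasing
    with pytest.raises(ValueError):
        ProtocolEvent(10.0, "FREEZE")
    with pytest.raises(ValueError):
        ProtocolEvent(10.0, "CAMP_CLAMP", value=-1.0)
    proto = Protocol([tg_event(30.0)])
    with pytest.raises(ValueError):
        proto.validate_span(20.0)


def test_protocol_parse():
    proto = Protocol.parse("tg:60:4,clamp:90:5.0,set:120:JGK:0.14")
    assert [e.action for e in proto.events] == ["TG", "CAMP_CLAMP", "PARAM_SET"]
    assert proto.events[0].factor == 4.0
    assert proto.events[1].value == 5.0
    assert proto.events[2].name == "JGK"


def test_integration_is_deterministic(ko_kir):
    tr1 = integrate(ko_kir, 3.0, dt_out_ms=100.0)
    tr2 = integrate(ko_kir, 3.0, dt_out_ms=100.0)
    np.testing.assert_array_equal(tr1.states, tr2.states)


def test_compiled_and_reference_integrators_agree(ko_kir):
    """The in-package Runge-Kutta kernel tracks scipy's stiff solver."""
    init = default_initial_state(ko_kir)
    tr1 = integrate(ko_kir, 2.0, init=init, rtol=1e-10, transient_min=0.0)
    tr2 = integrate(ko_kir, 2.0, init=init, rtol=1e-10, transient_min=0.0,
                    method="LSODA")
    assert np.allclose(tr1["V"], tr2["V"], atol=0.5)
    assert np.allclose(tr1["c"], tr2["c"], atol=5e-3)


def test_camp_clamp_masks_derivative(ko_kir):
    proto = Protocol([camp_clamp_event(1.0, 2.5)])
    tr = integrate(ko_kir, 3.0, protocol=proto, transient_min=0.0)
    post = tr.epoch_mask("post:cAMP=2.5", discard_transient=False)
    assert np.allclose(tr["cAMP"][post][1:], 2.5, atol=1e-12)


def test_param_set_events_compose(ko_kir):
    """Two PARAM_SET events applied in sequence equal one combined set."""
    two = Protocol([param_set_event(1.0, "JGK", 0.12),
                    param_set_event(1.5, "kgpdh", 0.12)])
    one = Protocol([param_set_event(1.5, "JGK", 0.12)])
    init = default_initial_state(ko_kir)
    tr2 = integrate(ko_kir, 3.0, init=init, protocol=two, transient_min=0.0)
    # after the second event both parameters are active in tr2; simulate the
    # combined set directly from tr2's state at that event time
    k = np.searchsorted(tr2.time_min, 1.5)
    p_comb = ko_kir.replace(JGK=0.12, kgpdh=0.12)
    tr_direct = integrate(p_comb, 1.5, init=tr2.states[k], transient_min=0.0)
    np.testing.assert_allclose(tr_direct.states[-1], tr2.states[-1],
                               rtol=1e-5, atol=1e-7)


def test_epochs_partition_span(ko_kir):
    proto = Protocol([tg_event(1.0), camp_clamp_event(2.0, 1.0)])
    tr = integrate(ko_kir, 3.0, protocol=proto, transient_min=0.0)
    labels = tr.epoch_label()
    assert not any(l is None for l in labels)
    starts = [e[0] for e in tr.epochs]
    ends = [e[1] for e in tr.epochs]
    assert starts == [0.0, 1.0, 2.0] and ends == [1.0, 2.0, 3.0]


def test_silent_without_calcium_current(ko_kir):
    """Removing I_Ca leaves a hyperpolarized electrical steady state that
    matches a direct equilibrium solve of the membrane equations (the
    glycolytic subsystem keeps cycling and is held at its late values)."""
    p = ko_kir.replace(gCa=1e-300)
    tr = integrate(p, 40.0, transient_min=0.0)
    late = tr.states[-1]
    assert tr["V"][-100:].std() < 1e-3          # settled membrane
    assert late[0] < -65.0                      # hyperpolarized

    def membrane(y3):
        y = late.copy()
        y[:3] = y3
        return model.rhs(0.0, y, p)[:3] * np.array([1.0, 1e3, 1e3])

    sol = root(membrane, late[:3], method="hybr", tol=1e-12)
    assert sol.success
    np.testing.assert_allclose(late[:3], sol.x, rtol=1e-3, atol=1e-7)


def test_trace_csv_roundtrip(tmp_path, ko_kir):
    tr = integrate(ko_kir, 2.0, transient_min=0.0)
    f = tmp_path / "trace.csv"
    tr.to_csv(f)
    import json
    import pandas as pd
    df = pd.read_csv(f)
    assert "V" in df and "epoch" in df and "g_Kir" in df
    np.testing.assert_allclose(df["c"].to_numpy(), tr["c"], rtol=1e-6)
    meta = json.loads(f.with_suffix(".csv.json").read_text())
    assert meta["variant"] == "KO_KIR21"
    assert meta["param_digest"] == ko_kir.digest()


def test_integration_failure_reports_time(wt):
    bad = wt.replace(Cm=1e-9)  # absurd capacitance blows the step size
    with pytest.raises(RuntimeError, match="min"):
        integrate(bad, 5.0, transient_min=0.0)
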