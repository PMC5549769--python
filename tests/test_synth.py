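import numpy as np
import pytest

from isletburst.metrics import burst_stats, segment_active_phases
from isletburst.synth import (CohortSummary, FuraTrace, ParseError,
                              cohort_summary, detect_onset, generate_cohort,
                              generate_synthetic_fura, parse_trace_file,
                              write_trace_file)


def recover(tr: FuraTrace, epoch="pre"):
    t, x = tr.epoch(epoch) if tr.onset_min is not None else (tr.time_min, tr.ratio)
    seg = segment_active_phases(t, x)
    return burst_stats(seg, t, x)


def test_noiseless_trace_recovers_generating_parameters():
    tr = generate_synthetic_fura(7.0, 0.4, noise_sd=0.0, seed=1, t_span_min=70.0)
    st = recover(tr)
    assert st.period_min == pytest.approx(7.0, abs=0.02)
    assert st.duty_cycle == pytest.approx(0.4, abs=0.02)
    assert st.classification == "slow_bursting"


def test_same_seed_reproducible_different_seed_differs():
    a = generate_synthetic_fura(7.0, 0.4, noise_sd=0.05, seed=7)
    b = generate_synthetic_fura(7.0, 0.4, noise_sd=0.05, seed=7)
    c = generate_synthetic_fura(7.0, 0.4, noise_sd=0.05, seed=8)
    np.testing.assert_array_equal(a.ratio, b.ratio)
    assert not np.array_equal(a.ratio, c.ratio)


def test_generator_input_validation():
    with pytest.raises(ValueError):
        generate_synthetic_fura(7.0, 1.2, seed=1)      # duty outside (0,1)
    with pytest.raises(ValueError):
        generate_synthetic_fura(7.0, 0.4, seed=None)   # seed mandatory
    with pytest.raises(ValueError):
        generate_synthetic_fura(-1.0, 0.4, seed=1)


def test_er_decline_lowers_late_plateau():
    flat = generate_synthetic_fura(8.0, 0.5, er_decline=0.0, seed=3,
                                   t_span_min=8.0)
    dec = generate_synthetic_fura(8.0, 0.5, er_decline=0.4, seed=3,
                                  t_span_min=8.0)
    # the plateau declines toward its end; without the ER signature it is flat
    early = (flat.time_min > 0.5) & (flat.time_min < 1.0)
    late = (flat.time_min > 3.0) & (flat.time_min < 3.6)
    assert flat.ratio[late].mean() == pytest.approx(flat.ratio[early].mean(),
                                                    abs=0.02)
    assert dec.ratio[late].mean() < dec.ratio[early].mean() - 0.15
    assert dec.ratio[late].mean() < flat.ratio[late].mean() - 0.2


def test_trace_file_roundtrip_bitexact(tmp_path):
    traces = [generate_synthetic_fura(6.0 + k, 0.4, noise_sd=0.03, seed=k,
                                      islet_id=f"islet{k}") for k in range(3)]
    f = tmp_path / "cohort.txt"
    write_trace_file(f, traces)
    back = parse_trace_file(f)
    assert len(back) == 3
    for orig, rt in zip(traces, back):
        np.testing.assert_array_equal(rt.ratio, orig.ratio)
        np.testing.assert_allclose(rt.time_min, orig.time_min, atol=1e-12)


def test_parser_layout_detection(tmp_path):
    f = tmp_path / "data.txt"
    f.write_text("time\tislet_a\tislet_b\tislet_c\n"
                 + "".join(f"{60*i}\t{1+0.1*i}\t{2.0}\t{1.5}\n" for i in range(30)))
    traces = parse_trace_file(f)
    assert len(traces) == 3
    assert traces[0].meta["delimiter"] == "tab"
    assert traces[0].meta["header_lines"] == 1
    # time column was in seconds; converted to minutes
    assert traces[0].meta["time_unit_detected"] == "s"
    assert traces[0].time_min[-1] == pytest.approx(29.0)


def test_parser_errors_name_the_line(tmp_path):
    f = tmp_path / "ragged.txt"
    f.write_text("0\t1.0\t1.0\n1\t1.1\n")
    with pytest.raises(ParseError, match="ragged"):
        parse_trace_file(f)
    g = tmp_path / "nonmono.txt"
    g.write_text("0\t1.0\n2\t1.1\n1\t1.2\n")
    with pytest.raises(ParseError, match="non-monotonic"):
        parse_trace_file(g)
    h = tmp_path / "cell.txt"
    h.write_text("0\t1.0\n1\tabc\n")
    with pytest.raises(ParseError, match="non-numeric"):
        parse_trace_file(h)


def test_identical_persisting_cohort_counts():
    traces = [
        generate_synthetic_fura(
            7.0, 0.4, noise_sd=0.0, seed=k, t_span_min=75.0,
            treatment={"onset_min": 30.0, "new_period": 7.0, "new_duty": 0.4},
            islet_id=f"i{k}")
        for k in range(10)
    ]
    summ = cohort_summary(traces)
    assert summ.pre_period_mean == pytest.approx(7.0, abs=0.05)
    assert summ.pre_period_sd == pytest.approx(0.0, abs=0.05)
    assert summ.n_persistent == 10
    assert summ.n_converted == 0 and summ.n_terminated == 0


def test_terminating_cohort_counts():
    traces = generate_cohort(6, seed=11, response="terminate")
    summ = cohort_summary(traces)
    assert summ.n_terminated == 6


def test_counts_partition_cohort(rng):
    traces = (generate_cohort(4, seed=21, response="persist")
              + generate_cohort(3, seed=22, response="convert")
              + generate_cohort(2, seed=23, response="terminate"))
    # one junk trace that must be excluded (too short for 2 cycles)
    junk = generate_synthetic_fura(25.0, 0.4, seed=5, t_span_min=75.0,
                                   treatment={"onset_min": 30.0, "terminate": True},
                                   islet_id="junk")
    summ = cohort_summary(traces + [junk])
    assert (summ.n_persistent + summ.n_converted + summ.n_terminated
            + summ.n_excluded) == 10
    assert summ.n_excluded >= 1


def test_cohort_statistics_recover_distribution():
    """Truncated-normal cohort means land within two standard errors."""
    traces = generate_cohort(10, seed=42, period_mean=7.3, period_sd=1.2,
                             duty_mean=0.4, duty_sd=0.08, response="persist")
    summ = cohort_summary(traces)
    assert abs(summ.pre_period_mean - 7.3) < 2 * 1.2 / np.sqrt(10) + 0.2
    assert abs(summ.pre_duty_mean - 0.4) < 2 * 0.08 / np.sqrt(10) + 0.03


def test_detect_onset_near_truth():
    tr = generate_synthetic_fura(
        7.0, 0.4, noise_sd=0.03, seed=9, t_span_min=75.0,
        treatment={"onset_min": 30.0, "terminate": True})
    assert abs(detect_onset(tr) - 30.0) < 3.0


def test_summary_invariant_to_trace_order():
    traces = generate_cohort(6, seed=33, response="persist")
    a = cohort_summary(traces)
    b = cohort_summary(list(reversed(traces)))
    assert a.pre_period_mean == pytest.approx(b.pre_period_mean)
    assert a.n_persistent == b.n_persistent


def test_summary_json(tmp_path):
    traces = generate_cohort(4, seed=3, response="persist")
    summ = cohort_summary(traces)
    f = tmp_path / "s.json"
    summ.to_json(f)
    import json
    doc = json.loads(f.read_text())
    assert doc["n_persistent"] == summ.n_persistent
    assert len(doc["table"]) == len(summ.table)
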