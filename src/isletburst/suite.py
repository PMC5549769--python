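"""One-command regeneration of every figure-level result with a pass/fail
report.

Each stage emits its data products (trace CSVs, burst statistics, diagram
JSON) stamped with the parameter digest and package version, and the report
records a set of scientific assertions: bursting classes, the c/cAMP phase
relation, the Kir-conductance phasing, fast-subsystem diagram topology
(bistable or not, SNIC vs homoclinic termination), and the virtual
thapsigargin / 8-Br-cAMP outcomes per variant.  Stage failures are recorded
and independent stages still run.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path

import numpy as np

from . import __version__, fastslow as fsm
from .metrics import (burst_stats, moving_average, phase_relation,
                      segment_active_phases)
from .params import ParameterSet, Variant
from .simulate import (Protocol, Trace, apply_tg, camp_clamp_event, integrate,
                       tg_event)

log = logging.getLogger(__name__)

__all__ = ["run_paper_suite", "trace_burst_stats", "run_variant"]


def trace_burst_stats(tr: Trace, epoch: str | None = None,
                      discard_min: float | None = None,
                      signal: str = "c", smooth_s: float = 12.0,
                      reference_range=None):
    """Burst statistics of a simulated trace (smoothed to suppress spikes)."""
    if epoch is not None:
        m = tr.epoch_mask(epoch)
    else:
        m = np.ones(len(tr.time_ms), dtype=bool)
    if discard_min is None:
        discard_min = tr.transient_min
    start = tr.time_min[m].min() + discard_min if epoch and not epoch.startswith("pre") \
        else discard_min
    m &= tr.time_min >= max(start, tr.transient_min if epoch in (None, "pre") else 0)
    t = tr.time_min[m]
    x = tr[signal][m]
    dt_s = float(np.median(np.diff(t))) * 60.0
    xs = moving_average(x, dt_s, window_s=smooth_s)
    seg = segment_active_phases(t, xs)
    st = burst_stats(seg, t, xs, reference_range=reference_range)
    if not seg.phases:
        # no slow-timescale phases: retry with a fast-bursting configuration
        # (light smoothing, short minimum phase duration)
        xf = moving_average(x, dt_s, window_s=2.0)
        seg_f = segment_active_phases(t, xf, min_duration_min=0.05)
        st_f = burst_stats(seg_f, t, xf, reference_range=reference_range)
        if (st_f.period_min is not None and st_f.period_min < 1.0
                and st_f.n_cycles >= 3):
            return st_f, seg_f, (t, xf)
    return st, seg, (t, xs)


def _camp_declines_at_onsets(tr: Trace, seg, discard_min: float) -> bool:
    """Does cAMP fall over the first ~30 s of each Ca2+ plateau?"""
    t = tr.time_min
    camp = tr["cAMP"]
    drops = []
    for onset, _ in seg.phases:
        m = (t >= onset) & (t <= onset + 0.5)
        if m.sum() >= 3:
            drops.append(camp[m][-1] - camp[m][0])
    return len(drops) >= 2 and np.median(drops) < 0


def _gkir_peaks_in_silent(tr: Trace, seg, discard_min: float) -> bool:
    """Smoothed Kir conductance should peak inside silent phases."""
    t = tr.time_min
    dt_s = float(np.median(np.diff(t))) * 60.0
    g = moving_average(tr["g_Kir"], dt_s, window_s=6.0)
    hits = total = 0
    phases = seg.phases
    for (on1, off1), (on2, _) in zip(phases[:-1], phases[1:]):
        m = (t >= off1) & (t <= on2)          # silent gap
        mc = (t >= on1) & (t <= on2)          # full cycle
        if m.sum() < 3 or mc.sum() < 6:
            continue
        total += 1
        tmax = t[mc][np.argmax(g[mc])]
        # the smoothed-Ca offset marker lags the electrical transition by
        # about the smoothing window; allow that much slack
        if off1 - 0.2 <= tmax <= on2:
            hits += 1
    return total >= 2 and hits >= 0.8 * total


def run_variant(variant: Variant, outdir: Path, t_span: float = 110.0,
                tg_span: float = 200.0, tg_at: float = 80.0,
                clamp_level_factor: float = 10.0,
                do_fastslow: bool = True, quick: bool = False) -> dict:
    """All stages for one variant; returns {checks, artifacts, errors}."""
    checks: list[dict] = []
    artifacts: dict[str, str] = {}
    errors: list[str] = []
    p = ParameterSet.default(variant)
    outdir.mkdir(parents=True, exist_ok=True)
    if quick:
        t_span, tg_span, tg_at = 70.0, 160.0, 65.0

    def check(name, passed, **info):
        checks.append({"name": f"{variant.value}:{name}",
                       "passed": bool(passed), **info})

    def stage(name, fn):
        try:
            fn()
        except Exception as exc:                # noqa: BLE001
            errors.append(f"{variant.value}:{name}: {exc}")
            log.error("%s stage %s failed:\n%s", variant.value, name,
                      traceback.format_exc())

    state: dict = {}

    # --- baseline bursting ------------------------------------------------
    def baseline():
        tr = integrate(p, t_span)
        f = outdir / f"{variant.value.lower()}_baseline.csv"
        tr.to_csv(f)
        artifacts["baseline_trace"] = str(f)
        st, seg, (t, xs) = trace_burst_stats(tr)
        state["baseline"] = (tr, st, seg)
        check("slow_bursting", st.classification == "slow_bursting",
              period_min=st.period_min, duty=st.duty_cycle)
        m = tr.time_min >= tr.transient_min
        if variant is Variant.WT_KATP:
            check("camp_declines_at_plateau_onset",
                  _camp_declines_at_onsets(tr, seg, tr.transient_min))
        if variant is Variant.KO_KIR21:
            lag = phase_relation(tr.time_min[m], xs_interp(tr, "c", m),
                                 xs_interp(tr, "cAMP", m))
            check("c_camp_antiphase", 0.4 <= lag <= 0.6, lag=lag)
            check("gkir_peaks_in_silent_phase",
                  _gkir_peaks_in_silent(tr, seg, tr.transient_min))

    def xs_interp(tr, name, m):
        t = tr.time_min[m]
        dt_s = float(np.median(np.diff(t))) * 60.0
        return moving_average(tr[name][m], dt_s, window_s=12.0)

    stage("baseline", baseline)

    # --- thapsigargin -----------------------------------------------------
    def tg():
        proto = Protocol([tg_event(tg_at, 4.0)])
        tr = integrate(p, tg_span, protocol=proto)
        f = outdir / f"{variant.value.lower()}_tg.csv"
        tr.to_csv(f)
        artifacts["tg_trace"] = str(f)
        pre, seg_pre, _ = trace_burst_stats(tr, epoch="pre")
        post, _, _ = trace_burst_stats(
            tr, epoch=f"post:TG/4", discard_min=15.0,
            reference_range=seg_pre.signal_range)
        state["tg"] = (pre, post)
        if variant is Variant.KO_KIR21:
            ok = (post.classification == "slow_bursting"
                  and pre.period_min and post.period_min
                  and post.period_min > pre.period_min)
            check("tg_bursting_persists_period_up", ok,
                  pre_period=pre.period_min, post_period=post.period_min)
        elif variant is Variant.KO_LEAK_KCA:
            check("tg_converts_to_fast_bursting",
                  post.classification in ("fast_bursting", "continuous_spiking"),
                  post_class=post.classification, post_period=post.period_min)
        else:
            mpost = tr.epoch_mask("post:TG/4")
            mpre = tr.epoch_mask("pre") & (tr.time_min >= tr.transient_min)
            elevated = tr["c"][mpost].mean() > tr["c"][mpre].mean()
            check("tg_continuous_or_fast_elevated",
                  post.classification in ("fast_bursting", "continuous_spiking")
                  and elevated,
                  post_class=post.classification, elevated=bool(elevated))

    stage("tg", tg)

    # --- 8-Br-cAMP (cAMP clamp) ------------------------------------------
    def clamp():
        if variant is Variant.KO_LEAK_KCA:
            return
        level = clamp_level_factor * p.Kcamp
        proto = Protocol([camp_clamp_event(tg_at, level)])
        tr = integrate(p, tg_span, protocol=proto)
        f = outdir / f"{variant.value.lower()}_camp_clamp.csv"
        tr.to_csv(f)
        artifacts["clamp_trace"] = str(f)
        pre, seg_pre, _ = trace_burst_stats(tr, epoch="pre")
        label = f"post:cAMP={level:g}"
        post, _, _ = trace_burst_stats(tr, epoch=label, discard_min=15.0,
                                       reference_range=seg_pre.signal_range)
        if variant is Variant.KO_KIR21:
            mpost = tr.epoch_mask(label)
            low_c = tr["c"][mpost][-100:].mean() < 0.1
            check("camp_clamp_silences", post.classification == "silent"
                  and low_c, post_class=post.classification)
        else:
            # matched-window control: the same span without the clamp
            ctrl = integrate(p, tg_span)
            mwin = (ctrl.time_min >= tg_at) & (ctrl.time_min <= tg_span)
            t0 = float(ctrl.time_min[mwin].min())
            from .metrics import burst_stats as _bs, segment_active_phases as _seg
            tc = ctrl.time_min[mwin & (ctrl.time_min >= t0 + 15.0)]
            xc = ctrl["c"][mwin & (ctrl.time_min >= t0 + 15.0)]
            dt_s = float(np.median(np.diff(tc))) * 60.0
            xcs = moving_average(xc, dt_s, 12.0)
            ctrl_stats = _bs(_seg(tc, xcs), tc, xcs)
            ok = (post.classification == "slow_bursting"
                  and ctrl_stats.period_min and post.period_min
                  and abs(post.period_min - ctrl_stats.period_min)
                  < 0.05 * ctrl_stats.period_min)
            check("camp_clamp_no_effect", ok, control_period=ctrl_stats.period_min,
                  post_period=post.period_min)

    stage("clamp", clamp)

    # --- fast/slow diagrams ----------------------------------------------
    def diagrams():
        if variant is Variant.WT_KATP or not do_fastslow:
            return
        if variant is Variant.KO_KIR21:
            tr = state["baseline"][0]
            m = tr.time_min >= tr.transient_min
            cer_mean = float(tr["cer"][m].mean())
            fs = fsm.FastSubsystem(p, "cinf", cer_clamp=cer_mean)
            diag = fsm.compute_diagram(fs, (0.0, 8.0), cycle_start=0.05)
            f = outdir / "ko_kir21_diagram.json"
            diag.to_json(f)
            artifacts["diagram"] = str(f)
            kinds = {L.kind for L in diag.labels}
            sns = [L for L in diag.labels if L.kind == "SN"]
            check("zcurve_two_folds", len(sns) >= 2,
                  n_folds=len(sns))
            check("has_hopf", "HB" in kinds)
            check("cycle_ends_in_snic", "SNIC" in kinds,
                  labels=sorted(kinds))
            check("no_bistable_interval", diag.bistable_interval is None,
                  interval=diag.bistable_interval)
        else:
            fs = fsm.FastSubsystem(p, "cer")
            diag = fsm.compute_diagram(fs, (0.0, 450.0), cycle_start=60.0)
            f = outdir / "ko_leak_kca_diagram.json"
            diag.to_json(f)
            artifacts["diagram"] = str(f)
            kinds = {L.kind for L in diag.labels}
            check("bistable_interval_present",
                  diag.bistable_interval is not None,
                  interval=diag.bistable_interval)
            check("cycle_ends_homoclinic", "HC" in kinds,
                  labels=sorted(kinds))
            # SERCA block: period-doubling cascade on the spiking branch
            ptg = apply_tg(p, 4.0)
            fs2 = fsm.FastSubsystem(ptg, "cer")
            diag2 = fsm.compute_diagram(fs2, (0.0, 120.0), cycle_start=12.0,
                                        follow_pd=True)
            f2 = outdir / "ko_leak_kca_tg_diagram.json"
            diag2.to_json(f2)
            artifacts["tg_diagram"] = str(f2)
            n_pd = sum(1 for L in diag2.labels if L.kind == "PD")
            check("tg_period_doubling_cascade", n_pd >= 1, n_pd=n_pd)

    stage("diagrams", diagrams)

    return {"checks": checks, "artifacts": artifacts, "errors": errors}


def run_paper_suite(outdir: Path, variants=None, seed: int = 12345,
                    quick: bool = False) -> dict:
    """Run every variant's stages plus the synthetic-cohort statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants = variants or [Variant.WT_KATP, Variant.KO_KIR21,
                            Variant.KO_LEAK_KCA]
    report: dict = {"version": __version__, "seed": seed, "checks": [],
                    "errors": [], "artifacts": {}}
    for v in variants:
        res = run_variant(v, outdir / v.value.lower(), quick=quick)
        report["checks"].extend(res["checks"])
        report["errors"].extend(res["errors"])
        report["artifacts"][v.value] = res["artifacts"]
        for ps in (ParameterSet.default(v),):
            report["artifacts"].setdefault("param_digests", {})[v.value] = ps.digest()

    # synthetic cohorts mirroring the experimental arms
    from .synth import cohort_summary, generate_cohort
    rng = np.random.default_rng(seed)
    arms = {
        "ko_tg": dict(n=10, response="persist", genotype="SUR1KO", agent="TG",
                      period_mean=7.3, period_sd=1.2, duty_mean=0.4,
                      duty_sd=0.08, post_period_mean=7.6, post_period_sd=1.1,
                      post_duty_mean=0.6, post_duty_sd=0.06),
        "wt_tg": dict(n=13, response="convert", genotype="WT", agent="TG",
                      period_mean=10.6, period_sd=0.9, duty_mean=0.5,
                      duty_sd=0.06, onset_min=40.0, t_span_min=100.0),
        "ko_8brcamp": dict(n=9, response="terminate", genotype="SUR1KO",
                           agent="8BrcAMP", period_mean=7.3, period_sd=1.2,
                           duty_mean=0.4, duty_sd=0.08),
    }
    cohorts = {}
    for name, kw in arms.items():
        traces = generate_cohort(seed=int(rng.integers(0, 2**31 - 1)), **kw)
        summ = cohort_summary(traces)
        summ.to_json(outdir / f"cohort_{name}.json")
        cohorts[name] = summ
    report["checks"].append({
        "name": "cohort:ko_tg_all_persist",
        "passed": cohorts["ko_tg"].n_persistent == 10,
        "n_persistent": cohorts["ko_tg"].n_persistent})
    report["checks"].append({
        "name": "cohort:ko_8brcamp_all_terminate",
        "passed": cohorts["ko_8brcamp"].n_terminated == 9,
        "n_terminated": cohorts["ko_8brcamp"].n_terminated})
    report["checks"].append({
        "name": "cohort:wt_tg_convert",
        "passed": cohorts["wt_tg"].n_converted >= 13,
        "n_converted": cohorts["wt_tg"].n_converted})
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=float))
    return report
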