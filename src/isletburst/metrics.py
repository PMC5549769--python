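"""Burst-trace analytics: segmentation, period/duty statistics, phase lags.

All functions operate on plain arrays (time in minutes) so they apply
equally to simulated Ca2+/voltage traces and to experimental fura-2 ratio
recordings.  Thresholds are expressed as fractions of the per-epoch signal
range, which makes every statistic invariant to affine rescaling of the
signal — fura ratio units are arbitrary, and treatments change baseline
and amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "BurstSegmentation", "BurstStats", "segment_active_phases", "burst_stats",
    "moving_average", "spike_average_voltage", "phase_relation",
    "estimate_period",
]


@dataclass
class BurstSegmentation:
    """Active phases of a bursting signal found by hysteresis thresholding."""

    phases: list[tuple[float, float]]      # (onset_min, offset_min), complete phases
    threshold_low: float                   # absolute units
    threshold_high: float
    signal_range: tuple[float, float]      # robust (low, high) used for thresholds
    flat: bool = False
    leading_partial: bool = False          # signal already active at window start
    trailing_partial: bool = False         # still active at window end

    @property
    def onsets(self) -> np.ndarray:
        return np.array([p[0] for p in self.phases])

    @property
    def durations(self) -> np.ndarray:
        return np.array([p[1] - p[0] for p in self.phases])


@dataclass
class BurstStats:
    """Per-trace oscillation descriptors over one treatment epoch."""

    period_min: float | None
    period_sd: float | None
    duty_cycle: float | None
    n_cycles: int
    classification: str                    # slow_bursting | fast_bursting | continuous_spiking | silent
    mean_level: float
    rel_mean: float                        # mean position within the reference range
    cycles: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    thresholds: tuple[float, float] = (np.nan, np.nan)
    flags: list[str] = field(default_factory=list)


def _robust_range(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, [1.0, 99.0])
    return float(lo), float(hi)


def segment_active_phases(
    time_min: np.ndarray,
    signal: np.ndarray,
    hysteresis_low: float = 0.4,
    hysteresis_high: float = 0.6,
    min_duration_min: float = 0.5,
    noise_floor: float = 1e-3,
    noise_floor_abs: float = 0.0,
) -> BurstSegmentation:
    """Hysteresis segmentation of elevated ("active") phases.

    Onset = upward crossing of the high threshold, offset = downward
    crossing of the low threshold; both thresholds are fractions of the
    robust per-window signal range.  Phases shorter than
    ``min_duration_min`` are discarded.  A window whose range is below the
    noise floor (relative to its magnitude) yields an empty segmentation.
    """
    t = np.asarray(time_min, dtype=float)
    x = np.asarray(signal, dtype=float)
    if t.shape != x.shape or t.ndim != 1:
        raise ValueError("time and signal must be 1-D arrays of equal length")
    if not 0.0 <= hysteresis_low < hysteresis_high <= 1.0:
        raise ValueError("need 0 <= hysteresis_low < hysteresis_high <= 1")
    lo, hi = _robust_range(x)
    rng = hi - lo
    scale = max(abs(lo), abs(hi), 1e-300)
    if rng <= max(noise_floor * scale, noise_floor_abs):
        return BurstSegmentation([], np.nan, np.nan, (lo, hi), flat=True)
    thr_lo = lo + hysteresis_low * rng
    thr_hi = lo + hysteresis_high * rng

    phases: list[tuple[float, float]] = []
    active = x[0] >= thr_hi
    leading = active
    start = t[0] if active else np.nan
    for k in range(1, len(x)):
        if not active and x[k - 1] < thr_hi <= x[k]:
            # linear interpolation of the crossing time
            f = (thr_hi - x[k - 1]) / (x[k] - x[k - 1])
            start = t[k - 1] + f * (t[k] - t[k - 1])
            active = True
        elif active and x[k - 1] > thr_lo >= x[k]:
            f = (thr_lo - x[k - 1]) / (x[k] - x[k - 1])
            end = t[k - 1] + f * (t[k] - t[k - 1])
            if not np.isnan(start):
                phases.append((start, end))
            elif leading:
                pass  # partial leading phase: onset unknown, dropped
            active = False
            start = np.nan
    trailing = active
    phases = [p for p in phases if p[1] - p[0] >= min_duration_min]
    # leading flag only meaningful if the partial phase was long enough to count
    return BurstSegmentation(phases, thr_lo, thr_hi, (lo, hi),
                             leading_partial=leading, trailing_partial=trailing)


def burst_stats(
    seg: BurstSegmentation,
    time_min: np.ndarray,
    signal: np.ndarray,
    fast_period_min: float = 1.0,
    reference_range: tuple[float, float] | None = None,
    silent_rel_mean: float = 0.35,
) -> BurstStats:
    """Period, duty cycle and a total classification from a segmentation.

    Period is the mean onset-to-onset interval (onsets are sharp in
    relaxation-type oscillations); duty cycle is mean active duration over
    the period.  Classification: ``silent`` (no active phases, mean low in
    the reference range), ``continuous_spiking`` (no sub-threshold returns
    but elevated mean), ``fast_bursting`` (period < ``fast_period_min``),
    else ``slow_bursting``.  The reference range defaults to this epoch's
    own robust range; pass the pre-treatment range when classifying a
    post-treatment epoch so "elevated" keeps its meaning after baseline
    shifts.
    """
    x = np.asarray(signal, dtype=float)
    mean_level = float(np.mean(x))
    ref = reference_range if reference_range is not None else seg.signal_range
    ref_rng = max(ref[1] - ref[0], 1e-300)
    rel_mean = (mean_level - ref[0]) / ref_rng
    flags: list[str] = []
    # against an external reference (e.g. the pre-treatment epoch), an
    # amplitude collapse means quiescence even if tiny drifts cross the
    # epoch-relative thresholds
    if reference_range is not None:
        own = seg.signal_range[1] - seg.signal_range[0]
        if own < 0.05 * ref_rng:
            seg = BurstSegmentation([], seg.threshold_low, seg.threshold_high,
                                    seg.signal_range, flat=True)
            flags.append("amplitude_collapse")

    onsets = seg.onsets
    n_cycles = max(len(onsets) - 1, 0)
    period = period_sd = duty = None
    cycles = pd.DataFrame()
    if len(onsets) >= 2:
        intervals = np.diff(onsets)
        period = float(np.mean(intervals))
        period_sd = float(np.std(intervals, ddof=1)) if len(intervals) > 1 else 0.0
        duty = float(np.mean(seg.durations[:-1] / intervals)) if len(intervals) else None
        cycles = pd.DataFrame({
            "onset_min": onsets[:-1],
            "offset_min": [p[1] for p in seg.phases[:-1]],
            "duration_min": seg.durations[:-1],
            "period_min": intervals,
        })
        cycles["duty_cycle"] = cycles["duration_min"] / cycles["period_min"]
    elif len(onsets) == 1:
        flags.append("single_cycle")

    if seg.flat or not seg.phases:
        # no oscillation: quiescent if the level sits low in the reference
        # range, sustained activity ("no sub-threshold returns") if elevated
        cls = "silent" if rel_mean < silent_rel_mean else "continuous_spiking"
    elif period is None:
        # one complete phase only: decide on elevation; a lone leading
        # transient in an otherwise low signal is quiescence
        dur = seg.durations.sum()
        span = float(np.asarray(time_min)[-1] - np.asarray(time_min)[0])
        if rel_mean >= 0.6:
            cls = "continuous_spiking"
        elif rel_mean < silent_rel_mean and dur < 0.3 * span:
            cls = "silent"
        else:
            cls = "slow_bursting"
        flags.append("period_undefined")
    elif period < fast_period_min:
        cls = "fast_bursting"
    else:
        cls = "slow_bursting"
    if duty is not None and not 0.0 <= duty <= 1.0:
        flags.append("duty_out_of_range")
        duty = min(max(duty, 0.0), 1.0)
    return BurstStats(period, period_sd, duty, n_cycles, cls, mean_level,
                      rel_mean, cycles, (seg.threshold_low, seg.threshold_high),
                      flags)


def moving_average(signal: np.ndarray, dt_s: float, window_s: float = 6.0) -> np.ndarray:
    """Centered moving mean with edge-shrinking window.

    Used on conductance series (e.g. the Kir2.1 conductance) to filter out
    fast voltage-dependent changes and expose the slow, cAMP-driven
    component.
    """
    x = np.asarray(signal, dtype=float)
    n = max(int(round(window_s / dt_s)), 1)
    if n % 2 == 0:
        n += 1
    if n <= 1:
        return x.copy()
    return (pd.Series(x).rolling(n, center=True, min_periods=1).mean()).to_numpy()


def spike_average_voltage(
    time_min: np.ndarray,
    V: np.ndarray,
    prominence_mv: float = 5.0,
) -> tuple[np.ndarray, dict]:
    """Per-spike mean voltage, exposing the slow burst envelope.

    Spikes are local V maxima above a prominence threshold; each spike's
    span runs between the local minima flanking the peak and is replaced
    by its mean voltage.  Samples outside spikes pass through.  With no
    detected spikes the voltage is returned unchanged and flagged.
    """
    t = np.asarray(time_min, dtype=float)
    v = np.asarray(V, dtype=float)
    peaks, _ = find_peaks(v, prominence=prominence_mv)
    if len(peaks) == 0:
        return v.copy(), {"n_spikes": 0, "no_spikes": True}
    troughs, _ = find_peaks(-v, prominence=prominence_mv / 2)
    out = v.copy()
    bounds = np.concatenate(([0], troughs, [len(v) - 1]))
    for pk in peaks:
        left = bounds[bounds <= pk].max()
        right = bounds[bounds >= pk].min()
        if right > left:
            out[left:right + 1] = v[left:right + 1].mean()
    return out, {"n_spikes": int(len(peaks)), "no_spikes": False}


def estimate_period(time_min: np.ndarray, x: np.ndarray) -> float | None:
    """Oscillation period (min) from the first autocorrelation maximum."""
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(x, dtype=float)
    y = y - y.mean()
    if np.allclose(y, 0):
        return None
    dt = float(np.median(np.diff(t)))
    acf = np.correlate(y, y, mode="full")[len(y) - 1:]
    acf /= acf[0]
    # first local max after the acf first dips below zero
    below = np.where(acf < 0)[0]
    if len(below) == 0:
        return None
    start = below[0]
    pk, _ = find_peaks(acf[start:])
    if len(pk) == 0:
        return None
    return float((start + pk[0]) * dt)


def phase_relation(
    time_min: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    period_tol: float = 0.10,
) -> float:
    """Relative lag of ``y`` behind ``x`` as a fraction of the period.

    Both signals must oscillate with matching periods (within
    ``period_tol``); the lag is the circular cross-correlation peak
    normalized by the period, in [0, 1).  Anti-phase signals give ≈ 0.5.
    """
    t = np.asarray(time_min, dtype=float)
    px = estimate_period(t, x)
    py = estimate_period(t, y)
    if px is None or py is None:
        raise ValueError("non-oscillatory input: no period detected")
    if abs(px - py) > period_tol * max(px, py):
        raise ValueError(f"period mismatch: {px:.3g} vs {py:.3g} min")
    period = 0.5 * (px + py)
    dt = float(np.median(np.diff(t)))
    nper = int(round(period / dt))
    xd = np.asarray(x, float) - np.mean(x)
    yd = np.asarray(y, float) - np.mean(y)
    # circular cross-correlation over exactly the lags within one period
    nwin = (len(xd) // nper) * nper
    if nwin == 0:
        raise ValueError("signal shorter than one period")
    xd, yd = xd[:nwin], yd[:nwin]
    lags = np.arange(nper)
    cc = np.array([np.dot(xd, np.roll(yd, -lag)) for lag in lags])
    return float(lags[np.argmax(cc)] / nper)
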