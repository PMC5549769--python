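"""Time integration of the model with timed treatment protocols.

A :class:`Protocol` is an ordered list of events applied at stated times:
thapsigargin (kSERCA divided by a factor), a cAMP clamp (the degradation-
resistant analogue 8-Br-cAMP modelled as holding cAMP constant, i.e. its
derivative is masked to zero), or an arbitrary named parameter change.
Events are handled by stopping and restarting the integrator at the event
time — the discontinuity is never smoothed or interpolated across.

Simulation is deterministic by construction: no randomness anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import _kernels, model
from .model import STATE_NAMES, StateVector, pack_params
from .params import PARAM_ORDER, ParameterSet, Variant

__all__ = [
    "ProtocolEvent", "Protocol", "Trace", "integrate",
    "apply_tg", "tg_event", "camp_clamp_event", "param_set_event",
    "default_initial_state",
]

MS_PER_MIN = 60_000.0

# absolute tolerances scaled to the typical magnitude of each variable
DEFAULT_ATOL = np.array([1e-6, 1e-10, 1e-10, 1e-5, 1e-5, 1e-7, 1e-5, 1e-9])


@dataclass(frozen=True)
class ProtocolEvent:
    """One timed action: 'TG', 'CAMP_CLAMP' or 'PARAM_SET'."""

    time_min: float
    action: str
    factor: float | None = None      # TG
    value: float | None = None       # CAMP_CLAMP / PARAM_SET
    name: str | None = None          # PARAM_SET

    def __post_init__(self) -> None:
        if self.action not in ("TG", "CAMP_CLAMP", "PARAM_SET"):
            raise ValueError(f"unknown protocol action {self.action!r}")
        if self.action == "TG" and not (self.factor or 0) >= 1:
            raise ValueError("TG factor must be >= 1")
        if self.action == "CAMP_CLAMP" and not (self.value is not None and self.value >= 0):
            raise ValueError("cAMP clamp level must be >= 0")
        if self.action == "PARAM_SET" and (self.name is None or self.value is None):
            raise ValueError("PARAM_SET needs 'name' and 'value'")

    @property
    def label(self) -> str:
        if self.action == "TG":
            return f"TG/{self.factor:g}"
        if self.action == "CAMP_CLAMP":
            return f"cAMP={self.value:g}"
        return f"{self.name}={self.value:g}"


def tg_event(time_min: float, factor: float = 4.0) -> ProtocolEvent:
    """Thapsigargin: divide the SERCA pump rate by ``factor``."""
    return ProtocolEvent(time_min, "TG", factor=factor)


def camp_clamp_event(time_min: float, value: float) -> ProtocolEvent:
    """8-Br-cAMP: hold cAMP at ``value`` (μM) from the event time on."""
    return ProtocolEvent(time_min, "CAMP_CLAMP", value=value)


def param_set_event(time_min: float, name: str, value: float) -> ProtocolEvent:
    return ProtocolEvent(time_min, "PARAM_SET", name=name, value=value)


@dataclass
class Protocol:
    events: list[ProtocolEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time_min for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    def validate_span(self, t_span_min: float) -> None:
        for e in self.events:
            if not 0.0 < e.time_min < t_span_min:
                raise ValueError(
                    f"event at {e.time_min} min outside simulation span (0, {t_span_min})")

    @classmethod
    def parse(cls, spec: str) -> "Protocol":
        """Parse compact CLI syntax, e.g. ``'tg:60:4,clamp:90:5.0'``."""
        events = []
        if spec:
            for item in spec.split(","):
                parts = item.split(":")
                kind = parts[0].lower()
                t = float(parts[1])
                if kind == "tg":
                    events.append(tg_event(t, float(parts[2]) if len(parts) > 2 else 4.0))
                elif kind == "clamp":
                    events.append(camp_clamp_event(t, float(parts[2])))
                elif kind == "set":
                    events.append(param_set_event(t, parts[2], float(parts[3])))
                else:
                    raise ValueError(f"unknown protocol item {item!r}")
        return cls(events)


def apply_tg(p: ParameterSet, factor: float = 4.0) -> ParameterSet:
    """Parameter set with kSERCA divided by ``factor`` (thapsigargin)."""
    if not factor >= 1:
        raise ValueError("factor must be >= 1")
    return p.replace(kSERCA=p.kSERCA / factor)


@dataclass
class Trace:
    """Time-stamped model evolution with derived series and epoch labels."""

    time_ms: np.ndarray
    states: np.ndarray                      # (n, 8)
    params: ParameterSet
    epochs: list[tuple[float, float, str]]  # (start_min, end_min, label)
    transient_min: float = 0.0
    meta: dict = field(default_factory=dict)
    derived: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.time_ms) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trace contains non-finite states")
        if not self.derived:
            self.derived = model.derived_series(self.states, self.params)

    # -- convenience access --------------------------------------------
    @property
    def time_min(self) -> np.ndarray:
        return self.time_ms / MS_PER_MIN

    def __getitem__(self, name: str) -> np.ndarray:
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name)]
        return self.derived[name]

    @property
    def variant(self) -> Variant:
        return self.params.variant

    def epoch_label(self) -> np.ndarray:
        labels = np.empty(len(self.time_ms), dtype=object)
        tmin = self.time_min
        for start, end, label in self.epochs:
            labels[(tmin >= start) & (tmin <= end)] = label
        return labels

    def epoch_mask(self, label: str, discard_transient: bool = True) -> np.ndarray:
        for start, end, lab in self.epochs:
            if lab == label:
                m = (self.time_min >= start) & (self.time_min <= end)
                if discard_transient:
                    m &= self.time_min >= self.transient_min
                return m
        raise KeyError(f"no epoch labelled {label!r}")

    # -- i/o -------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_min": self.time_min})
        for i, nm in enumerate(STATE_NAMES):
            df[nm] = self.states[:, i]
        for nm, series in self.derived.items():
            df[nm] = series
        df["epoch"] = self.epoch_label()
        return df

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {
                "variant": self.variant.value,
                "param_digest": self.params.digest(),
                "transient_min": self.transient_min,
                "epochs": self.epochs,
                **self.meta,
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2))


def default_initial_state(p: ParameterSet) -> StateVector:
    """Initial condition near a low-activity rest state.

    A damped root solve of the full vector field from a hyperpolarized
    guess; the result is nudged off the exact equilibrium so trajectories
    do not sit on an unstable fixed point, and simulations mark a
    transient-discard window anyway.
    """
    guess = np.array([-65.0, 0.0002, 0.1, 150.0, 150.0, 2.0, 700.0, 0.4])
    packed = pack_params(p)
    dy = np.empty(8)

    def f(y):
        _kernels.rhs(0.0, y, packed, dy)
        return dy * np.array([1.0, 1e3, 1e3, 10.0, 10.0, 1e2, 1.0, 1e3])

    sol = root(f, guess, method="hybr")
    y = sol.x if sol.success else guess
    y[0] += 1.0  # leave the fixed point
    y = np.clip(y, [ -90, 0, 1e-4, 1e-3, 1e-3, 1e-4, 1e-3, 1e-4], None)
    return StateVector.from_array(y)


def _segments(t_span_min: float, protocol: Protocol | None):
    events = protocol.events if protocol else []
    bounds = [0.0] + [e.time_min for e in events] + [t_span_min]
    labels = ["pre"] + [f"post:{e.label}" for e in events]
    return bounds, labels, events


def integrate(
    p: ParameterSet,
    t_span_min: float,
    init: StateVector | Sequence[float] | None = None,
    protocol: Protocol | None = None,
    dt_out_ms: float = 100.0,
    rtol: float = 1e-8,
    atol: np.ndarray | None = None,
    transient_min: float = 20.0,
    method: str = "dopri5",
    max_step_ms: float | None = None,
) -> Trace:
    """Integrate the model over ``t_span_min`` minutes and annotate epochs.

    ``method`` is ``'dopri5'`` (compiled adaptive Runge–Kutta, default) or
    any stiff-capable scipy method name ('LSODA', 'Radau', 'BDF') for
    cross-checks.  Protocol events restart the integration at the event
    time with the modified parameters.
    """
    if protocol:
        protocol.validate_span(t_span_min)
    if init is None:
        init = default_initial_state(p)
    y = init.to_array() if isinstance(init, StateVector) else np.asarray(init, float).copy()
    atol = DEFAULT_ATOL if atol is None else np.asarray(atol, float)
    max_step = dt_out_ms if max_step_ms is None else max_step_ms

    bounds, labels, events = _segments(t_span_min, protocol)
    current = p
    camp_clamp: float | None = None
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    epochs: list[tuple[float, float, str]] = []

    for k in range(len(bounds) - 1):
        t0, t1 = bounds[k] * MS_PER_MIN, bounds[k + 1] * MS_PER_MIN
        if k > 0:
            ev = events[k - 1]
            if ev.action == "TG":
                current = apply_tg(current, ev.factor)
            elif ev.action == "PARAM_SET":
                current = current.replace(**{ev.name: ev.value})
            elif ev.action == "CAMP_CLAMP":
                camp_clamp = ev.value
                y[_kernels.ICAMP] = ev.value
        packed = pack_params(current, camp_clamp=camp_clamp)
        n_out = max(int(round((t1 - t0) / dt_out_ms)), 2)
        tgrid = np.linspace(t0, t1, n_out + 1)
        if method.lower() == "dopri5":
            Y, status, t_reached = _kernels.integrate_grid(
                y, packed, tgrid, rtol, atol, max_step, 1e-2)
            if status != 0:
                raise RuntimeError(
                    f"integration failed at t = {t_reached / MS_PER_MIN:.3f} min "
                    f"(segment {labels[k]!r}); last state {Y[-1]}")
        else:
            dy = np.empty(8)

            def f(t, yy):
                _kernels.rhs(t, yy, packed, dy)
                return dy.copy()

            sol = solve_ivp(f, (t0, t1), y, method=method, t_eval=tgrid,
                            rtol=rtol, atol=atol, max_step=max_step)
            if not sol.success:
                raise RuntimeError(f"integration failed in segment {labels[k]!r}: {sol.message}")
            Y = sol.y.T
        if not np.all(np.isfinite(Y)):
            raise RuntimeError(f"non-finite state in segment {labels[k]!r}")
        y = Y[-1].copy()
        sl = slice(None) if k == 0 else slice(1, None)  # avoid duplicate boundary
        all_t.append(tgrid[sl])
        all_y.append(Y[sl])
        epochs.append((bounds[k], bounds[k + 1], labels[k]))

    time_ms = np.concatenate(all_t)
    states = np.concatenate(all_y)
    meta = {
        "t_span_min": t_span_min,
        "dt_out_ms": dt_out_ms,
        "rtol": rtol,
        "method": method,
        "protocol": [
            {"time_min": e.time_min, "action": e.action, "factor": e.factor,
             "value": e.value, "name": e.name} for e in (protocol.events if protocol else [])
        ],
    }
    return Trace(time_ms=time_ms, states=states, params=p, epochs=epochs,
                 transient_min=transient_min, meta=meta)
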