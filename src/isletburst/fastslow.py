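"""Fast/slow dissection: bifurcation structure of the fast subsystem.

The fast subsystem is (V, n, c); the remaining variables change on much
slower timescales and are frozen.  For the Kir2.1 knockout the natural
bifurcation parameter is the cAMP-dependent Kir activation c∞ (treated as a
constant, with c_er clamped at its burst-cycle mean); for the leak/K(Ca)
knockout it is the ER Ca2+ concentration c_er itself.

Equilibria are continued in pseudo-arclength with Jacobian eigenvalues at
every point; saddle-nodes and Hopf points are detected from eigenvalue and
fold structure and refined.  Limit cycles are continued by single shooting
with the period as unknown and an anchoring phase condition; Floquet
multipliers come from the finite-difference monodromy matrix.  A periodic
branch whose period blows up is classified SNIC (terminal parameter at an
equilibrium fold) or homoclinic (terminal parameter interior to the fold
interval) — the dichotomy that separates parabolic bursting in the Kir2.1
model from square-wave bursting in the leak/K(Ca) model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from . import _kernels, model
from .model import pack_params
from .params import ParameterSet, Variant

__all__ = [
    "FastSubsystem", "EquilibriumBranch", "PeriodicBranch", "LabeledPoint",
    "BifurcationDiagram", "equilibrium_continuation", "detect_bifurcations",
    "periodic_continuation", "classify_blowup", "cinf_slow_curve",
    "cer_nullcline", "overlay_trajectory", "compute_diagram",
    "find_equilibrium", "equilibrium_curve_by_voltage",
]

_FAST = list(_kernels.FAST_VARS)          # indices of V, n, c in the state
_FROZEN_DEFAULT = {"cer": 150.0, "F6P": 1000.0, "FBP": 1.0, "ADPc": 500.0,
                   "cAMP": 0.5}


@dataclass
class FastSubsystem:
    """(V, n, c) subsystem with one frozen slow quantity as parameter."""

    params: ParameterSet
    mode: str                       # 'cinf' or 'cer'
    cer_clamp: float = 150.0        # used in 'cinf' mode

    def __post_init__(self) -> None:
        if self.mode not in ("cinf", "cer"):
            raise ValueError("mode must be 'cinf' or 'cer'")
        if self.mode == "cinf" and self.params.variant is not Variant.KO_KIR21:
            raise ValueError("c_inf continuation requires the KO_KIR21 variant")
        if self.mode == "cer" and self.params.variant is not Variant.KO_LEAK_KCA:
            raise ValueError("c_er continuation requires the KO_LEAK_KCA variant")

    def packed(self, pval: float) -> np.ndarray:
        fm = 1 if self.mode == "cinf" else 2
        return pack_params(self.params, fastmode=fm, fastparam=pval)

    def embed(self, y3: np.ndarray) -> np.ndarray:
        y = np.empty(8)
        y[_kernels.IV], y[_kernels.IN], y[_kernels.IC] = y3
        y[_kernels.ICER] = self.cer_clamp
        y[_kernels.IF6P] = _FROZEN_DEFAULT["F6P"]
        y[_kernels.IFBP] = _FROZEN_DEFAULT["FBP"]
        y[_kernels.IADP] = _FROZEN_DEFAULT["ADPc"]
        y[_kernels.ICAMP] = _FROZEN_DEFAULT["cAMP"]
        return y

    def rhs(self, y3: np.ndarray, pval: float) -> np.ndarray:
        dy = np.empty(8)
        _kernels.rhs(0.0, self.embed(np.asarray(y3, float)), self.packed(pval), dy)
        return dy[_FAST]

    def jac(self, y3: np.ndarray, pval: float, eps: float = 1e-6) -> np.ndarray:
        """Finite-difference Jacobian of the 3-variable vector field."""
        y3 = np.asarray(y3, dtype=float)
        f0 = self.rhs(y3, pval)
        J = np.empty((3, 3))
        scale = np.array([1.0, 1e-3, 1e-3])  # V in mV vs gating/μM
        for k in range(3):
            h = eps * max(abs(y3[k]), 1.0) * scale[k] / scale[k]
            h = eps * max(abs(y3[k]), scale[k])
            yp = y3.copy(); yp[k] += h
            ym = y3.copy(); ym[k] -= h
            J[:, k] = (self.rhs(yp, pval) - self.rhs(ym, pval)) / (2 * h)
        return J

    def flow(self, y3: np.ndarray, pval: float, T: float,
             rtol: float = 1e-10, dense: bool = False):
        """Integrate the fast subsystem for T ms (compiled kernel)."""
        packed = self.packed(pval)
        n_out = 2 if not dense else max(int(T / 1.0), 2)
        tgrid = np.linspace(0.0, T, n_out)
        atol = np.array([1e-8, 1e-11, 1e-11, 1, 1, 1, 1, 1], dtype=float)
        Y, status, t_reached = _kernels.integrate_grid(
            self.embed(np.asarray(y3, float)), packed, tgrid, rtol, atol,
            max(T / 10.0, 1.0), 1e-3)
        if status != 0:
            raise RuntimeError(f"fast-subsystem integration failed at t={t_reached}")
        if dense:
            return tgrid, Y[:, _FAST]
        return Y[-1, _FAST]


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumBranch:
    p: np.ndarray                  # parameter values along arclength
    X: np.ndarray                  # (n, 3) states
    eigs: np.ndarray               # (n, 3) complex eigenvalues
    stable: np.ndarray             # (n,) bool
    warnings: list[str] = field(default_factory=list)

    @property
    def V(self) -> np.ndarray:
        return self.X[:, 0]


@dataclass
class PeriodicBranch:
    p: np.ndarray
    X0: np.ndarray                 # (n, 3) anchor states on the cycle
    T: np.ndarray                  # periods (ms)
    Vmin: np.ndarray
    Vmax: np.ndarray
    multipliers: np.ndarray        # (n, 3) complex Floquet multipliers
    stable: np.ndarray
    end_reason: str = ""


@dataclass
class LabeledPoint:
    kind: str                      # SN | HB | SNP | SNIC | HC | PD | UNRESOLVED
    p: float
    V: float
    info: dict = field(default_factory=dict)


@dataclass
class BifurcationDiagram:
    mode: str
    equilibria: EquilibriumBranch
    cycles: list[PeriodicBranch]
    labels: list[LabeledPoint]

    @property
    def bistable_interval(self) -> tuple[float, float] | None:
        """Parameter interval where a stable equilibrium coexists with a
        stable limit cycle; None if the diagram has no such interval."""
        eq = self.equilibria
        best = None
        for br in self.cycles:
            stab_c = br.p[br.stable]
            if len(stab_c) == 0:
                continue
            stab_e = eq.p[eq.stable]
            lo = max(stab_c.min(), stab_e.min())
            hi = min(stab_c.max(), stab_e.max())
            # require actual pointwise coexistence, not just range overlap
            pts = stab_c[(stab_c >= lo) & (stab_c <= hi)]
            cover = [pp for pp in pts if np.any(np.abs(stab_e - pp) < 0.02 * (eq.p.max() - eq.p.min()))]
            if len(cover) >= 2:
                iv = (float(min(cover)), float(max(cover)))
                if iv[1] - iv[0] > 1e-6 and (best is None or iv[1] - iv[0] > best[1] - best[0]):
                    best = iv
        return best

    def to_json(self, path: str | Path) -> None:
        def ser(x):
            if isinstance(x, np.ndarray):
                if np.iscomplexobj(x):
                    return {"re": x.real.tolist(), "im": x.imag.tolist()}
                return x.tolist()
            return x
        doc = {
            "mode": self.mode,
            "equilibria": {k: ser(v) for k, v in vars(self.equilibria).items()},
            "cycles": [{k: ser(v) for k, v in vars(br).items()} for br in self.cycles],
            "labels": [{"kind": L.kind, "p": L.p, "V": L.V, "info": L.info}
                       for L in self.labels],
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def find_equilibrium(fs: FastSubsystem, pval: float,
                     guess: np.ndarray | None = None) -> np.ndarray:
    """Damped root solve for one fast-subsystem equilibrium."""
    if guess is None:
        guess = np.array([-65.0, 1e-4, 0.1])
    sol = root(lambda y: fs.rhs(y, pval) * np.array([1.0, 1e3, 1e3]),
               np.asarray(guess, float), method="hybr", tol=1e-13)
    # judge by the residual, not the solver flag (hybr reports "no progress"
    # when started at an already-converged point)
    if np.linalg.norm(fs.rhs(sol.x, pval)) > 1e-9:
        raise RuntimeError(f"no equilibrium found at parameter {pval}")
    return sol.x


def _point(fs: FastSubsystem, x: np.ndarray, pval: float):
    J = fs.jac(x, pval)
    eigs = np.linalg.eigvals(J)
    return eigs, bool(np.all(eigs.real < 0))


def equilibrium_curve_by_voltage(fs: FastSubsystem, Vgrid: np.ndarray):
    """Equilibrium branch parameterized explicitly by voltage.

    At an equilibrium n = n∞(V) and c solves the cytosolic balance, so the
    branch admits a closed form with V as the curve parameter; the
    bifurcation parameter follows from the current balance.  Used as an
    independent cross-check of the arclength continuation and to refine
    fold locations.
    """
    p = fs.params
    out_p, out_x = [], []
    for V in np.asarray(Vgrid, dtype=float):
        ninf = 1.0 / (1.0 + np.exp((p.vn - V) / p.sn))
        ICa = model.current_ca(V, p)
        IK = p.gK * ninf * (V - p.VK)
        if fs.mode == "cinf":
            c = model.ciss(V, fs.cer_clamp, p)
            if c < 0:
                continue
            IKCa = model.current_kca(V, c, p)
            kinf = model.kir_block(V, p.VKir, p.sKir)
            denom = p.gKir * kinf * (V - p.VK)
            if abs(denom) < 1e-12:
                continue
            pv = -(ICa + IK + IKCa) / denom
            out_p.append(pv); out_x.append((V, ninf, c))
        else:
            Ileak = p.gleak * (V - p.VK)
            if abs(V - p.VK) < 1e-9:
                continue
            w_req = (-(ICa + IK + Ileak) / (V - p.VK)) / p.gKCa
            if not 0.0 < w_req < 1.0:
                continue
            c = p.Kc * np.sqrt(w_req / (1.0 - w_req))
            denom_c = p.kpmca + p.kleak + p.kSERCA
            cer = (c * denom_c + p.alpha * ICa) / p.kleak
            out_p.append(cer); out_x.append((V, ninf, c))
    return np.array(out_p), np.array(out_x)


def equilibrium_continuation(
    fs: FastSubsystem,
    p_range: tuple[float, float],
    p_start: float | None = None,
    x_start: np.ndarray | None = None,
    ds: float = 0.02,
    ds_min: float = 1e-7,
    ds_max: float = 0.2,
    max_points: int = 4000,
) -> EquilibriumBranch:
    """Pseudo-arclength continuation of fast-subsystem equilibria.

    The branch is traced in both directions from an initial equilibrium
    (found by damped root-finding).  Variables are scaled so that mV and μM
    contribute comparably to the arclength metric.  On corrector failure
    the step is halved; below ``ds_min`` the branch is truncated with a
    warning record.
    """
    plo, phi = min(p_range), max(p_range)
    pscale = max(phi - plo, 1e-12)
    wts = np.array([1 / 50.0, 1.0, 1.0])    # V, n, c scaling

    if x_start is None:
        if p_start is None:
            # seed from the voltage-parameterized branch: pick a point whose
            # parameter lies inside the requested window, away from the
            # V ≈ V_K asymptote where the parameter blows up
            Vgrid = np.linspace(fs.params.VK + 2.0, -12.0, 300)
            pv, xv = equilibrium_curve_by_voltage(fs, Vgrid)
            inside = np.where((pv > plo) & (pv < phi))[0]
            if len(inside) == 0:
                raise RuntimeError("no equilibrium with parameter inside the range")
            k = inside[len(inside) // 2]
            p_start = float(pv[k])
            x_start = np.array(xv[k])
            x_start = find_equilibrium(fs, p_start, guess=x_start)
        else:
            x_start = find_equilibrium(fs, p_start)
    elif p_start is None:
        raise ValueError("x_start given without p_start")

    def F(u):
        x, pv = u[:3], u[3]
        return fs.rhs(x, pv) * np.array([1.0, 1e3, 1e3])

    def trace(direction: int):
        pts = []
        u = np.concatenate([x_start, [p_start]])
        tang = np.zeros(4); tang[3] = direction
        step = ds
        warnings_: list[str] = []
        for _ in range(max_points):
            upred = u + step * tang * np.array([*(1 / wts), pscale])

            def G(uu):
                arc = (np.dot((uu[:3] - upred[:3]) * wts, tang[:3])
                       + (uu[3] - upred[3]) / pscale * tang[3])
                return np.concatenate([F(uu), [arc]])

            sol = root(G, upred, method="hybr", tol=1e-12)
            ok = sol.success and np.linalg.norm(F(sol.x)) < 1e-8
            if not ok:
                step *= 0.5
                if step < ds_min:
                    warnings_.append(
                        f"branch truncated at p={u[3]:.6g} (step underflow)")
                    break
                continue
            unew = sol.x
            # new unit tangent in the scaled metric
            d = unew - u
            dscaled = np.concatenate([d[:3] * wts, [d[3] / pscale]])
            nrm = np.linalg.norm(dscaled)
            if nrm > 0:
                tang = dscaled / nrm
            u = unew
            pts.append(u.copy())
            step = min(step * 1.3, ds_max)
            if not (plo - 0.05 * pscale <= u[3] <= phi + 0.05 * pscale):
                break
            if u[0] < fs.params.VK + 0.5 or u[0] > -5.0:
                break  # V_K asymptote / depolarized edge of the window
        return pts, warnings_

    fwd, w1 = trace(+1)
    bwd, w2 = trace(-1)
    allpts = [np.concatenate([x_start, [p_start]])] + fwd
    allpts = list(reversed(bwd)) + allpts
    P = np.array([u[3] for u in allpts])
    X = np.array([u[:3] for u in allpts])
    eigs = np.empty((len(P), 3), dtype=complex)
    stable = np.empty(len(P), dtype=bool)
    for i in range(len(P)):
        eigs[i], stable[i] = _point(fs, X[i], P[i])
    return EquilibriumBranch(P, X, eigs, stable, warnings=w1 + w2)


def detect_bifurcations(fs: FastSubsystem, branch: EquilibriumBranch,
                        refine_tol: float = 1e-8) -> list[LabeledPoint]:
    """Label saddle-node (fold) and Hopf points along an equilibrium branch.

    SN: the parameter reverses direction along arclength while a real
    eigenvalue crosses zero — refined via the voltage-parameterized branch
    (dp/dV = 0 solved by bracketed root-finding).  HB: a complex pair's
    real part changes sign — refined by bisection in the parameter.
    """
    labels: list[LabeledPoint] = []
    P, X = branch.p, branch.X
    prange = max(P.max() - P.min(), 1e-12)

    def _dup(kind, pv):
        return any(L.kind == kind and abs(L.p - pv) < 1e-4 * prange
                   for L in labels)

    # --- folds ---
    dP = np.diff(P)
    for i in range(1, len(dP)):
        if dP[i - 1] * dP[i] < 0:
            V1, V2 = X[i - 1, 0], X[i + 1, 0]
            Vlo, Vhi = min(V1, V2), max(V1, V2)

            def dpdV(V, h=1e-5):
                p1, _ = equilibrium_curve_by_voltage(fs, np.array([V - h, V + h]))
                if len(p1) < 2:
                    return np.nan
                return (p1[1] - p1[0]) / (2 * h)

            try:
                d1, d2 = dpdV(Vlo), dpdV(Vhi)
                if np.isfinite(d1) and np.isfinite(d2) and d1 * d2 < 0:
                    Vf = brentq(dpdV, Vlo, Vhi, xtol=1e-10)
                    pf, xf = equilibrium_curve_by_voltage(fs, np.array([Vf]))
                    if not _dup("SN", float(pf[0])):
                        labels.append(LabeledPoint("SN", float(pf[0]), float(Vf)))
                    continue
            except (ValueError, RuntimeError):
                pass
            if not _dup("SN", float(P[i])):
                labels.append(LabeledPoint("SN", float(P[i]), float(X[i, 0]),
                                           info={"refined": False}))

    # --- Hopf ---
    def _pair_real(e):
        cplx = e[np.abs(e.imag) > 1e-9]
        return cplx.real.max() if len(cplx) else np.nan

    re_pair = np.array([_pair_real(branch.eigs[i]) for i in range(len(P))])
    for i in range(len(P) - 1):
        r1, r2 = re_pair[i], re_pair[i + 1]
        if np.isfinite(r1) and np.isfinite(r2) and r1 * r2 < 0:
            # bisection in parameter along the (locally monotone) branch
            pa, pb = P[i], P[i + 1]
            xa = X[i].copy()
            for _ in range(60):
                pm = 0.5 * (pa + pb)
                try:
                    xm = find_equilibrium(fs, pm, guess=xa)
                except RuntimeError:
                    break
                em, _ = _point(fs, xm, pm)
                rm = _pair_real(em)
                if not np.isfinite(rm):
                    break
                if rm * r1 <= 0:
                    pb = pm
                else:
                    pa, r1, xa = pm, rm, xm
                if abs(pb - pa) < refine_tol * max(1.0, abs(pm)):
                    break
            pm = 0.5 * (pa + pb)
            try:
                xm = find_equilibrium(fs, pm, guess=xa)
                em, _ = _point(fs, xm, pm)
                omega = float(np.abs(em.imag).max())
            except RuntimeError:
                xm, omega = X[i], np.nan
            labels.append(LabeledPoint("HB", float(pm), float(xm[0]),
                                       info={"omega": omega}))
    return labels


# ---------------------------------------------------------------------------
# limit cycles
# ---------------------------------------------------------------------------

def _settle_orbit(fs: FastSubsystem, pval: float,
                  y0: np.ndarray | None = None,
                  settle_ms: float = 30_000.0) -> tuple[np.ndarray, float]:
    """Converge to a stable cycle by integration; return (anchor, period).

    The anchor point is the upward mean-V crossing of the settled orbit.
    """
    candidates = ([np.asarray(y0, float)] if y0 is not None else
                  [np.array([-25.0, 0.05, 0.3]), np.array([-25.0, 0.05, 0.08]),
                   np.array([-40.0, 0.01, 0.05])])
    V = None
    for y0c in candidates:
        y = fs.flow(y0c, pval, settle_ms)
        t, Y = fs.flow(y, pval, 5000.0, dense=True)
        V = Y[:, 0]
        if V.max() - V.min() >= 1.0:
            break
    if V is None or V.max() - V.min() < 1.0:
        raise RuntimeError(f"no oscillation at parameter {pval}")
    vmid = 0.5 * (V.max() + V.min())
    ups = np.where((V[:-1] < vmid) & (V[1:] >= vmid))[0]
    if len(ups) < 3:
        t, Y = fs.flow(y, pval, 60_000.0, dense=True)
        V = Y[:, 0]
        vmid = 0.5 * (V.max() + V.min())
        ups = np.where((V[:-1] < vmid) & (V[1:] >= vmid))[0]
        if len(ups) < 3:
            raise RuntimeError(f"could not isolate a cycle at parameter {pval}")
    T = float(np.mean(np.diff(t[ups[-3:]])))
    return Y[ups[-2]].copy(), T


def _monodromy(fs: FastSubsystem, x0: np.ndarray, T: float, pval: float,
               eps: float = 1e-6) -> np.ndarray:
    M = np.empty((3, 3))
    scale = np.array([1.0, 1e-3, 1e-3])
    for k in range(3):
        h = eps * max(abs(x0[k]), scale[k])
        xp = x0.copy(); xp[k] += h
        xm = x0.copy(); xm[k] -= h
        M[:, k] = (fs.flow(xp, pval, T) - fs.flow(xm, pval, T)) / (2 * h)
    return M


def periodic_continuation(
    fs: FastSubsystem,
    p_range: tuple[float, float],
    p_start: float,
    start_state: np.ndarray | None = None,
    direction: int = +1,
    ds: float = 0.02,
    ds_min: float = 1e-6,
    ds_max: float = 0.1,
    max_points: int = 300,
    period_cutoff_factor: float = 10.0,
) -> PeriodicBranch:
    """Continue a limit-cycle branch by single shooting.

    Unknowns are (x0, T, p) with the return map condition, an anchoring
    phase condition (orthogonality to the previous cycle's flow direction)
    and a pseudo-arclength constraint.  The branch ends at period blow-up
    (candidate SNIC/homoclinic), orbit collapse (Hopf), a parameter-range
    exit, or step underflow.
    """
    plo, phi = min(p_range), max(p_range)
    pscale = max(phi - plo, 1e-12)
    wts = np.array([1 / 50.0, 1.0, 1.0])

    x0, T0 = _settle_orbit(fs, p_start, start_state)
    Tscale = T0

    ps, X0s, Ts, Vmins, Vmaxs, mults, stabs = [], [], [], [], [], [], []
    end_reason = "range_exit"

    u = np.concatenate([x0, [T0, p_start]])
    tang = np.zeros(5); tang[4] = direction
    step = ds
    median_T = T0

    def record(u):
        x0_, T_, p_ = u[:3], u[3], u[4]
        tt, Y = fs.flow(x0_, p_, T_, dense=True)
        M = _monodromy(fs, x0_, T_, p_)
        mu = np.linalg.eigvals(M)
        # stability: nontrivial multipliers inside unit circle
        mu_sorted = mu[np.argsort(-np.abs(mu))]
        nontriv = mu_sorted[np.abs(np.abs(mu_sorted) - 1.0) > 1e-3]
        if len(nontriv) == 0:
            nontriv = mu_sorted[1:]
        st = bool(np.all(np.abs(nontriv) < 1.0 + 1e-6))
        ps.append(p_); X0s.append(x0_.copy()); Ts.append(T_)
        Vmins.append(float(Y[:, 0].min())); Vmaxs.append(float(Y[:, 0].max()))
        mults.append(mu); stabs.append(st)

    record(u)
    fdir = fs.rhs(u[:3], u[4])

    for _ in range(max_points):
        upred = u + step * tang * np.array([*(1 / wts), Tscale, pscale])
        uref = u.copy()
        fref = fs.rhs(uref[:3], uref[4])

        def G(uu):
            x0_, T_, p_ = uu[:3], abs(uu[3]), uu[4]
            ret = (fs.flow(x0_, p_, T_) - x0_) * np.array([1.0, 1e2, 1e2])
            phase = np.dot(fref * np.array([1.0, 1e2, 1e2]), x0_ - uref[:3])
            arc = (np.dot((uu[:3] - upred[:3]) * wts, tang[:3])
                   + (uu[3] - upred[3]) / Tscale * tang[3]
                   + (uu[4] - upred[4]) / pscale * tang[4])
            return np.concatenate([ret, [phase, arc]])

        try:
            sol = root(G, upred, method="hybr", tol=1e-10)
            ok = sol.success and np.linalg.norm(G(sol.x)[:4]) < 1e-6
        except RuntimeError:
            ok = False
        if not ok:
            step *= 0.5
            if step < ds_min:
                end_reason = "step_underflow"
                break
            continue
        unew = sol.x
        unew[3] = abs(unew[3])
        d = unew - u
        dscaled = np.concatenate([d[:3] * wts, [d[3] / Tscale, d[4] / pscale]])
        nrm = np.linalg.norm(dscaled)
        if nrm > 0:
            tang = dscaled / nrm
        u = unew
        record(u)
        step = min(step * 1.3, ds_max)
        median_T = float(np.median(Ts))
        if u[3] > period_cutoff_factor * median_T:
            end_reason = "period_blowup"
            break
        amp = Vmaxs[-1] - Vmins[-1]
        if amp < 0.5:
            end_reason = "orbit_collapse"
            break
        if not (plo - 0.02 * pscale <= u[4] <= phi + 0.02 * pscale):
            end_reason = "range_exit"
            break

    return PeriodicBranch(np.array(ps), np.array(X0s), np.array(Ts),
                          np.array(Vmins), np.array(Vmaxs),
                          np.array(mults), np.array(stabs), end_reason)


def detect_cycle_bifurcations(branch: PeriodicBranch) -> list[LabeledPoint]:
    """SNP (fold of cycles) and period-doubling points along a cycle branch."""
    labels: list[LabeledPoint] = []
    P = branch.p
    if len(P) < 3:
        return labels
    dP = np.diff(P)
    for i in range(1, len(dP)):
        if dP[i - 1] * dP[i] < 0:
            labels.append(LabeledPoint("SNP", float(P[i]), float(branch.Vmax[i])))

    def real_neg(mu):
        cand = [m.real for m in mu if abs(m.imag) < 1e-6 and m.real < 0]
        return min(cand) if cand else np.nan

    rn = np.array([real_neg(branch.multipliers[i]) for i in range(len(P))])
    for i in range(len(P) - 1):
        if np.isfinite(rn[i]) and np.isfinite(rn[i + 1]):
            if (rn[i] + 1.0) * (rn[i + 1] + 1.0) < 0:
                frac = (-1.0 - rn[i]) / (rn[i + 1] - rn[i])
                pc = P[i] + frac * (P[i + 1] - P[i])
                labels.append(LabeledPoint(
                    "PD", float(pc), float(branch.Vmax[i]),
                    info={"bracket": (float(P[i]), float(P[i + 1]))}))
    return labels


def classify_blowup(
    fs: FastSubsystem,
    branch: PeriodicBranch,
    eq_labels: list[LabeledPoint],
    rel_tol: float = 0.05,
) -> LabeledPoint:
    """Classify a period-blow-up endpoint as SNIC or homoclinic.

    SNIC: the terminal parameter coincides with an equilibrium fold and the
    cycle passes near the fold point.  HC: the terminal parameter lies in
    the interior of the fold interval (the cycle collides with the saddle
    on the middle branch).  The asymptotic period-scaling exponent is
    recorded as a diagnostic, not enforced.
    """
    blown = branch.end_reason == "period_blowup" or (
        branch.end_reason == "step_underflow" and len(branch.T) >= 5
        and branch.T[-1] > 3.0 * branch.T[0])
    if not blown or len(branch.p) < 3:
        return LabeledPoint("UNRESOLVED", float(branch.p[-1]),
                            float(branch.Vmax[-1]),
                            info={"reason": branch.end_reason})
    p_term = float(branch.p[-1])
    folds = [L for L in eq_labels if L.kind == "SN"]
    prange = max(abs(branch.p.max() - branch.p.min()), 1e-12)
    info: dict = {"p_term": p_term, "period_term": float(branch.T[-1])}
    # period growth diagnostic: fit T ~ (p - p*)^(-1/2) vs -log(p - p*)
    tail = slice(max(len(branch.p) - 6, 0), len(branch.p))
    dp = np.abs(branch.p[tail] - p_term) + 1e-15
    with np.errstate(all="ignore"):
        pow_fit = np.polyfit(np.log(dp[:-1]), np.log(branch.T[tail][:-1]), 1)[0]
    info["period_scaling_exponent"] = float(pow_fit)
    if folds:
        nearest = min(folds, key=lambda L: abs(L.p - p_term))
        info["nearest_fold_p"] = nearest.p
        if abs(nearest.p - p_term) < rel_tol * prange:
            return LabeledPoint("SNIC", p_term, nearest.V, info)
        lo = min(L.p for L in folds)
        hi = max(L.p for L in folds)
        if lo - rel_tol * prange < p_term < hi + rel_tol * prange or len(folds) == 1:
            return LabeledPoint("HC", p_term, float(branch.Vmin[-1]), info)
    return LabeledPoint("UNRESOLVED", p_term, float(branch.Vmax[-1]), info)


# ---------------------------------------------------------------------------
# slow structures and overlays
# ---------------------------------------------------------------------------

def cinf_slow_curve(Vgrid: np.ndarray, AMPc: float, cer_clamped: float,
                    p: ParameterSet):
    """The (c∞, V) curve of the slow cAMP steady state at fixed AMP_c.

    For each V: c at its steady state, then the cAMP steady state, then the
    Kir activation c∞.  Increasing AMP_c inhibits adenylyl cyclase and
    shifts the curve toward smaller c∞.  Grid points where the cAMP balance
    has no finite root are returned as NaN (curve gap).
    """
    out = np.full(len(Vgrid), np.nan)
    for i, V in enumerate(np.asarray(Vgrid, dtype=float)):
        try:
            camp = model.camp_steady_state(V, AMPc, cer_clamped, p)
        except ValueError:
            continue
        out[i] = model.kir_camp_activation(camp, p.alpha_camp, p.beta_camp, p.Kcamp)
    return out


def cer_nullcline(Vgrid: np.ndarray, p: ParameterSet):
    """ER-balance curve (c_er, V): where dc_er/dt = 0 with c at quasi-steady
    state.  Along it k_leak·(c_er − c) = k_SERCA·c with c = α|I_Ca|/k_pmca."""
    V = np.asarray(Vgrid, dtype=float)
    c = -p.alpha * model.current_ca(V, p) / p.kpmca
    c = np.maximum(c, 0.0)
    cer = c * (p.kleak + p.kSERCA) / p.kleak
    return cer, c


def overlay_trajectory(trace, plane: str):
    """Project a full-model trajectory into the ('cinf', V) or ('cer', V)
    plane for superposition on a fast-subsystem diagram."""
    if plane == "cinf":
        p = trace.params
        x = model.kir_camp_activation(trace["cAMP"], p.alpha_camp,
                                      p.beta_camp, p.Kcamp)
    elif plane == "cer":
        x = trace["cer"]
    else:
        raise ValueError("plane must be 'cinf' or 'cer'")
    return x, trace["V"]


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def compute_diagram(
    fs: FastSubsystem,
    p_range: tuple[float, float],
    cycle_start: float | None = None,
    follow_pd: bool = False,
) -> BifurcationDiagram:
    """Full fast-subsystem diagram: z-curve, labeled points, cycle branches.

    ``cycle_start`` is a parameter value with a stable spiking orbit (found
    by direct simulation); the cycle branch is continued from there toward
    its termination.  With ``follow_pd`` the first period-doubled branch is
    also continued (used for the SERCA-block cascade).
    """
    eq = equilibrium_continuation(fs, p_range)
    labels = detect_bifurcations(fs, eq)
    cycles: list[PeriodicBranch] = []
    if cycle_start is not None:
        br = periodic_continuation(fs, p_range, cycle_start, direction=+1)
        cycles.append(br)
        labels.extend(detect_cycle_bifurcations(br))
        if br.end_reason in ("period_blowup", "step_underflow"):
            labels.append(classify_blowup(fs, br, labels))
        br2 = periodic_continuation(fs, p_range, cycle_start, direction=-1)
        if len(br2.p) > 1:
            cycles.append(br2)
            labels.extend(detect_cycle_bifurcations(br2))
            if br2.end_reason in ("period_blowup", "step_underflow"):
                labels.append(classify_blowup(fs, br2, labels))
        if follow_pd:
            pds = [L for L in labels if L.kind == "PD"]
            if pds:
                L = pds[0]
                try:
                    cycles.append(_follow_period_doubled(fs, p_range, L))
                except RuntimeError as exc:
                    warnings.warn(f"period-doubled branch not continued: {exc}")
    return BifurcationDiagram(fs.mode, eq, cycles, labels)


def _follow_period_doubled(fs: FastSubsystem, p_range, pd_label: LabeledPoint,
                           offset_frac: float = 0.03) -> PeriodicBranch:
    """Start a cycle branch just past a period-doubling point.

    The doubled orbit is obtained by settling the flow slightly beyond the
    PD parameter; the settled cycle there has twice the base period.
    """
    lo, hi = pd_label.info.get("bracket", (pd_label.p, pd_label.p))
    span = abs(hi - lo) + 1e-9
    for pv in (hi + span, hi + 3 * span, lo - span, lo - 3 * span):
        try:
            return periodic_continuation(fs, p_range, pv, direction=+1,
                                         max_points=60)
        except RuntimeError:
            continue
    raise RuntimeError("could not settle a doubled orbit near the PD point")
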