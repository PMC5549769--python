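"""Core model definition: currents, algebraic relations and the vector field.

The model is an 8-variable conductance-based β-cell, the Dual Oscillator
Model family: a fast electrical/Ca2+ oscillator (V, n, c) coupled to a slow
glycolytic oscillator (F6P, FBP) through adenine nucleotides (ADP_c, with
ATP_c and AMP_c derived algebraically), an ER Ca2+ compartment (c_er), and
cAMP turnover (adenylyl cyclase vs. phosphodiesterase).  Three variants
differ only in which hyperpolarizing K+ conductance couples metabolism to
the membrane: nucleotide-gated K(ATP) (wild type), a cAMP-potentiated
inward-rectifier Kir2.1 current (SUR1-knockout rescue), or a constant K+
leak with elevated K(Ca) (alternative knockout rescue).

Scalar relations here are thin, array-friendly wrappers; the compiled
right-hand side lives in :mod:`isletburst._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import IADP, IC, ICAMP, ICER, IF6P, IFBP, IN, IV, N_PACKED, N_PARAMS
from .params import PARAM_ORDER, ParameterSet, Variant

__all__ = [
    "StateVector", "STATE_NAMES",
    "kca_activation", "kir_block", "kir_camp_activation",
    "current_ca", "current_k", "current_kca", "current_katp", "current_kir",
    "current_leak", "katp_open_fraction",
    "atp_amp_from_adp", "pfk_flux", "gpdh_flux",
    "v_ac", "v_pde", "ciss", "camp_steady_state",
    "rhs", "pack_params", "derived_series",
]

STATE_NAMES = ("V", "n", "c", "cer", "F6P", "FBP", "ADPc", "cAMP")

# Guard against silent drift between the named parameter order and the
# positional unpacking inside the compiled kernel.
_KERNEL_ORDER = (
    "Cm", "gK", "gCa", "gKCa", "gKATP_bar", "gKir", "gleak", "VK", "VCa",
    "vm", "sm", "vn", "sn", "tau_n", "Kc",
    "fcyt", "alpha", "kpmca", "kleak", "kSERCA", "fer", "Vcte",
    "VKir", "sKir", "alpha_camp", "beta_camp", "Kcamp",
    "vAC_bar", "alphaAC", "betaAC", "KACca", "beta_amp", "Kamp", "amp_exp",
    "vPDE_bar", "alphaPDE", "betaPDE", "KPDEca", "KPDEcamp",
    "JGK", "vPFK", "lambda_pfk", "Kamp_pfk", "Kfbp_pfk", "Kf6p_pfk", "Katp_pfk",
    "f13", "f23", "f41", "f42", "f43", "kgpdh", "kFBP", "f6p_frac",
    "Atot", "tau_a", "r_base", "r1", "w_pmca", "vgamma", "kgamma",
    "kdd", "ktd", "ktt", "frac_mgadp", "frac_adp3", "frac_atp4",
)
assert _KERNEL_ORDER == PARAM_ORDER, "kernel/parameter layout mismatch"
assert len(PARAM_ORDER) == N_PARAMS


@dataclass
class StateVector:
    """The 8 dynamical variables at one instant.

    V in mV, n dimensionless in [0, 1], all concentrations in μM.  ATP_c and
    AMP_c are not state variables; they derive from ADP_c through nucleotide
    conservation and adenylate-kinase equilibrium (:func:`atp_amp_from_adp`).
    """

    V: float
    n: float
    c: float
    cer: float
    F6P: float
    FBP: float
    ADPc: float
    cAMP: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("state contains non-finite components")
        if not 0.0 <= self.n <= 1.0:
            raise ValueError(f"n must be in [0, 1], got {self.n}")
        for name in ("c", "cer", "F6P", "FBP", "ADPc", "cAMP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.V, self.n, self.c, self.cer, self.F6P, self.FBP,
             self.ADPc, self.cAMP], dtype=np.float64)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "StateVector":
        return cls(*[float(x) for x in np.asarray(arr, dtype=np.float64)])


# ---------------------------------------------------------------------------
# gating / activation functions
# ---------------------------------------------------------------------------

def kca_activation(c, Kc):
    """K(Ca) activation ω = c²/(c² + Kc²); in [0, 1), increasing in c."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("c must be non-negative")
    if not np.all(np.asarray(Kc) > 0):
        raise ValueError("Kc must be positive")
    out = c * c / (c * c + Kc * Kc)
    return float(out) if out.ndim == 0 else out


def kir_block(V, VKir, sKir):
    """Polyamine block of Kir2.1: Boltzmann k∞, decreasing in V."""
    if not np.all(np.asarray(sKir) > 0):
        raise ValueError("sKir must be positive")
    out = 1.0 / (1.0 + np.exp((np.asarray(V, dtype=float) - VKir) / sKir))
    return float(out) if out.ndim == 0 else out


def kir_camp_activation(cAMP, alpha_camp, beta_camp, Kcamp):
    """cAMP activation c∞ = α + β·cAMP⁴/(cAMP⁴ + K⁴), in [α, α+β)."""
    cAMP = np.asarray(cAMP, dtype=float)
    if np.any(cAMP < 0):
        raise ValueError("cAMP must be non-negative")
    h = cAMP ** 4
    out = alpha_camp + beta_camp * h / (h + Kcamp ** 4)
    return float(out) if out.ndim == 0 else out


def _m_inf(V, p: ParameterSet):
    return 1.0 / (1.0 + np.exp((p.vm - np.asarray(V, dtype=float)) / p.sm))


def _n_inf(V, p: ParameterSet):
    return 1.0 / (1.0 + np.exp((p.vn - np.asarray(V, dtype=float)) / p.sn))


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def _require(p: ParameterSet, variant: Variant, what: str) -> None:
    if p.variant is not variant:
        raise ValueError(f"{what} is not part of variant {p.variant.value}")


def current_ca(V, p: ParameterSet):
    """Voltage-gated Ca2+ current (fA); inward (negative) below V_Ca."""
    return p.gCa * _m_inf(V, p) * (np.asarray(V, dtype=float) - p.VCa)


def current_k(V, n, p: ParameterSet):
    """Delayed-rectifier K+ current (fA)."""
    return p.gK * np.asarray(n, dtype=float) * (np.asarray(V, dtype=float) - p.VK)


def current_kca(V, c, p: ParameterSet):
    """Ca2+-activated K+ current (fA)."""
    return p.gKCa * kca_activation(c, p.Kc) * (np.asarray(V, dtype=float) - p.VK)


def katp_open_fraction(ATP, ADP, p: ParameterSet):
    """Nucleotide-dependent K(ATP) open fraction (Magnus–Keizer form).

    MgADP activates, free ADP3- and ATP4- block; strictly positive for any
    nucleotide state.
    """
    ATP = np.asarray(ATP, dtype=float)
    ADP = np.asarray(ADP, dtype=float)
    mgadp = p.frac_mgadp * ADP
    adp3 = p.frac_adp3 * ADP
    atp4 = p.frac_atp4 * ATP
    top = 0.08 * (1 + 2 * mgadp / p.kdd) + 0.89 * (mgadp / p.kdd) ** 2
    bot = (1 + mgadp / p.kdd) ** 2 * (1 + adp3 / p.ktd + atp4 / p.ktt)
    return top / bot


def current_katp(V, ATP, ADP, p: ParameterSet):
    """K(ATP) current (fA); wild-type variant only."""
    _require(p, Variant.WT_KATP, "I_K(ATP)")
    return p.gKATP_bar * katp_open_fraction(ATP, ADP, p) * (np.asarray(V, dtype=float) - p.VK)


def current_kir(V, cAMP, p: ParameterSet):
    """Kir2.1 current (fA) = gKir·k∞(V)·c∞(cAMP)·(V−VK); KO_KIR21 only."""
    _require(p, Variant.KO_KIR21, "I_Kir")
    return (p.gKir * kir_block(V, p.VKir, p.sKir)
            * kir_camp_activation(cAMP, p.alpha_camp, p.beta_camp, p.Kcamp)
            * (np.asarray(V, dtype=float) - p.VK))


def current_leak(V, p: ParameterSet):
    """Constant-conductance K+ leak (fA); KO_LEAK_KCA only."""
    _require(p, Variant.KO_LEAK_KCA, "I_leak")
    return p.gleak * (np.asarray(V, dtype=float) - p.VK)


# ---------------------------------------------------------------------------
# metabolism
# ---------------------------------------------------------------------------

def atp_amp_from_adp(ADP, p: ParameterSet):
    """(ATP_c, AMP_c) from ADP_c via conservation + adenylate equilibrium.

    ATP + ADP + AMP = Atot and AMP·ATP = ADP² give a quadratic in ATP whose
    physical root is returned; the triple satisfies the conservation total
    exactly by construction.
    """
    ADP = np.asarray(ADP, dtype=float)
    b = p.Atot - ADP
    disc = np.maximum(b * b - 4.0 * ADP * ADP, 0.0)
    ATP = 0.5 * (b + np.sqrt(disc))
    AMP = ADP * ADP / np.maximum(ATP, 1e-12)
    return ATP, AMP


def pfk_flux(F6P, FBP, ATP, AMP, p: ParameterSet):
    """Allosteric PFK rate (μM/ms), 16-state Smolen-type weighted sum.

    AMP and FBP activate (interaction factors < 1 tighten F6P binding),
    ATP inhibits (factors > 1 loosen it); states with F6P bound catalyse,
    at relative rate ``lambda_pfk`` when no activator is bound.
    """
    F6P, FBP, ATP, AMP = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (F6P, FBP, ATP, AMP)))
    a = AMP / p.Kamp_pfk
    b = FBP / p.Kfbp_pfk
    f = F6P * F6P / p.Kf6p_pfk
    t = ATP * ATP / p.Katp_pfk
    num = np.zeros_like(a)
    den = np.zeros_like(a)
    for i in (0, 1):
        for j in (0, 1):
            for l in (0, 1):
                base = (a if i else 1.0) * (b if j else 1.0) * (t if l else 1.0)
                base = base / (p.f41 if i and l else 1.0) / (p.f42 if j and l else 1.0)
                den = den + base
                w1 = base * f
                w1 = (w1 / (p.f13 if i else 1.0) / (p.f23 if j else 1.0)
                      / (p.f43 if l else 1.0))
                den = den + w1
                num = num + w1 * (p.lambda_pfk if (i == 0 and j == 0) else 1.0)
    out = p.vPFK * num / den
    return float(out) if out.ndim == 0 else out


def gpdh_flux(FBP, p: ParameterSet):
    """GPDH (downstream glycolytic) flux, ∝ sqrt(FBP)."""
    out = p.kgpdh * np.sqrt(np.maximum(np.asarray(FBP, dtype=float), 0.0))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# cAMP turnover and steady states
# ---------------------------------------------------------------------------

def v_ac(c, AMPc, p: ParameterSet):
    """Adenylyl-cyclase rate (μM/ms): Ca2+-stimulated, AMP-inhibited."""
    c = np.asarray(c, dtype=float)
    AMPc = np.asarray(AMPc, dtype=float)
    if np.any(c < 0) or np.any(AMPc < 0):
        raise ValueError("concentrations must be non-negative")
    c3 = c ** 3
    caf = p.alphaAC + p.betaAC * c3 / (c3 + p.KACca ** 3)
    ampf = p.beta_amp * p.Kamp ** p.amp_exp / (AMPc ** p.amp_exp + p.Kamp ** p.amp_exp)
    out = p.vAC_bar * caf * ampf
    return float(out) if out.ndim == 0 else out


def v_pde(c, cAMP, p: ParameterSet):
    """Phosphodiesterase rate (μM/ms): Ca2+-stimulated, zero at cAMP = 0."""
    c = np.asarray(c, dtype=float)
    cAMP = np.asarray(cAMP, dtype=float)
    if np.any(c < 0) or np.any(cAMP < 0):
        raise ValueError("concentrations must be non-negative")
    c3 = c ** 3
    caf = p.alphaPDE + p.betaPDE * c3 / (c3 + p.KPDEca ** 3)
    out = p.vPDE_bar * caf * cAMP / (cAMP + p.KPDEcamp)
    return float(out) if out.ndim == 0 else out


def ciss(V, cer_clamped, p: ParameterSet):
    """Steady-state cytosolic Ca2+ with c_er clamped.

    Balance of the cytosolic fluxes: c_iss = (α·|I_Ca| + k_leak·c_er) /
    (k_pmca + k_leak + k_SERCA).  The Ca2+ influx enters with the magnitude
    of the inward current so that c_iss ≥ 0, matching the flux sign
    convention of the cytosolic Ca2+ balance.
    """
    influx = -p.alpha * current_ca(V, p)  # I_Ca < 0 below V_Ca
    out = (influx + p.kleak * cer_clamped) / (p.kpmca + p.kleak + p.kSERCA)
    return float(out) if np.ndim(out) == 0 else out


def camp_steady_state(V, AMPc, cer_clamped, p: ParameterSet) -> float:
    """Steady-state cAMP at fixed V and AMP_c (c at its own steady state).

    cAMP_ss = K_PDEcamp·V_AC / (v̄_PDE·(α_PDE + β_PDE·c³/(c³+K³)) − V_AC);
    raises if the AC rate reaches the maximal PDE capacity (no finite
    steady state).
    """
    ci = ciss(V, cer_clamped, p)
    if ci < 0:
        ci = 0.0
    vac = v_ac(ci, AMPc, p)
    c3 = ci ** 3
    pde_cap = p.vPDE_bar * (p.alphaPDE + p.betaPDE * c3 / (c3 + p.KPDEca ** 3))
    denom = pde_cap - vac
    if denom <= 0:
        raise ValueError("no finite cAMP steady state: V_AC >= maximal PDE capacity")
    return float(p.KPDEcamp * vac / denom)


# ---------------------------------------------------------------------------
# vector field
# ---------------------------------------------------------------------------

def pack_params(
    p: ParameterSet,
    camp_clamp: float | None = None,
    fastmode: int = 0,
    fastparam: float = 0.0,
) -> np.ndarray:
    """Pack a ParameterSet (+ runtime switches) for the compiled kernel."""
    arr = np.zeros(N_PACKED, dtype=np.float64)
    arr[:N_PARAMS] = p.to_array()
    if camp_clamp is not None:
        arr[_kernels.I_CLAMP_FLAG] = 1.0
        arr[_kernels.I_CLAMP_VALUE] = camp_clamp
    arr[_kernels.I_FASTMODE] = float(fastmode)
    arr[_kernels.I_FASTPARAM] = fastparam
    return arr


def rhs(t: float, state, p: ParameterSet) -> np.ndarray:
    """d(state)/dt for the variant encoded in ``p`` (μM/ms, mV/ms)."""
    y = state.to_array() if isinstance(state, StateVector) else np.asarray(
        state, dtype=np.float64)
    if y.shape != (8,):
        raise ValueError("state must have 8 components")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite components")
    dy = np.empty(8)
    _kernels.rhs(float(t), y, pack_params(p), dy)
    return dy


def derived_series(Y: np.ndarray, p: ParameterSet) -> dict[str, np.ndarray]:
    """Derived quantities along a state matrix (rows = time samples).

    Returns ATP_c, AMP_c, the metabolically gated conductance of the active
    variant (g_KATP or g_Kir, pS) and every membrane current (fA); currents
    excluded from the variant are identically zero and omitted.
    """
    Y = np.asarray(Y, dtype=float)
    V, n, c, cAMP = Y[:, IV], Y[:, IN], Y[:, IC], Y[:, ICAMP]
    ATP, AMP = atp_amp_from_adp(Y[:, IADP], p)
    out: dict[str, np.ndarray] = {"ATP": ATP, "AMP": AMP}
    out["I_Ca"] = current_ca(V, p)
    out["I_K"] = current_k(V, n, p)
    out["I_KCa"] = current_kca(V, c, p)
    if p.variant is Variant.WT_KATP:
        out["g_KATP"] = p.gKATP_bar * katp_open_fraction(ATP, Y[:, IADP], p)
        out["I_KATP"] = out["g_KATP"] * (V - p.VK)
    elif p.variant is Variant.KO_KIR21:
        out["g_Kir"] = (p.gKir * kir_block(V, p.VKir, p.sKir)
                        * kir_camp_activation(cAMP, p.alpha_camp, p.beta_camp, p.Kcamp))
        out["I_Kir"] = out["g_Kir"] * (V - p.VK)
    else:
        out["I_leak"] = current_leak(V, p)
    return out
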