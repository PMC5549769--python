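"""Compiled numerical kernels: model right-hand side and ODE integrator.

The right-hand side consumes a packed float64 parameter vector whose layout
is ``params.PARAM_ORDER`` followed by four runtime slots (cAMP-clamp flag and
value, fast-subsystem mode and bifurcation-parameter value).  ``model.py``
asserts the layout at import time so the kernel and the named parameter set
cannot drift apart.

State layout (μM unless noted):
    y = [V (mV), n, c, c_er, F6P, FBP, ADP_c, cAMP]
"""

from __future__ import annotations

import numpy as np
from numba import njit

# number of named parameters; runtime slots appended after these
N_PARAMS = 67
I_CLAMP_FLAG = 67
I_CLAMP_VALUE = 68
I_FASTMODE = 69      # 0: full model, 1: fast subsystem w/ c_inf param, 2: w/ c_er param
I_FASTPARAM = 70
N_PACKED = 71

# state indices
IV, IN, IC, ICER, IF6P, IFBP, IADP, ICAMP = range(8)

# Variables integrated in fast-subsystem mode (the rest are frozen).
FAST_VARS = (IV, IN, IC)


@njit(cache=True)
def nucleotides(ADP: float, Atot: float) -> tuple[float, float]:
    """ATP and AMP from ADP under conservation + adenylate-kinase equilibrium.

    ATP + ADP + AMP = Atot with AMP = ADP^2/ATP gives a quadratic for ATP;
    the physical (larger) root is returned.
    """
    b = Atot - ADP
    disc = b * b - 4.0 * ADP * ADP
    if disc < 0.0:
        disc = 0.0
    ATP = 0.5 * (b + np.sqrt(disc))
    if ATP < 1e-12:
        ATP = 1e-12
    AMP = ADP * ADP / ATP
    return ATP, AMP


@njit(cache=True)
def rhs(t: float, y: np.ndarray, p: np.ndarray, dy: np.ndarray) -> None:
    """In-place evaluation of d(state)/dt for the packed parameter vector."""
    V = y[0]
    n = y[1]
    c = y[2]
    cer = y[3]
    F6P = y[4]
    FBP = y[5]
    ADP = y[6]
    cAMP = y[7]

    # --- unpack (order must match params.PARAM_ORDER) ---
    Cm = p[0]; gK = p[1]; gCa = p[2]; gKCa = p[3]; gKATP_bar = p[4]
    gKir = p[5]; gleak = p[6]; VK = p[7]; VCa = p[8]; vm = p[9]; sm = p[10]
    vn = p[11]; sn = p[12]; tau_n = p[13]; Kc = p[14]
    fcyt = p[15]; alpha = p[16]; kpmca = p[17]; kleak = p[18]; kSERCA = p[19]
    fer = p[20]; Vcte = p[21]
    VKir = p[22]; sKir = p[23]; alpha_camp = p[24]; beta_camp = p[25]; Kcamp = p[26]
    vAC_bar = p[27]; alphaAC = p[28]; betaAC = p[29]; KACca = p[30]
    beta_amp = p[31]; Kamp = p[32]; amp_exp = p[33]
    vPDE_bar = p[34]; alphaPDE = p[35]; betaPDE = p[36]; KPDEca = p[37]; KPDEcamp = p[38]
    JGK = p[39]; vPFK = p[40]; lam = p[41]
    k1 = p[42]; k2 = p[43]; k3 = p[44]; k4 = p[45]
    f13 = p[46]; f23 = p[47]; f41 = p[48]; f42 = p[49]; f43 = p[50]
    kgpdh = p[51]; kFBP = p[52]; f6p_frac = p[53]
    Atot = p[54]; tau_a = p[55]; r_base = p[56]; r1 = p[57]
    w_pmca = p[58]; vgamma = p[59]; kgamma = p[60]
    kdd = p[61]; ktd = p[62]; ktt = p[63]
    frac_mgadp = p[64]; frac_adp3 = p[65]; frac_atp4 = p[66]

    clamp_flag = p[I_CLAMP_FLAG]
    fastmode = p[I_FASTMODE]
    fastparam = p[I_FASTPARAM]

    if fastmode == 2.0:
        cer = fastparam

    ATP, AMP = nucleotides(ADP, Atot)

    # --- membrane currents ---
    minf = 1.0 / (1.0 + np.exp((vm - V) / sm))
    ninf = 1.0 / (1.0 + np.exp((vn - V) / sn))
    w = c * c / (c * c + Kc * Kc)

    ICa = gCa * minf * (V - VCa)
    IK = gK * n * (V - VK)
    IKCa = gKCa * w * (V - VK)

    mgadp = frac_mgadp * ADP
    adp3 = frac_adp3 * ADP
    atp4 = frac_atp4 * ATP
    topo = 0.08 * (1.0 + 2.0 * mgadp / kdd) + 0.89 * (mgadp / kdd) ** 2
    boto = (1.0 + mgadp / kdd) ** 2 * (1.0 + adp3 / ktd + atp4 / ktt)
    oinf = topo / boto
    IKATP = gKATP_bar * oinf * (V - VK)

    kinf = 1.0 / (1.0 + np.exp((V - VKir) / sKir))
    if fastmode == 1.0:
        cinf = fastparam
    else:
        c4 = cAMP ** 4
        cinf = alpha_camp + beta_camp * c4 / (c4 + Kcamp ** 4)
    IKir = gKir * kinf * cinf * (V - VK)
    Ileak = gleak * (V - VK)

    dy[0] = -(IK + ICa + IKCa + IKATP + IKir + Ileak) / Cm
    dy[1] = (ninf - n) / tau_n

    # --- calcium ---
    Jmem = -alpha * ICa - kpmca * c
    JER = kleak * (cer - c) - kSERCA * c
    dy[2] = fcyt * (Jmem + JER)
    dy[3] = -fer * Vcte * JER

    # --- glycolysis: Smolen-type allosteric PFK ---
    a = AMP / k1
    b = FBP / k2
    ffr = F6P * F6P / k3
    tt = ATP * ATP / k4
    num = 0.0
    den = 0.0
    for i in range(2):
        wa = a if i == 1 else 1.0
        for j in range(2):
            wb = b if j == 1 else 1.0
            for l in range(2):
                wt = tt if l == 1 else 1.0
                base = wa * wb * wt
                if i == 1 and l == 1:
                    base /= f41
                if j == 1 and l == 1:
                    base /= f42
                den += base          # F6P not bound
                w1 = base * ffr      # F6P bound
                if i == 1:
                    w1 /= f13
                if j == 1:
                    w1 /= f23
                if l == 1:
                    w1 /= f43
                den += w1
                num += w1 * (lam if (i == 0 and j == 0) else 1.0)
    JPFK = vPFK * num / den

    FBPpos = FBP if FBP > 0.0 else 0.0
    JGPDH = kgpdh * np.sqrt(FBPpos)
    dy[4] = f6p_frac * (JGK - JPFK)
    dy[5] = JPFK - kFBP * JGPDH

    # --- adenine nucleotides ---
    # ATP production rises with glycolytic flux (gamma); hydrolysis scales
    # with the Ca2+-ATPase pump load (plasma-membrane + SERCA), so SERCA
    # block relieves part of the hydrolytic burden
    gamma = vgamma * JGPDH / (kgamma + JGPDH)
    hyd = (w_pmca * kpmca + kSERCA) * c / r1
    dy[6] = (ATP - ADP * np.exp((r_base + gamma) * (1.0 - hyd))) / tau_a

    # --- cAMP turnover ---
    c3 = c * c * c
    acca = alphaAC + betaAC * c3 / (c3 + KACca ** 3)
    ampf = beta_amp * Kamp ** amp_exp / (AMP ** amp_exp + Kamp ** amp_exp)
    VAC = vAC_bar * acca * ampf
    pdeca = alphaPDE + betaPDE * c3 / (c3 + KPDEca ** 3)
    VPDE = vPDE_bar * pdeca * cAMP / (cAMP + KPDEcamp)
    dy[7] = VAC - VPDE

    if clamp_flag != 0.0:
        dy[7] = 0.0
    if fastmode != 0.0:
        dy[3] = 0.0
        dy[4] = 0.0
        dy[5] = 0.0
        dy[6] = 0.0
        dy[7] = 0.0


@njit(cache=True)
def integrate_grid(
    y0: np.ndarray,
    p: np.ndarray,
    tgrid: np.ndarray,
    rtol: float,
    atol: np.ndarray,
    max_step: float,
    first_step: float,
) -> tuple[np.ndarray, int, float]:
    """Adaptive Dormand–Prince 5(4) integration sampled onto ``tgrid``.

    Output values on the grid are linearly interpolated within accepted
    steps; ``max_step`` bounds the interpolation error (simulate.py caps it
    at the output spacing).  Returns (samples, status, t_reached) with
    status 0 on success, 1 on step-size underflow / non-finite state.
    """
    nT = tgrid.shape[0]
    ny = y0.shape[0]
    out = np.empty((nT, ny))
    out[0] = y0
    t = tgrid[0]
    tend = tgrid[nT - 1]
    y = y0.copy()

    k1 = np.empty(ny); k2 = np.empty(ny); k3 = np.empty(ny)
    k4 = np.empty(ny); k5 = np.empty(ny); k6 = np.empty(ny); k7 = np.empty(ny)
    ytmp = np.empty(ny)
    ynew = np.empty(ny)
    yerr = np.empty(ny)

    rhs(t, y, p, k1)
    h = first_step
    hmin = 1e-10
    idx = 1
    while idx < nT:
        if h > max_step:
            h = max_step
        if t + h > tend:
            h = tend - t
        # Dormand-Prince stages
        for m in range(ny):
            ytmp[m] = y[m] + h * (0.2 * k1[m])
        rhs(t + 0.2 * h, ytmp, p, k2)
        for m in range(ny):
            ytmp[m] = y[m] + h * (3.0 / 40.0 * k1[m] + 9.0 / 40.0 * k2[m])
        rhs(t + 0.3 * h, ytmp, p, k3)
        for m in range(ny):
            ytmp[m] = y[m] + h * (44.0 / 45.0 * k1[m] - 56.0 / 15.0 * k2[m] + 32.0 / 9.0 * k3[m])
        rhs(t + 0.8 * h, ytmp, p, k4)
        for m in range(ny):
            ytmp[m] = y[m] + h * (19372.0 / 6561.0 * k1[m] - 25360.0 / 2187.0 * k2[m]
                                  + 64448.0 / 6561.0 * k3[m] - 212.0 / 729.0 * k4[m])
        rhs(t + 8.0 / 9.0 * h, ytmp, p, k5)
        for m in range(ny):
            ytmp[m] = y[m] + h * (9017.0 / 3168.0 * k1[m] - 355.0 / 33.0 * k2[m]
                                  + 46732.0 / 5247.0 * k3[m] + 49.0 / 176.0 * k4[m]
                                  - 5103.0 / 18656.0 * k5[m])
        rhs(t + h, ytmp, p, k6)
        for m in range(ny):
            ynew[m] = y[m] + h * (35.0 / 384.0 * k1[m] + 500.0 / 1113.0 * k3[m]
                                  + 125.0 / 192.0 * k4[m] - 2187.0 / 6784.0 * k5[m]
                                  + 11.0 / 84.0 * k6[m])
        rhs(t + h, ynew, p, k7)
        # embedded 4th-order error estimate
        errnorm = 0.0
        ok = True
        for m in range(ny):
            yerr[m] = h * ((35.0 / 384.0 - 5179.0 / 57600.0) * k1[m]
                           + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3[m]
                           + (125.0 / 192.0 - 393.0 / 640.0) * k4[m]
                           + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5[m]
                           + (11.0 / 84.0 - 187.0 / 2100.0) * k6[m]
                           - 1.0 / 40.0 * k7[m])
            if not np.isfinite(ynew[m]):
                ok = False
            ay = abs(y[m])
            an = abs(ynew[m])
            sc = atol[m] + rtol * (ay if ay > an else an)
            e = yerr[m] / sc
            errnorm += e * e
        errnorm = np.sqrt(errnorm / ny)
        if ok and errnorm <= 1.0:
            # accept: emit grid points covered by this step
            tnew = t + h
            while idx < nT and tgrid[idx] <= tnew + 1e-12:
                s = (tgrid[idx] - t) / h
                for m in range(ny):
                    out[idx, m] = y[m] + s * (ynew[m] - y[m])
                idx += 1
            t = tnew
            for m in range(ny):
                y[m] = ynew[m]
                k1[m] = k7[m]  # FSAL
            fac = 0.9 * errnorm ** -0.2 if errnorm > 1e-10 else 5.0
        else:
            fac = 0.9 * errnorm ** -0.2 if (ok and errnorm > 1e-10) else 0.2
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
        if h < hmin:
            return out, 1, t
    return out, 0, tend
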