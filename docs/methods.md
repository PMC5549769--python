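# Methods

## The model

`isletburst` implements an eight-variable Dual Oscillator Model (DOM) of a
pancreatic islet β-cell. The state is

    y = (V, n, c, c_er, F6P, FBP, ADP_c, cAMP)

with membrane potential `V` (mV), delayed-rectifier activation `n`,
cytosolic and ER free Ca²⁺ `c`, `c_er` (μM), the glycolytic metabolites
fructose 6-phosphate `F6P` and fructose 1,6-bisphosphate `FBP` (μM),
cytosolic ADP (μM), and cAMP (μM). ATP and AMP are not integrated: they
follow from ADP through the conserved adenine-nucleotide total
`ATP + ADP + AMP = A_tot` and the adenylate-kinase equilibrium
`AMP·ATP = ADP²`, which give a closed-form quadratic for ATP (the larger
root is the physical one; the triple satisfies the conservation total
exactly by construction).

### Membrane and calcium

    C_m dV/dt = −(I_K + I_Ca + I_K(Ca) + I_X)
    dn/dt     = (n∞(V) − n)/τ_n
    dc/dt     = f_cyt (−α I_Ca − k_pmca c  +  k_leak(c_er − c) − k_SERCA c)
    dc_er/dt  = −f_er V_cte (k_leak(c_er − c) − k_SERCA c)

`I_Ca = g_Ca m∞(V)(V − V_Ca)` with instantaneous Boltzmann activation,
`I_K = g_K n (V − V_K)`, and `I_K(Ca) = g_KCa ω(c)(V − V_K)` with
`ω = c²/(c² + K_c²)`. `I_X` is the variant-defining metabolically gated
K⁺ current:

* **WT_KATP** — `I_K(ATP) = ḡ_KATP o∞(ATP, ADP)(V − V_K)` with a
  Magnus–Keizer-type open fraction: MgADP activates, free ADP³⁻ and ATP⁴⁻
  block. `o∞` is strictly positive for any nucleotide state.
* **KO_KIR21** — `I_Kir = g_Kir k∞(V) c∞(cAMP)(V − V_K)`, where
  `k∞ = 1/(1 + exp((V − V_Kir)/s_Kir))` is the voltage-dependent polyamine
  block (inward rectification; monotone decreasing in V) and
  `c∞ = α_camp + β_camp·cAMP⁴/(cAMP⁴ + K_camp⁴)` is the cAMP/PKA-dependent
  activation, bounded in `[α_camp, α_camp + β_camp)`.
* **KO_LEAK_KCA** — a constant-conductance leak `I_leak = g_leak (V − V_K)`
  with `g_leak = 32.5 pS`, together with an elevated `g_KCa = 90 pS`.

Exactly one of `ḡ_KATP`, `g_Kir`, `g_leak` is non-zero in a valid
parameter set; calling a current that is not part of the active variant is
a contract violation, not a zero.

### cAMP turnover

    dcAMP/dt = V_AC − V_PDE
    V_AC  = v̄_AC (α_AC + β_AC c³/(c³+K_ACca³)) · (β_amp K_amp^h/(AMP_c^h + K_amp^h))
    V_PDE = v̄_PDE (α_PDE + β_PDE c³/(c³+K_PDEca³)) · cAMP/(cAMP + K_PDEcamp)

Ca²⁺ stimulates both adenylyl cyclase and phosphodiesterase; cytosolic AMP
inhibits the cyclase. The AMP Hill exponent `h` defaults to 2 and is
exposed as a parameter (`amp_exp`) so higher-order AMP dependence can be
explored. The closed-form steady state used by the fast/slow analysis is

    cAMP_ss = K_PDEcamp · V_AC / (v̄_PDE(α_PDE + β_PDE c³/(c³+K³)) − V_AC)

which has no finite value when the cyclase rate reaches the maximal PDE
capacity; the slow-curve routines record such grid points as gaps.

### Glycolysis and nucleotides

The slow oscillator is a substrate-depletion relaxation cycle built on a
16-state allosteric phosphofructokinase (PFK) rate law of the Smolen type:
binding weights for AMP (activator), FBP (product activator), F6P
(substrate, entering squared) and ATP (inhibitor, squared), with pairwise
interaction factors `f13, f23, f41, f42, f43`; states with F6P bound
catalyse, at relative rate `λ` when no activator is bound.

    dF6P/dt = f6p_frac (J_GK − J_PFK)
    dFBP/dt = J_PFK − k_FBP · J_GPDH,      J_GPDH = k_gpdh √FBP
    dADP/dt = (ATP − ADP exp((r + γ)(1 − hyd)))/τ_a

`J_GK` is the constant glucokinase influx (0.09 μM/ms wild type,
0.14 μM/ms knockout). `k_FBP` (0.8 wild type, 0.95 knockout) is
implemented as the dimensionless stoichiometric weight of FBP consumption
by the downstream (GPDH) flux — the main text names the constant and its
values but not its position, and this is the simplest placement consistent
with its dimensionless value and its role as a glycolytic throughput
parameter. `γ = v_γ J_GPDH/(k_γ + J_GPDH)` is the glycolytic boost of ATP
production, and `hyd = (w_pmca·k_pmca + k_SERCA)·c/r1` ties ATP hydrolysis
to the Ca²⁺-ATPase pump load. Writing the hydrolysis term through the pump
rates (instead of bare `c`) matters for pharmacology: SERCA block removes
part of the hydrolytic burden, which lowers the AMP floor and lengthens
the knockout burst period under thapsigargin, the direction seen
experimentally.

The oscillation mechanism deserves a note because it constrains several
constants jointly. With `J_GK` fixed at its printed value, a multi-minute
period forces millimolar F6P excursions (the refill rate is bounded by
`f6p_frac·J_GK ≈ 0.03 μM/ms`). The cycle works as follows: on the low-flux
branch PFK throughput saturates below `J_GK` (small `λ`, weak AMP binding
synergy), so F6P accumulates for minutes; when the FBP-activation loop
ignites (an autocatalytic runaway whose position is set by
`K_f6p = 1.2·10⁹ μM²`), flux jumps several-fold, F6P burns down, FBP
crashes, and the cycle restarts. The same constants with only the printed
`J_GK`/`k_FBP` differences give a wild-type period near 11 min and a
knockout period near 7 min — close to the recorded cohort values
(10.6 ± 0.9 and 7.3 ± 1.2 min) without separate tuning.

### Parameter provenance

Parameter files (`src/isletburst/parameter_sets/*.yaml`) carry a value,
unit and source note per entry. Values printed in the primary literature
for this model family (the glucokinase rates, `k_FBP`, the leak-variant
conductances, the thapsigargin factor) are used verbatim; the remaining
constants were calibrated once so that each variant reproduces its
qualitative phenotype (slow bursting of the right period and duty cycle,
plateau-riding spikes, rest near −60 mV, cAMP swinging across the Kir
activation threshold) and are not tuned per experiment. The loader rejects
unknown keys, missing keys and wrong units outright.

## Numerics

* **Integration.** The right-hand side is compiled (numba); the default
  integrator is an in-package adaptive Dormand–Prince 5(4) with per-state
  absolute tolerances and `rtol = 1e-8` (configurable). scipy's stiff
  solvers (LSODA/Radau/BDF) are available behind the same interface and are
  used as a cross-check in the tests. Output is sampled on a uniform grid
  (default 100 ms); the maximum internal step is capped at the output
  spacing so linear in-step interpolation stays accurate.
* **Protocols.** Treatment events (thapsigargin = `k_SERCA/factor`,
  8-Br-cAMP = cAMP derivative masked to zero at a stated concentration,
  arbitrary parameter changes) stop and restart the integrator at the event
  time; discontinuities are never smoothed or interpolated across. The
  first 20 simulated minutes are marked as transient, not deleted.
* **Initial conditions.** A damped root solve of the full vector field from
  a hyperpolarized guess, nudged 1 mV off the fixed point. The transient
  window absorbs the remaining settling.
* **Determinism.** Simulation uses no random numbers anywhere; the only
  randomness in the package is the seeded synthetic-trace generator.

## Fast/slow analysis

The fast subsystem is `(V, n, c)`; the bifurcation parameter is the Kir
activation `c∞` (Kir knockout, with `c_er` clamped at its burst-cycle
mean) or `c_er` itself (leak knockout). Implementation choices:

* Equilibria are continued by pseudo-arclength (scaled variables, step
  halving on corrector failure, truncation with a warning record below the
  minimum step), with finite-difference Jacobian eigenvalues and stability
  flags at every point. Because `n` and `c` are explicit functions of `V`
  at equilibrium, the branch also admits a closed-form parameterization by
  voltage; this is used as an independent cross-check and to refine fold
  positions by bracketed root-finding on `dp/dV`.
* Hopf points are located by bisection on the real part of the complex
  eigenvalue pair.
* Limit cycles are continued by single shooting with unknowns
  `(x₀, T, p)`, an anchoring phase condition, and pseudo-arclength
  stepping. Floquet multipliers come from the central-difference monodromy
  matrix; the trivial multiplier is reproduced to ~1e-6 away from the
  homoclinic limit (and degrades as the monodromy becomes ill-conditioned
  near it, which the tests acknowledge).
* A period blow-up endpoint is classified SNIC when the terminal parameter
  coincides with an equilibrium fold (within 5% of the cycle-branch span),
  homoclinic when it is interior to the fold interval; the asymptotic
  period-scaling exponent is recorded as a diagnostic, never enforced.
  Period-doubling points are flagged where a real multiplier crosses −1,
  and the period-doubled branch can be continued by settling the flow just
  past the PD point (used for the SERCA-block cascade in the leak model).

In this reconstruction the leak/K(Ca) diagram shows the expected wide
bistable interval with a homoclinic termination far from the lower knee
(square-wave bursting), while the Kir diagram's cycle branch terminates in
a homoclinic close to the knee with only a narrow bistable sliver. The
published dichotomy is stronger (no bistability at all and a true SNIC in
the Kir case); our spiking orbit's minima stay ~10 mV above the knee
voltage, so the saddle catches the orbit slightly before the fold. The
quantitative gap (bistable widths, terminal-parameter offsets) is reported
by the analysis rather than hidden. Known limitation; see the ledgered
analysis of what was tried.

## Burst analytics

Active phases are segmented by hysteresis (onset at an upward crossing of
the 60% level of the per-epoch robust range, offset at a downward crossing
of the 40% level; phases shorter than 30 s discarded). All thresholds are
range-relative, making every statistic invariant to affine rescaling of
the signal — fura-2 ratio units are arbitrary and treatments shift
baseline and amplitude, so post-treatment epochs are re-ranged and
classified against the pre-treatment range. Period is the mean
onset-to-onset interval (onsets are the sharp edge of relaxation-type
oscillations); duty cycle is mean active duration over the period.
Classification is total: `silent`, `continuous_spiking`, `fast_bursting`
(period < 1 min; an order of magnitude below the 5–12 min slow rhythms),
or `slow_bursting`. An amplitude collapse below 5% of the pre-treatment
range, or below five times the recording's own high-frequency noise level,
counts as quiescence even if residual drift crosses the (tiny)
epoch-relative thresholds.

The phase relation between two oscillatory traces is the circular
cross-correlation peak lag normalized by the period; anti-phase signals
give ≈ 0.5. Spike-averaged voltage replaces each spike (a local maximum
above a 5-mV prominence) by its mean over the flanking troughs, exposing
the slow burst envelope; conductance traces are smoothed with a centered
6-s moving mean to suppress fast voltage-dependent gating.

## Synthetic fura-2 traces

The generator emulates what the analysis pipeline assumes about real
recordings: square-wave-like plateaus with 10-s logistic edges, an
optional linear within-plateau decline (the ER-leak signature, abolished
by SERCA block), linear baseline drift, additive Gaussian noise, and an
epoch switch at a treatment time — new rhythm parameters (persistence),
a sustained elevated plateau (conversion), or return to baseline
(termination). Cohorts draw period and duty from truncated normal
distributions; the shipped study conditions use the recorded cohort
statistics (knockout 7.3 ± 1.2 min, duty 0.40 ± 0.08 pre-treatment,
7.6 ± 1.1 min and 0.60 ± 0.06 after SERCA block; wild type 10.6 ± 0.9 min,
duty 0.5 ± 0.06). A seed is mandatory and reproduces a trace bit-for-bit.

What the generator does **not** emulate: photobleaching and other
nonstationary noise, islet-to-islet waveform diversity beyond
period/duty/amplitude, sampling jitter, movement artifacts, and partial or
mixed treatment responses. Passing parameter-recovery and cohort tests
therefore demonstrates that the analysis is correct for clean
square-wave-like data of the stated SNR, not that it is robust to every
pathology of real recordings.

## Problem sizes used

Test and acceptance runs use 70–200 simulated minutes per trace (enough
for ≥ 5 pre-treatment cycles and ≥ 8 post-treatment cycles of the slowest
rhythm), 50-trace recovery grids, and continuation branches of a few
hundred points; these sizes were chosen so the full suite re-runs in well
under half an hour on one core while every statistic retains at least a
few cycles of averaging.
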