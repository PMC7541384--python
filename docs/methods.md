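# Methods

## The model

The circulation is a closed electrical-analog network: pressure ↔ voltage,
flow ↔ current, blood-volume storage ↔ capacitor charge.  Twenty-five
capacitive compartments (4 chambers, proximal aorta, three proximal aortic
branches, four terminal upper-body arteries, proximal systemic artery,
systemic veins, vena cava, four upper-body venous reservoirs, and six
pulmonary compartments — left/right proximal artery, distal artery, veins)
are connected by resistive edges, some with series inertance and some with
ideal diodes (the four heart valves plus venous check valves).  The state
vector is the volume of every compartment plus the flow of every inductive
edge; node pressures are algebraic functions of the local volume, and the
ODE is the flow balance

    dV_i/dt = Σ inflows − Σ outflows,     dQ_j/dt = (P_up − P_down − R·Q_j)/L_j.

Because every edge moves volume from one node to another, the analytic sum
of all volume derivatives is identically zero; the integrated total drifts
only at machine-precision level (~10⁻¹⁰ ml over 700 s).

### Chambers

Each chamber interpolates between an end-diastolic envelope
P_ED = M₀|exp(λ(V−V₀))−1| and an end-systolic envelope
P_ES = a(F_con)·E_es·(V−V_d) with a periodic activation e(t).  Ventricles
use a four-Gaussian activation of the form exp[−((b·φ−C_i)/B_i)²] where
φ is the cardiac phase and b(F_con) shortens systole with sympathetic
tone; atria use a single Gaussian with the exp[−0.5(·)²] convention and
unit time scale.  The two exponent conventions differ deliberately — each
is implemented exactly as its source formula is printed, and a brute-force
oracle in the tests pins both.  Atria take a ≡ 1.

Activation components whose centers sit at the period boundary are
evaluated without a periodic image; at the widths involved (B ≈ 0.04 s)
the neglected tail is below 10⁻⁴⁰.  Scheduled amplitudes that would
extrapolate negative are clamped at zero (activation is a physical
fraction), and the activation total is floored at zero.

### Vessels

Linear compartments use P = V/C.  The systemic veins, vena cava and
proximal systemic artery carry the published nonlinear laws (log₁₀
stiffening; piecewise exponential/linear with the boundary volume assigned
to the linear branch exactly as printed — the ~0.39 mmHg jump at the seam
is tolerated by the solver; vasoconstriction-weighted active/passive
blend).  Remodelled pulmonary vessels use the saturating law
P = −K ln(1−V/V_m), whose pole at V_m is guarded: states with
V ≥ 0.999·V_m abort the run with a physiological-limit error naming the
compartment rather than returning unbounded pressures.

Volume-dependent resistances (vena cava, proximal systemic artery) are
evaluated continuously at every derivative call — they are cheap closed
forms and nothing in their definition suggests per-cycle freezing.

### Heart rate and clock

Hr = h₁ + h₂F_s − h₃F_s² − h₄F_v + h₅F_v² − h₆F_vF_s, all frequencies
normalized to [0,1] and fixed at 0.5 for every run (no baroreflex loop:
frequencies are inputs, never state).  The shipped configuration sets the
cycle duration explicitly to T = 0.7845 s; when a configuration omits T it
is derived once as 60/Hr and held constant.  Cycle summaries use
Hr = 60/T so stroke volume × rate is internally consistent.

## Numerical scheme

Classical 4th-order fixed-step Runge–Kutta at dt = 0.0005 s (the step size
the scenarios were designed around; only the step, not the scheme, is
prescribed by the source material, and RK4 is robust for the mildly stiff
diode switching at this step).  Ideal diodes are resolved from the
instantaneous pressure difference inside every derivative evaluation — no
event location.  Halving the step changes converged systolic pressures by
well under 0.5% (tested), and on a linear two-compartment loop the solver
shows the expected 4th-order convergence against the closed-form solution.

The inner loop is numba-compiled; a pure-Python right-hand side built from
the scalar law functions serves as an independent oracle and is held
against the kernel to 12 digits in the tests.  Node and edge ordering are
fixed at build time, so trajectories are bit-reproducible and CSV exports
byte-identical across runs.

Integration proceeds cycle by cycle: at every cycle boundary the active
scenario schedule rewrites the constant arrays (disease parameters are
frozen *within* a cycle), consuming the previous cycle's per-node pressure
statistics.  One parameter snapshot is recorded per completed cycle
(892 for a 700 s run at T = 0.7845 s).

## Disease schedules

Disease time is simulation time: the clinical course of months–years is
compressed onto the 700 s run, and all rate coefficients are per second of
simulation time.  All four scenarios keep heart rate, systemic circuit and
frequencies at their normal values; only the published scheduled
quantities move.

* **dpas** — distal resistances R_pad(t) = (1+g_r t)·R_pad,0 from the
  r(t) = (1+g_r t)^(−1/4) radius law; distal compliances
  C(t) = τ(t)r⁴/R₀ with τ(t) = τ₀e^(−σt) (so R·C = τ holds identically);
  proximal arteries switch to the log law (K = 20 mmHg, V_m = 100 ml) at
  t = 0; RV elastance ramps at k₁ = 0.0013 s⁻¹ until the cycle-averaged
  mPAP (= sPAP/3 + 2dPAP/3 of the previous completed cycle, averaged over
  the two symmetric proximal arteries) first reaches 50 mmHg, then at
  k₂ = 0.0008; the breakpoint time t_c is immutable once set and the ramp
  is continuous there.
* **lvdd** — M_lv, λ_lv ramps; all six pulmonary compartments switch to
  log laws whose K(t) grow linearly, clamped to the published admissible
  intervals (19–56 proximal, 14–49 distal, 4–37 venous; the clamps never
  engage within 700 s); pulmonary resistances follow
  R = τ(t)/(g_c e^(−h_c P_m)) with P_m the compartment's previous-cycle
  mean pressure (resistances keep their normal values for cycle 0, before
  any cycle statistics exist); LA elastance/EDPVR ramps; LA activation
  replaced by the ten-Gaussian table with linearly scheduled amplitudes.
* **vsd** — a shunt resistor between the ventricles (no diode: flow may
  reverse) with R_ltor(t) = 100/(1+0.0408t)²; pulmonary K(t) and R
  schedules as in lvdd with the vsd coefficient block; RV and LA elastance
  ramps; three-Gaussian LA activation with a constant first peak and
  growing second peak.
* **ms** — mitral resistance R_m(t) = 0.02+0.0003t on the valve edge; LA
  elastance/EDPVR ramps; three-Gaussian LA activation with a shrinking
  first peak, growing second peak, and an additive baseline term k_x1·t
  read on the disease-time scale (constant within each cycle).  The
  baseline raises the diastolic atrial pressure floor as the disease
  progresses; read as a within-cycle ramp it would peak at 2.6·10⁻⁴ and
  do nothing, so the disease-time reading is adopted.

## The calibrated fixture

The per-compartment element values of the original platform's appendix are
not available in machine-readable form, so the shipped configuration is
*calibrated*: the published constants (chamber tables, activation tables,
heart-rate and contractility constants, the nonlinear systemic-reservoir
constants, initial pulmonary resistances 0.05/0.06/0.07 mmHg·s/ml) are
fixed, and the remaining compliances, branch resistances, inertances and
initial volumes were tuned, by iterating normal 30–60 s runs, to the
normal targets: LV systolic ≈ 122 mmHg, aortic 80–120 mmHg, cardiac output
5–6 L/min, pulmonary artery ≈ 20/12 mmHg, systemic-vein volume ≈ 2610 ml,
total volume 4711 ml.  The resulting operating point is LV 122.8 mmHg,
aorta 83.8–121.7 mmHg, CO 5.17 L/min, PA ≈ 22/9 mmHg (mPAP 13.3).

Calibration choices worth knowing:

* **Resistance placement.**  The source tables give one resistance per
  pulmonary compartment without printing its position relative to the
  capacitor.  The standard inlet-resistance Windkessel convention is used:
  each compartment's resistance sits on its inflow edge, with the proximal
  arteries' resistance in series with the pulmonary valve and a small
  calibrated outlet resistance (0.08 mmHg·s/ml) from the pulmonary veins
  into the LA.  With the alternative outlet placement the stenosed distal
  resistance never carries pulsatile inflow and the distal-stenosis
  endpoint falls ~20 mmHg short; inlet placement reproduces it.
* **Inertance.**  The proximal→distal pulmonary branches carry
  0.005 mmHg·s²/ml of blood inertia (the third Windkessel element),
  sharpening the normal pulmonary pulse; systemic inertances sit on the
  four proximal aortic branches.
* **Viscoelastic resistances.**  The per-capacitor viscoelastic resistors
  of the original figure are folded into the adjacent edge resistances
  (series equivalence), keeping the volume-state ODE explicit.
* **Peripheral branches.**  Head/arm/limb arteries and their veins are
  parallel linear R(-L)-C chains between the aorta and the vena cava whose
  split is part of the fixture; only aggregate systemic behavior is
  validated.  The wiring lives entirely in the config edge list and can be
  changed without touching the solver.
* **Continuity with the schedules.**  Normal distal pulmonary compliance
  is 9 ml/mmHg (= τ₀/R_pad,0) so the stenosis schedule is continuous at
  t = 0; every scheduled scalar equals its normal value at t = 0 (tested).

## What the simulations do and do not show

The platform reproduces: the normal operating point above; a
distal-stenosis run ending at RV systolic ≈ 94 mmHg (target 90 ± 5) with
monotonically rising mPAP; an LVDD run whose late left-atrial P-V path is
two-lobed (self-intersecting) while the normal loop is simple, with K(t)
inside the published intervals throughout; a VSD run with strictly
left-to-right shunting early, the exact R_ltor(t) law, and substantial
transient reversal only late in the run.

The mitral-stenosis endpoint falls short: the run ends at RV systolic
≈ 64 mmHg versus the published 78 ± 5.  The shortfall is structural, not a
coefficient error: with the published activation tables the mitral valve
is open ≈ 0.52 s of the 0.7845 s cycle, so in steady state the transmitral
gradient is R_m·SV/t_open ≈ 26–29 mmHg at the run's stroke volume, capping
mean LA pressure near 30 mmHg and with it the entire pulmonary pressure
chain.  Reaching 78 mmHg would require a cardiac output *above normal* at
the MS endpoint (≈ 6.9 L/min) or a filling window half as long — neither
consistent with the published chamber tables and the normal-state targets.
Calibration variants that raise the MS endpoint (higher cardiac output,
larger pulmonary-vein outlet resistance) push the distal-stenosis endpoint
and the normal aortic/LV targets out of range first.  The corresponding
acceptance test is left failing rather than loosened.

Beyond that, the usual 0D caveats apply: no wave propagation or 1D vessel
mechanics, no baroreflex feedback, no Eisenmenger terminal stage beyond
the emergent transient right-to-left flow, and the peripheral-branch split
is a modelling convenience, not anatomy.  Waveform *shapes* are
qualitative; only the cycle-level numbers above are quantitative claims.

## Problem sizes

Defaults: 700 s runs (892 cycles, 1.4 M steps) for disease scenarios, 30–35 s
for normal-state checks; recording decimated to every 10th step (2 ms)
for interactive use and every 20th in the heaviest tests.  A full 700 s
run integrates in a few seconds once the kernel is compiled.
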