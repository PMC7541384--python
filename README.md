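# pulmosim

A lumped-parameter ("0D") electrical-analog simulator of the closed human
circulation — four time-varying-elastance heart chambers, Windkessel and
nonlinear vessel compartments, ideal-diode valves — together with four
*time-progressive pulmonary-hypertension (PH) scenarios* that grow out of
the normal state over a 700 s run:

| scenario | etiology | mechanism in the model |
|----------|----------|------------------------|
| `dpas` | distal pulmonary artery stenosis | Poiseuille radius shrinkage: R ∝ r⁻⁴ grows, RC-time decay shrinks distal compliance, RV elastance compensates (piecewise ramp with an mPAP = 50 mmHg breakpoint) |
| `lvdd` | LV diastolic dysfunction | EDPVR stiffening (M_lv, λ_lv ramps), saturating-log pulmonary P-V laws with growing stiffness K(t), pressure-coupled pulmonary resistances, ten-Gaussian left-atrial activation |
| `vsd`  | ventricular septal defect | interventricular resistive shunt R_ltor(t) = R₀/(1+k_r t)² collapsing from 100 to ~0.11 mmHg·s/ml, plus pulmonary remodelling |
| `ms`   | mitral stenosis | mitral resistance ramp R_m(t) = 0.02 + 0.0003 t, left-atrial compensation, pulmonary remodelling |

The target audience is computational-physiology and hemodynamics
researchers (and educators) who want a self-contained, deterministic,
tested platform for studying how chamber, valve and vessel parameter
changes propagate through a closed circulation.

## Model core

Each chamber blends an end-systolic and an end-diastolic pressure–volume
relation through a periodic Gaussian-sum activation e(t) ∈ [0, 1]:

    P(V, t) = e(t) · a(F_con) E_es (V − V_d)  +  (1 − e(t)) · M₀ |exp(λ(V − V₀)) − 1|

Vessels are linear compartments P = V/C except the systemic veins
(−K_v·log₁₀(V_max/V − 0.99)), vena cava (piecewise, volume-dependent
resistance), proximal systemic artery (vasoconstriction-weighted blend) and
the remodelled pulmonary vessels (P = −K ln(1 − V/V_m)).  The circuit is a
single closed loop over 25 compartments; volumes and inductor flows form
the ODE state, integrated by fixed-step RK4 (dt = 0.0005 s, numba-compiled)
with diode valves resolved per derivative evaluation.  Disease parameters
are frozen within each cardiac cycle and updated at cycle boundaries.

Heart rate follows the sympathetic/vagal response surface
Hr = h₁ + h₂F_s − h₃F_s² − h₄F_v + h₅F_v² − h₆F_vF_s, which gives
76.5 bpm at the default frequencies (cycle T = 0.7845 s).  Total blood
volume is 4711 ml and is conserved to machine precision.

The per-compartment circuit constants (compliances, branch resistances,
inertances, initial volumes) are a **calibrated fixture**
(`src/pulmosim/data/normal.yaml`) tuned so the normal run reproduces
textbook hemodynamics; the calibration procedure and every modelling
choice is documented in [`docs/methods.md`](docs/methods.md).

## Worked example

```bash
pulmosim --scenario normal --duration 30
```

prints (deterministically):

```
scenario=normal  duration=30.0 s  dt=0.0005 s  cycles=38
LV systolic:  first cycle   140.8 mmHg   last cycle   122.8 mmHg
RV systolic:  first cycle    36.5 mmHg   last cycle    30.3 mmHg
aortic P:     last cycle 83.9-121.8 mmHg
mPAP:         first cycle    15.8 mmHg   last cycle    13.3 mmHg
cardiac output (last cycle): 5.17 L/min
total-volume drift: 7.19e-11 ml
```

The first cycle reflects the startup transient; after a few beats the loop
settles into a periodic state with a left-ventricular systolic pressure of
~123 mmHg, an aortic pressure swinging over ~84–122 mmHg and a cardiac
output of 5.2 L/min — a normal resting human circulation.  A disease run,

```bash
pulmosim --scenario dpas --duration 700 --out results/dpas --figures
```

ends with an RV systolic pressure of 94.1 mmHg and mPAP of 48.5 mmHg
(severe pulmonary hypertension grown from the same normal start), writing
trajectory/flow/cycle-summary/parameter-snapshot CSVs and P-V-loop figures.

The same is available as a library:

```python
import pulmosim
traj = pulmosim.run_scenario("ms", duration=700)
last = pulmosim.summarize_cycles(traj)[-1]
V, P = pulmosim.pv_loop(traj, "la", traj.n_cycles - 2)   # two-lobed LA loop
```

## Layout

```
src/pulmosim/
  parameters.py    constants registry, config I/O, heart-rate law, clock
  chambers.py      elastance chamber models and activation functions
  vasculature.py   vessel P-V and resistance laws, stenosis machinery
  topology.py      circuit assembly into flat solver arrays
  engine.py        numba RK4 kernel (ideal diodes, domain guards)
  network.py       integration driver, Trajectory, pure-Python reference
  pathologies.py   per-cycle disease schedules (dpas/lvdd/vsd/ms)
  analysis.py      cycle summaries, P-V loops, CSV export
  cli.py           `pulmosim` command-line entry point
  data/normal.yaml calibrated default configuration
```
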