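# clotlyse

Kinetic modeling and turbidimetric analysis of fibrin clot formation and
**two-regime fibrinolysis**.

In turbidimetric clot-lysis assays (fibrinogen + plasminogen + tPA + PAI-1,
clotted with thrombin, light attenuation recorded once per minute), the
lysis of the clot ubiquitously proceeds in two regimes: a long **slow**
phase in which normalized turbidity (NT) rises linearly, followed by a
**fast** sigmoidal phase that completes the lysis.  `clotlyse` implements a
complete computational treatment of this observation, for researchers
modeling fibrinolysis or analyzing plate-reader/turbidimeter lysis curves:

* **Turbidity analysis** — slice (1 in 3), Savitzky–Golay smooth (11-point,
  cubic), min–max normalize; then extract the clot formation time
  (CFT = time of the turbidity minimum), total lysis time (TLT = time of
  maximal dNT/dt), the slow/fast split (SLT from a backward scan against
  the linear fit of NT between the 0.01 and 0.075 crossings, threshold
  Δ = 0.005; FLT = TLT − SLT), the slow-regime slope, and the regime
  ratios R_SL = SLT/(SLT+FLT), R_FL = 1 − R_SL.
* **Clot formation** — a polymerization ODE system (fibrinogen → monomer →
  oligomers f₂..f₁₀ → protofibrils → fibers, with lateral aggregation)
  coupled to reversible tPA/Pg adsorption on the growing fibers,
  Michaelis–Menten activation of bound Pg to bound plasmin by bound tPA,
  and irreversible PAI-1 inhibition of free tPA.  Produces the initial
  conditions for lysis: bound species, fibrin content and the mean fiber
  radius R_f0 = √(f_n^tot/(f_r·π·p₀)).
* **Fibrinolysis** — bound plasmin cleaves the fibrin in the κ outer
  protofibril "shells" of each fiber at rate
  dL/dt = γ·k_Pn2·[Pn_b]·Θ_Pn/(K_PnM + Θ_Pn), with the solubilization
  factor γ = 0.1, fiber radius R_f²(t) = R_f0²(1 − L/C_fr0) and porosity
  ε = 1 − (1−ε₀)(R_f/R_f0)².  The reaction depth κ is a policy: surface
  (κ = 0), full bulk (κ = R_f/r₀), fixed, or a schedule.
* **Shell-schedule fitting** — the central object of study: at every
  Δt = 0.1 s step, the κ minimizing the one-step squared error against a
  target NT curve is selected (greedy, ties to the smallest κ), yielding
  the time course of the shell fraction φ = κ_opt/κ_max.
* **Surrogate model** — needs no target curve: while R̃_f = R_f/R_f0 > 0.9
  the system is in the slow regime and φ is drawn from the slow-regime
  empirical distribution, below 0.9 from the fast one; SLT/FLT follow from
  the 0.9 and 0.6 radius crossings.
* **Parameter search** — grid screening of the six polymerization constants
  by simulated fiber diameter and ≥80% fibrinogen incorporation, rank-sum
  scoring of candidate sets against lysis curves, and Sobol sensitivity
  indices (Saltelli sampling) of any formation output.
* **Synthetic data** — seeded generators for eight-channel assay traces
  (piecewise-analytic curves with exact ground truth, or full forward-model
  traces), so everything above is testable without laboratory data.

## Worked example

```python
import numpy as np
from clotlyse import (
    SyntheticAssayConfig, generate_phenomenological, analyze_trace,
    run_clot_formation, ClotConstants, run_fibrinolysis,
)

# 1. a noise-free synthetic assay with the published mean timescales
cfg = SyntheticAssayConfig(noise_sd=0.0, n_channels=1)   # CFT 19, SLT 73, FLT 67 min
traces, truth = generate_phenomenological(cfg)
ts = analyze_trace(traces[0], keep_every=1)
print(f"CFT {ts.cft:.0f} min  SLT {ts.slt:.0f} min  FLT {ts.flt:.0f} min  "
      f"R_SL {ts.r_sl:.3f}")

# 2. clot formation for the control condition (3 mg/mL fibrinogen,
#    0.001/0.01/13 µg/mL tPA/PAI-1/Pg), best-ranked rate set, 1000 s
clot = run_clot_formation()
print(f"fiber radius {clot.rf0:.1f} nm, "
      f"incorporated {100 * clot.frac_incorporated:.0f}% of fibrinogen")

# 3. surface vs bulk lysis of that clot
cc = ClotConstants.from_clot_state(clot)
for policy in ("surface", "bulk"):
    traj = run_fibrinolysis(clot, policy, constants=cc, t_max=30000, record_every=10)
    slt = traj.t[np.argmax(traj.rf_norm <= 0.9)] / 60
    print(f"{policy:8s} slow regime ends (R̃f = 0.9) at {slt:.0f} min")
```

prints

```
CFT 20 min  SLT 72 min  FLT 67 min  R_SL 0.518
fiber radius 68.7 nm, incorporated 83% of fibrinogen
surface  slow regime ends (R̃f = 0.9) at 92 min
bulk     slow regime ends (R̃f = 0.9) at 63 min
```

The analysis recovers the generator's configured timescales to within one
sample; the formation model yields ~140 nm fiber diameters with >80% of the
fibrinogen in fibers; and surface-restricted lysis is distinctly slower
than bulk lysis — the gap the two regimes live in.

A command-line interface mirrors the library
(`clotlyse analyze|simulate-formation|simulate-lysis|fit-shells|surrogate|synth|grid-search|sobol|run`).

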