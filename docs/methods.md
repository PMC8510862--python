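# Methods

This note documents the models implemented in `clotlyse`, their
assumptions, the parameters that matter, and the numerical choices made
where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Turbidity analysis

The normalized-turbidity (NT) pipeline is the assay's standard recipe:

1. keep one sample in three (default; discards minute-scale sensor
   fluctuations),
2. Savitzky–Golay filter, 11-point window (five points each side), cubic
   polynomial — cubic because the curve changes concavity at the clotting
   minimum and at the fast-lysis inflection,
3. min–max normalize to [0, 1]; the span max − min is reported as
   Δturbidity.

Timescales: **CFT** is the time of the global NT minimum (ties to the
earliest sample).  **TLT** is the time of the maximal central-difference
derivative of the smoothed NT after CFT, reported as an offset from CFT.
The slow regime is characterized by a least-squares line through the
samples between the first post-CFT crossings of NT = 0.01 and NT = 0.075 —
these two levels do not define the regime, they only bound a stretch that
is safely inside it.  **SLT** is found by scanning backward in time from
the TLT point: it is the latest sample whose deviation from that line is
≤ Δ = 0.005, i.e. the last point still on the line.  **FLT** = TLT − SLT,
and the end of lysis is the first time after TLT with NT ≥ 0.95.

Choices the recipe leaves open, and what this implementation does:

* *Boundary handling for the filter*: mirror padding (five reflected
  samples per side), which avoids flattening a clotting minimum near the
  start of a record.
* *Crossings searched on smoothed NT* (not raw): the raw signal's
  minute-scale noise would make threshold crossings ambiguous.
* *SLT is not clamped* to the end of the fit window; on curves that never
  leave the fitted line the backward scan returns the TLT point itself.
* Times are minutes from trace start, except SLT/FLT/TLT which are offsets
  from CFT.

The Δ = 0.005 boundary is intentionally tight; on noisy channels where the
fitted slope is corrupted (short fit windows at coarse sampling) the
detectors raise typed errors rather than guessing.  This mirrors how such
channels are excluded from analysis in practice.

## Clot formation

Polymerization follows the classical kinetic scheme: thrombin-mediated
conversion of fibrinogen (kA), stepwise monomer addition up to 10-mers
(kPI), protofibril creation at the 11-monomer threshold, protofibril
elongation (kPG), protofibril–protofibril association into fibers (kFI),
protofibril addition to fibers (kFG), and fiber–fiber aggregation (kFA).
Bookkeeping species track protofibrils inside fibers (f_n^tot) and the
fibrin content of protofibrils (C_fn) and fibers (C_fr).  Total fibrin
M = f_a + f_1 + Σ j·f_j + C_fn + C_fr is conserved exactly (the oligomer
chain telescopes); the suite verifies dM/dt = 0 on random states to 1e-8
relative.  The kFA·f_r² term feeds f_n^tot as the scheme is published,
although it nominally creates protofibril count upon fiber–fiber
aggregation; it is kept as printed and is numerically negligible for the
default rates.

Polymerization runs in molecules·L⁻¹ (the published rate constants are
printed in L·molecules⁻¹·s⁻¹); the binding subsystem runs in µM; explicit
converters (`clotlyse.units`) sit at the interface.  One printed constant
is corrected: kPG appears with a positive exponent (10¹⁵), thirty orders
of magnitude beyond the diffusion limit; the value used is 1e-15
(configurable).

**Geometry.**  Fibers are cylinders of protofibrils packed at areal
density p₀ = 0.01116 nm⁻²; the mean radius is
R_f = √(f_n^tot/(f_r·π·p₀)).  The κ outer "shells" of thickness r₀
(protofibril radius, default 5 nm — consistent with p₀: the packing
spacing is 1/√p₀ ≈ 9.5 nm, i.e. ≈ 2·r₀) contain

    m(R_f, κ) = π·p₀·((R_f + r₀)² − max(R_f − κ·r₀, 0)²)

protofibrils — the annulus integral of the packing density.  The `max(·,0)`
keeps the inner integration boundary at the fiber axis once κ·r₀ exceeds
R_f; without it the closed form loses monotonicity in κ for sub-r₀ fibers.
κ = 0 exposes the outer half-layer ("the exposed side of the outer
protofibrils"); κ_max = ⌈R_f/r₀⌉ exposes the entire cross-section.

**Binding sites.**  The site concentration available to tPA (q = 1.5 sites
per fibrin monomer) and Pg (q = 2.4) is Θ = q·C_fr·(exposed fraction),
with the exposed fraction m(κ)/m(κ_max) — both numerator and denominator
from the same annulus integral, so the fraction is smooth, bounded in
(0, 1], and exactly 1 at full bulk.  An alternative `literal` mode
reproduces the raw sites-per-fiber product (C_fr/f_n^tot)·m·q for
comparison.  The bound-tPA fraction after clotting is sensitive to this
normalization (and to r₀); with the defaults the model leaves ≈3% of the
initial tPA fibrin-bound after 1000 s, at the upper edge of the "a few
percent" regime that makes lysis possible at all despite PAI-1 (free tPA
is >99% inhibited by then).  `scripts/acceptance.py` recomputes this
number from scratch.

During formation only adsorption is considered, at κ = 0 (surface);
binding, Michaelis–Menten activation of bound Pg by bound tPA
(k = 0.2 s⁻¹, K_M = 0.02 µM) and PAI-1 inhibition of free tPA
(k_i = 25 µM⁻¹s⁻¹) run concurrently with polymerization, with Θ recomputed
continuously inside the right-hand side.  Integration: LSODA, rtol 1e-8,
per-component atol (1e-12 of the fibrinogen load for polymerization
species, 1e-16 µM for binding species); the rate constants span >13 orders
of magnitude.  Clotting time is fixed at 1000 s; the final state (bound
species, C_fr0, R_f0) seeds the lysis model.  An inhibited-tPA accumulator
is integrated alongside so that free + bound + inhibited tPA equals the
initial load to solver precision (a suite invariant).

Default molecular weights (overridable): fibrinogen 340 kDa, tPA 68 kDa,
Pg 92 kDa, PAI-1 43 kDa — literature standards.

## Fibrinolysis

Bound plasmin (per fibrin-phase volume) cleaves exposed fibrin:

    dL/dt = γ·k_Pn2·[Pn_b]·Θ_Pn/(K_PnM + Θ_Pn),   γ = 0.1,
    k_Pn2 = 25 s⁻¹,  K_PnM = 250 µM,

scaled by (1 − ε) to express L per whole volume.  Because fibers shrink
from the outside at constant internal density, geometry is algebraic in L:
R_f² = R_f0²·(1 − L/C_fr0) (so R_f = 0 exactly at complete lysis — the
anchor that pins the normalization of the printed radius law, whose raw
constant grouping is typographically ambiguous) and
ε = 1 − (1−ε₀)(R_f/R_f0)².  ε₀ comes from the fibrin volume fraction: one
monomer occupies 1/(p₀·λ_p) nm³ of fiber, with λ_p = 2/22.5 monomers/nm
(two half-staggered strands per 22.5 nm repeat), giving a within-fiber
fibrin concentration of ≈1.65 mM — constant during lysis, which is why
Θ during lysis is that constant times q times the exposed fraction.
Θ_Pn uses q_Pn = 1.0 sites per exposed monomer (the substrate site count
is not tabulated anywhere; it is a config knob).

Bound concentrations are per fibrin-phase volume (whole-volume values from
the formation stage are divided by 1 − ε₀ at the handoff).  The fluid
phase couples through s = (1−ε)/ε.  The conserved quantities are the mass
relations [i] + s·[i]_b = [i]₀, up to PAI-1 inhibition (tPA) and internal
Pg→Pn conversion.  Two consequences for the right-hand side:

* the fluid phase exchanges only the adsorption/desorption fluxes — the
  activation term converts bound Pg to bound plasmin *within* the bound
  phase and must not appear in the fluid equations, which a literal
  reading of the fluid-phase shorthand d[i]/dt = −s·d[i]_b/dt would imply;
* as the fibrin phase shrinks, the bound material on dissolved fibrin
  returns to the fluid (a −ds/dt·[i]_b source).  Free plasmin is inert:
  it accumulates from desorption and the release term and never rebinds
  (fluid-phase Pg activation is orders of magnitude slower than on the
  fiber and is omitted).

**Integration** is fixed-step explicit Euler on the Δt = 0.1 s grid used
by the schedule optimizer, with a conservative stepper: bound species and
L advance by their rates, fluid species are then updated from the discrete
mass relations.  This preserves [i] + s·[i]_b exactly at machine precision
for any Δt (a naive Euler step drifts O(Δt) through the moving s
coupling, ≈4e-5 relative at Δt = 0.1 s).  The binding rates are far from
the 1/Δt stability limit, and halving Δt changes the total lysis time by
<0.5% (a suite invariant).  Runs stop at exhaustion
(L ≥ (1 − 1e-6)·C_fr0, avoiding the ε → 1 singularity in s) or at t_max.

**Shell policies**: `surface` (κ = 0), `bulk` (κ = κ_max, recomputed from
the shrinking radius each step), a fixed integer (clamped to κ_max), an
arbitrary (time, κ) schedule, or a callable.  Cumulative lysis is
monotone nondecreasing in κ, so surface and bulk bracket every policy.

## Shell-schedule fitting

The optimizer mirrors the sequential procedure it implements: at each
Δt step, one trial step is taken for every candidate κ ∈ {0..κ_max} and
the κ whose predicted percent lysis at t+Δt is closest (squared error) to
the target is committed; ties break to the smallest κ (most conservative
depth), and the error search exploits unimodality in κ to stop early.
There is no lookahead beyond one step and no smoothing of κ(t).  The
target is an NT curve interpreted as percent lysis (NT tracks the fibrin
remaining in fibers), linearly interpolated onto the 0.1 s grid and offset
to 0 at lysis start.  Because κ is bounded by κ_max, the one-step error
cannot be made arbitrarily small and errors can accumulate; the
time-averaged squared error is reported alongside the schedule.

Aggregation over runs normalizes time within three regions — [0, SLT],
[SLT, TLT], [TLT, end of lysis] — into 10 bins each and reports the
median and quartiles of the shell fraction φ = κ_opt/κ_max per bin.

## Surrogate model

The surrogate replaces the per-step fitting with draws from two empirical
distributions of per-run mean φ (slow regime and fast regime), stored as
raw samples and drawn uniformly with replacement (no kernel smoothing —
the smallest assumption set).  The regime is decided by the normalized
radius: slow while R̃_f > 0.9, fast below; since R̃_f is nonincreasing the
switch happens at most once.  φ is redrawn every step by default (the
cadence is configurable; with point-mass distributions the cadence is
immaterial, a suite check).  κ = round(φ·κ_max), clamped.  SLT is the
time of the first crossing R̃_f ≤ 0.9 and FLT the additional time to
R̃_f ≤ 0.6; these thresholds match where the slow and fast regimes are
observed to end (R̃_f between 0.9–1.0 and 0.6–0.7 respectively).

A caution established while testing: whether the surrogate's FLT lands
between the surface-only and bulk-only values depends on the fast-regime
φ distribution.  If that distribution is concentrated at φ = 1 the
surrogate enters the fast phase later than the bulk model but with more
accumulated plasmin, and its FLT can undercut the bulk value by a
fraction of a percent.  With distributions from gradually deepening
fits — φ rising with radius loss, as the fitted schedules themselves
behave — the surrogate's SLT and FLT medians bracket cleanly between the
surface and bulk values (verified over 50 seeds in the suite).

## Parameter search and sensitivity

Grid screening runs clot formation (1000 s) for each candidate set at
fibrinogen 1–4 mg/mL and keeps sets whose simulated fiber diameter 2·R_f0
falls inside a measured acceptance window at every concentration and which
incorporate ≥80% of the fibrinogen into fibers.  The diameter window is a
required input: it comes from microscopy measurements, not from the model.
Rank scoring sorts sets per experiment by their maximal |simulated −
target| percent-lysis deviation up to the TLT (the maximum is the right
conservative statistic here: a lysis curve cannot recover toward the
target after overshooting, since that would require re-forming fibrin),
assigns ranks (ascending; ties get average ranks, which makes the score
invariant to experiment ordering; NaN errors rank last), and sums ranks
over experiments.  With S sets and E experiments the worst possible score
is S·E; normalized scores live in [1/S, 1].

Sobol sensitivity uses the Saltelli cross-sampling design on a scrambled
Sobol' sequence (scipy.stats.qmc): n·(2d+2) model runs give first-,
second- and total-order indices (Jansen/Saltelli estimators), with
bootstrap confidence half-widths.  Parameter ranges default to log-uniform
decades bracketing the best-ranked set, fully overridable.  Failed model
evaluations discard the whole cross-sample row (keeping estimator pairing)
and are counted.  The estimators are validated against the closed-form
indices of an additive function.

## Synthetic data

The phenomenological generator produces the statistical structure the
analysis assumes, with exact ground truth: a half-cosine clotting descent
reaching the minimum exactly at CFT; a linear slow ramp of the configured
slope, ending at NT = 0.1 by default (the level at which the slow regime
is observed to end — this is also why 1/slope is proportional to SLT
across a batch, a suite invariant); and a fast rise a·S((t−t_on)/T) with
the cubic smoothstep S(x) = 3x² − 2x³.  The smoothstep was chosen over a
logistic for three reasons: it is identically zero before onset, so its
tail cannot leak into the slow-regime fit window and bias the fitted
slope; it is a cubic, which the cubic Savitzky–Golay filter reproduces
exactly except near the two C¹ joins; and its onset can be placed so the
deviation from the extended slow-regime line crosses Δ = 0.005 exactly at
the configured SLT, with the maximal slope at the configured TLT.  This
makes the generator's ground truth *operationally* aligned with the
detectors: on noise-free curves the round-trip recovers CFT, SLT and TLT
within one 1-minute sample.

Noise is additive Gaussian on intensity, default sd 0.5% of the dynamic
range (the instrument's noise is not characterized; this is a choice), and
Δturbidity scales with the fibrinogen level in the condition presets.  One
master seed spawns independent per-channel streams.  What the generator
does *not* emulate: optical physics (wavelength or fiber-size dependent
scattering — intensity is an affine proxy for fibrin), drifting baselines,
bubbles/artifacts, or channel failures; passing round-trips therefore
validate the analysis logic, not robustness to instrument pathology.

The mechanistic generator composes the forward models (formation → lysis
under any shell policy) and maps fibrin-in-fibers affinely to intensity at
1-minute sampling.  By default the trace starts at the clotting minimum:
the kinetic model polymerizes in ~3 minutes (the clotting phase is then
held to its nominal 1000 s), which at 1-minute sampling is a near-step
that the smoothing filter cannot follow.  Its noise default is 0.2% of
range — on forward-model traces the long pre-lysis plateau makes the
0.01-crossing search sensitive to noise excursions of the normalized
minimum.  With the surface→bulk switch policy these traces reproduce the
two-regime signature: a linear slow segment (R² > 0.99 in the fit window)
followed by a convex fast segment, with the detected SLT falling at
R̃_f ≈ 0.9–1.0.

## Problem sizes used in the suite

Unit and property tests run on a reduced clot (C_fr0 = 2 µM, R_f0 = 50 nm,
prescribed bound plasmin 0.01 µM) whose complete lysis takes 1.5–3·10³ s
of simulated time — large enough to resolve both regimes and every
invariant, small enough that exhaustive policy comparisons and 50-seed
surrogate ensembles complete in seconds.  The control-condition clot
(full formation run) is used where the comparison is about that state
itself: the surface/bulk ordering, the surrogate bracketing, and the
bound-tPA fraction.  Sobol validation uses analytic test functions at
n = 1024 (the formation-model closure is provided for real analyses).

## Known limitations

* Fibers shrink homogeneously; transverse cutting/transection, spatial
  lysis fronts, diffusion and advection are out of scope, as are
  α2-antiplasmin and TAFI.
* The polymerization scheme ignores oligomer–oligomer ligation,
  fibrinopeptide-B kinetics and network branching; clot formation and
  lysis are decoupled (lysis starts when clotting ends).
* The bound-tPA fraction after clotting depends on the site-exposure
  normalization and on r₀, neither of which is pinned by published
  numbers; both are configurable and the defaults are documented above.
* The heterogeneous (core-dense) protofibril cross-section variant is not
  implemented; the cross-section is uniform at p₀.
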