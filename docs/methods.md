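# Methods

This note documents the models, the synthetic-data generator, the trace
pipeline and the numerical choices behind `ringmotor`. Units throughout:
forces in pN, distances in nm, contour lengths and steps in bp (0.34 nm/bp),
concentrations in μM, rates in 1/s (second-order rates in 1/(s·μM)),
energies in pN·nm or kBT.

## Thermal scale and energetics

`ThermalScale` carries k_B·T with k_B = 0.0138065 pN·nm/K. The package
default is kBT = 4.11 pN·nm (room temperature, ~297.7 K); every model
function accepts an explicit scale. Product-release free energies are
returned as the **magnitude released**: `ΔG = ln(K_d/[ligand])` in kBT,
positive when release is favorable. The free energy available per ATP
turnover is exposed as a configurable budget of 110 pN·nm; it is used only
as an audit (a simulated power stroke whose work F·d exceeds the budget
rejects the configuration with a warning), never computed from standard
free energies, because the buffer-dependent value is an input, not a
result.

## Force–velocity models

Three renewal-cycle families (see README for the formulas): single
force-sensitive transition, linear two-transition, and branched. Design
points:

* The single-transition velocity is implemented in denominator form
  `V = Vmax/[(1−p) + p·exp(FΔx‡/kBT)]`: the cycle time is the weighted sum
  of a force-free block `(1−p)/Vmax` and a Bell-factor block, which
  reproduces the required limits `V(0) = Vmax` and monotone decrease.
* The branched family fixes equal branch step sizes `d_A = d_B = d`; the
  unequal-step variant is weakly constrained by velocity data alone and is
  deliberately not implemented.
* The branched family is *not* monotone in force for every admissible
  parameter set: if the force-disfavored branch A is slower than branch B,
  shifting weight toward B raises the velocity. Monotonicity is guaranteed
  (and property-tested) when `k_A(F) ≥ k_B(F)` everywhere.

### Calibration of the default linear-model parameters

The distances ΔxL† = 1.3 nm and ΔxH† = 0.4 nm and the step size d = 2 bp
are fixed at the fitted values; the five rate-like parameters
(k0, kL0, β, kH0, α) are pinned by five deterministic anchor conditions:

| anchor | value |
|---|---|
| V(0 pN, saturating ATP) | 6500 bp/s |
| V(5 pN, 3 mM ATP) | 4000 bp/s |
| K_M(5 pN) | 500 μM |
| V(30 pN, saturating) | 3200 bp/s |
| V(50 pN, saturating) | 2000 bp/s |

The first three are the motor's reported operating points; K_M(5 pN) is a
free choice consistent with the 0.25–5 mM titration range since no K_M is
printed. The last two are this package's own shape anchors, chosen so the
curve shows the observed bi-phasic form: a plateau in the 15–40 pN window
and a clear high-force drop-off. Calibration is a `scipy.optimize.root`
solve in log-parameter space with a fixed starting point — deterministic,
no randomness. Resulting defaults: k0 ≈ 4323/s, α ≈ 4.667/(s·μM),
kL0 ≈ 3018/s, β ≈ 3.54, kH0 ≈ 2.97×10⁵/s.

## Synthetic-data generator

### Subunit cycle

A continuous-time Markov chain per hexamer cycle (renewal abstraction —
one effective subunit at a time, which reproduces every trace-level
observable; a spatially resolved six-subunit simulation is out of scope):

    apo → (ATP docking, α·[ATP]) → docked → (tight binding, k2) →
    tight → (k_L(F)) → (k0_rest) → (power stroke, k_H(F)) → +2 bp → apo

with `1/k2 + 1/k0_rest = 1/k0` so the mean cycle time equals the linear
model's exactly. The force-sensitive non-stroke block k_L is attached after
tight binding and before the stroke, consistent with a deformation-like
transition distinct from phosphate release; the assignment is a lumped-rate
choice and does not affect trace statistics. ATP undocking (`k_unbind`) is
available but defaults to 0 (docking commits, hydrolysis reversibility is
collapsed into the lumped block for efficiency).

Off-pathway features:

* **ADP occupancy.** From apo the subunit can bind ADP
  (`adp_binding·[ADP]`) and must release it (`adp_binding·K_d`, K_d fixed
  at 129 μM) before ATP can dock. First-step analysis gives a mean waiting
  time `(1+[ADP]/K_d)/(α[ATP])` — exact competitive inhibition.
* **Pausing.** From apo, pause entry at `pause_entry` (default 0; 7/s in
  pausing studies, chosen to give a few pauses per kbp at 250 μM ATP);
  exit at `pause_exit_rate·[ATP]` with `pause_exit_rate = 0.012/(s·μM)`,
  i.e. a 1/3 s mean pause at 250 μM. Pause durations are exponential and
  force-independent by construction, matching the observed kinetics.
* **Slipping.** Active only in the single-grip window (apo/ADP-bound,
  before the next subunit engages): hazard
  `slip_hazard0·exp(F·slip_dx/kBT)` with defaults slip_hazard0 = 0.4/s
  (0 unless enabled), slip_dx = 0.3 nm, released contour exponential with
  mean 500 bp. No quantitative slip rates are reported for the motor, so
  these defaults are chosen to reproduce the qualitative orderings only:
  density increasing with force, much more steeply at low [ATP] (time spent
  in the vulnerable window scales as 1/[ATP]). In the paused state the
  motor grips DNA with two subunits, so the hazard is suppressed there (and
  in nucleotide-bound states) by the multiplicative factor
  `slip_suppression`, default 0.

### Tether and trap

Marko–Siggia worm-like chain, persistence length 50 nm, optional stretch
modulus (solved self-consistently when finite). Passive mode balances WLC
tension against a Hookean trap (stiffness 0.1 pN/nm, starting force 3 pN):
the bead position solves `F_wlc(x; L) = κ(c−x)` by Brent's method at every
contour change, so force rises as the motor reels in DNA and drops at
slips. Constant-force mode pins the force at the setpoint and moves the
extension along the WLC isotension curve. Instrument constants (2500 Hz
sampling, 2 nm Gaussian noise on extension only, trap stiffness,
persistence length) are not reported for the instrument modeled and are
set to typical dual-trap/micropipette values; all are configurable. Force
is frozen within each Gillespie dwell and re-solved at each event —
adequate because a 2-bp step changes the force by ≪ 0.01 pN.

What the generator does *not* emulate: bead/fluid hydrodynamics and the
correlated (Ornstein–Uhlenbeck) component of bead noise, instrument drift,
multiple motors per tether, and sequence dependence. Passing recovery tests
therefore demonstrate correctness of the pipeline and estimators under
white measurement noise, not robustness to every instrumental artifact.

### Reproducibility

One root seed; per-trace generators are spawned from a
`numpy.random.SeedSequence`, making corpora byte-identical under a fixed
seed and independent across traces.

## Trace pipeline

* **Contour conversion** inverts Marko–Siggia per sample via a vectorized
  Newton solve of the relative extension (≤ 1e-12 in z), then `L = x/z`.
  Samples with F ≤ 0 are flagged NaN and excluded.
* **Pause detection** is a best-first binary segmentation of the contour
  series into straight-line segments. Interval costs use O(1) cumulative
  sums; candidate splits are accepted largest-gain-first while they lower a
  Schwarz-type criterion `n·ln(RSS/n) + (k+1)·ln(n)` (Gaussian residual
  likelihood, ln n penalty per changepoint); the search stops at the first
  rejected best candidate. Minimum segment length 8 samples. Segments are
  classified against a reference translocation speed taken as the 0.9
  duration-weighted quantile of segment speeds (robust even when pauses
  occupy most of the trace): segments slower than 10 % of the reference
  are pause-like, runs of segments slower than 50 % are merged and the
  merged run's overall slope decides, with a strict per-segment fallback.
  A merged run is a pause if it lasts at least the detection threshold:
  50 ms at [ATP] ≤ 0.5 mM, 30 ms above.
* **Pause-free velocity** excises detected pauses, stitches the remaining
  time axis (so pause time does not dilute the slope) and fits contour vs
  time by least squares within half-open 2-pN force windows; cells with
  fewer than 10 samples are skipped with a warning.
* **Missed-pause correction** uses the censored-exponential MLE: for
  durations observed only above threshold t₀, `τ̂ = mean(observed) − t₀`
  (memorylessness), detected fraction `exp(−t₀/τ̂)`, corrected count =
  observed / detected fraction. This is the exact maximizer of the
  truncated-exponential likelihood (property-tested against a numerical
  grid search). Pause density is reported per kbp of pause-free
  translocation (per unit time is the plausible alternative; the per-kbp
  convention matches density-vs-velocity plots).
* **Slip detection** flags contour increases ≥ 50 bp within ≤ 20 ms,
  measuring the release from the last pre-jump sample; densities are
  events per kbp translocated with √N counting errors.
* **Consolidation** pools per-window velocities across near-saturating
  [ATP] cells and re-bins them into the twelve canonical force intervals
  (2–4, 4–6, 6–8, 8–10, 10–13, 13–16, 16–20, 20–25, 25–30, 30–40, 40–45,
  45–50 pN).

## Fitting

Weighted least squares (weights 1/SEM²; the original analysis does not
state its weighting, a documented divergence risk) via lmfit. Standard
errors come from the Jacobian covariance at the optimum. The linear and
branched families use deterministic multi-start over log-spaced rate grids;
best chi² wins, ties broken by the smaller parameter norm. Model comparison
ranks fits of identical data by `chi² + 2k`.

When a force–velocity dataset contains only near-saturating [ATP], the ATP
on-rate α and the lumped rate k0 enter the cycle time as two additive
constants and cannot be separated; such fits pin α (and d = 2 bp, as in
the original analysis) and leave k0, kL0, β, ΔxL†, kH0, ΔxH† free.

## Recovery experiments (acceptance surface)

Because the raw experimental traces are not deposited, the quantitative
targets are parameter-recovery experiments seeded by the published fit
values, at 5 % multiplicative Gaussian noise per velocity measurement and
20 seeded replicates (means reported):

* **K_i**: ATP titrations (0.25–5 mM, 7 levels) at [ADP] ∈ {0, 100, 300,
  500} μM generated from K_i = 129 μM with the calibrated V_max and
  K_M = 500 μM at 5 pN; global shared-parameter refit.
* **ΔxH†, ΔxL†**: per-window velocities at 2, 3 and 5 mM over the twelve
  canonical bins, five pooled measurements per (bin, [ATP]) cell —
  mirroring the pooled-then-binned consolidated curve, whose per-bin SEMs
  reflect many 2-pN windows — consolidated and refit with d and α pinned.
  A single 12-point curve at 5 % noise leaves ΔxL† weakly identified (the
  β–ΔxL ridge is nearly flat and the per-replicate MLE is skewed high);
  the consolidated design restores identifiability without changing the
  per-measurement noise level.
* **Vmax**: single-transition data over 3–49 pN (2-pN spacing) from
  (Vmax = 4.2 kbp/s, p = 1, Δx‡ = 0.07 nm), refit with all three
  parameters free.

Problem sizes were chosen so the full test suite runs in well under a
minute and the acceptance script in seconds on one CPU.

## Known limitations

* The changepoint detector resolves pauses down to roughly its minimum
  segment length (≈ 3 ms at 2500 Hz) but the *reliable* regime is the
  stated 30/50 ms thresholds; shorter pauses are handled statistically by
  the censored-exponential correction, which assumes a single-exponential
  duration distribution.
* The renewal-cycle simulator cannot express inter-subunit heterogeneity
  (e.g. a damaged subunit) or coordinated multi-subunit pauses.
* Slip parameters are qualitative: only orderings across force and [ATP],
  not absolute slip densities, should be compared to measurements.
* Passive-mode force windows use the instantaneous force per sample;
  windows are half-open [lo, hi).
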