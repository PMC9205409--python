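# Methods

## Model and assumptions

The package models MMI treatment of Graves' disease with two coupled
first-order ODEs: intrathyroidal MMI mass `x1` (mg) relaxes toward the
daily dose `u` at rate `kd`, and FT4 `x2` (pmol/L) balances two saturating
Michaelis–Menten synthesis terms against first-order degradation `kf`.
TRAb (`d1`) stimulates synthesis directly and competitively blunts the
TSH-driven term; intrathyroidal MMI scales both half-saturation constants
through `1 + x1/km`. All quantities are concentrations/masses, so the
admissible region is the non-negative orthant, which the dynamics leave
invariant: every synthesis term is bounded (by `ka1 + kT1`) and the only
outflows are proportional to the states themselves, giving the a-priori
bound `x2 ≤ max(x2(0), (ka1+kT1)/kf)`.

Time is continuous in days. The daily dose is treated as a constant
infusion over its prescription interval (no intra-day tablet kinetics);
doses change only at appointments, so the input is piecewise constant and
the integrator restarts at every dose switch. TRAb/TSH measurements are
interpolated linearly between appointments and held constant outside the
measured window. Stimulating and blocking antibodies are not
distinguished; `d1` acts as a single stimulating input. FT3, circadian
effects and thyroid volume are outside scope (volume effects are absorbed
by the patient-specific constants).

Initial conditions for record simulations follow a steady-state
convention: `x2(0)` is the first measured FT4; `x1(0)` equals the first
prescribed dose for patients already on MMI at entry (pre-entry
equilibrium of the first equation) and 0 for treatment-naive patients.
The caller states which case applies (`treatment_naive` flag); the
on-treatment convention is the default.

## Numerics

Integration uses the adaptive stiff-capable `lsoda` code (via
`scipy.integrate.odeint`; any `solve_ivp` method can be selected instead).
Default tolerances are rtol 1e-8 / atol 1e-10; the fitting loop relaxes
them to 1e-6 / 1e-8 for speed. Dose discontinuities are exact restart
points. Round-off excursions below zero (bounded by ~1e3·atol) are
clamped to 0; anything larger aborts with an error. The closed-form
steady state (`x1* = u`, `x2*` = synthesis/degradation at `x1 = u`) serves
as an independent oracle for the integrator and as the workhorse of
feasibility screening.

## Parameter identification

Eight parameters from one appointment series is a practically
non-identifiable problem (`ka2`, `kT2`, `kT3` trade off against each
other), so the contract is *trajectory* recovery, not parameter-wise
equality. The objective is the unweighted sum of squared FT4 residuals at
appointment days. Parameters are optimised on log scale (they span up to
three decades; the log box is roughly isotropic). Multi-start: 32
Latin-hypercube points in the log box are screened with one objective
evaluation each; the best 5 are polished with bound-constrained
trust-region least squares on a tight iteration budget, stopping early if
a candidate reaches numerically-zero SSR (< 1e-6 (pmol/L)²); the winner
gets one deep refinement with a generous budget. A candidate whose
untreated steady-state FT4 at the record's highest TRAb exceeds 150
pmol/L is rejected as physiologically implausible (admissible parameters
must not allow runaway FT4); fits with fewer than 8 FT4 points are
returned but flagged unconverged. Everything is deterministic given
(record, seed).

## Virtual cohort

The generator emulates the study conditions under which automated
titration is evaluated: treatment-naive, overtly hyperthyroid GD patients
followed at (by default) 28-day appointments over 420 days.

TRAb archetypes are drawn with probabilities 0.10 / 0.76 / 0.14
(persistent / disappearing / complex), matching their reported occurrence
in real disease courses. Disappearing: `A·exp(−t/τ)` with τ capped so the
course falls below the 15 U/L assay upper normal before the horizon.
Persistent: `A(1 + ε sin(2πt/T + φ))` with ε ∈ [0.02, 0.10] — a small
bounded fluctuation; larger swings proved untrackable at monthly sampling
and are not what "persistent" denotes clinically. Complex: the
disappearing shape plus a Gaussian rebound flare (centre 30–70% of the
horizon, width 20–60 d, height 0.3–0.8·A); the functional form is this
package's construction. Amplitudes are log-uniform in [20, 400] U/L,
bracketing the dispersion of baseline TRAb in overt disease (typical mean
near 110 U/L with a similar-sized SD).

Parameters are rejection-sampled log-uniformly from the admissible box
and accepted only if the implied patient is clinically coherent at every
stage of the disease, judged by closed-form steady states:

1. *presenting*: untreated FT4 at peak TRAb (TSH suppressed) in
   [25, 120] pmol/L — overtly hyperthyroid but bounded;
2. *controllable*: FT4 at the 40 mg/day maximum and peak TRAb in
   [9.5, 16.75] pmol/L — the admissible dose range can reach the target
   but cannot push the steady state below the interval;
3. *recovered*: with TRAb gone, no MMI and mid-normal TSH (1.5 µU/mL),
   FT4 in [13, 23] pmol/L — remission means euthyroidism, not permanent
   hypothyroidism;
4. *no hypothyroid valley*: untreated FT4 stays ≥ 9.5 pmol/L at residual
   TRAb 2.5–15 U/L (in the model, low TRAb can block TSH-driven synthesis
   more than it adds; a patient whose recovery passes through必然 passes through
   an untreatable hypothyroid phase is not a meaningful titration
   subject);
5. *dose-grid compatible*: one 1.25 mg quantum above the euthyroid dose
   keeps steady-state FT4 ≥ 9.5, checked at TRAb 0 and 15 U/L — the FT4
   levels reachable on the clinical dose ladder are dense enough to land
   inside the target interval.

TSH is animated by a first-order lag toward a graded equilibrium
`1.5/(1 + exp((FT4 − 23)/1.5))` µU/mL (recovery time constant 60 d,
suppression 5 d). A hard on/off threshold was tried first and produced a
relay-feedback oscillation in closed loop; the graded form is also closer
to the continuous pituitary response. The dosing controller never reads
TSH.

What the generator does **not** emulate: real registry data with missing
values and irregular visits, assay noise (optional multiplicative noise,
CV 5%, default off for reproducibility), blocking antibodies, demographic
covariates, or spontaneous parameter drift. Passing tests therefore show
that the pipeline is correct and the controller robust across the modelled
phenotype spread — not that it is validated on real patients.

## Controller

Discrete-time PI on the FT4 tracking error `e = FT4 − r`, `r = 16.75`
pmol/L, handling arbitrary appointment intervals by weighting the integral
with elapsed days. The first visit is dosed from the guideline band map
(FT4/ULN < 1 → 0 mg; <1.5 → 10; <2 → 20; <3 → 30; else 40 — upper band
ends, since the cohort presents overtly hyperthyroid); the PI law starts
at visit 2. Constraints, in order: rate limit, saturation to [0, 40],
quantisation to the 1.25 mg grid with half-grid ties rounded to the lower
dose (safety).

The rate-limit map concretises "change doses gently, but act faster the
further out of range the patient is": |Δu| ≤ 20 mg when FT4 > 2·B_u,
≤ 10 mg when FT4 > B_u, ≤ 15 mg *decrease* when FT4 < B_l (rapid
withdrawal from an over-treated patient), ≤ 5 mg otherwise — and dose
*increases* while FT4 is already inside [B_l, B_u] are capped at one
quantum, because raising the dose of an in-range patient is never urgent
and protects quantum-sensitive patients from overshoot.

Anti-windup is back-calculation: after the constraints are applied the
integral is nudged toward consistency with the dose actually prescribed
(tracking constant 56 d ≈ two visits). Conditional integration was
implemented first and rejected: it freezes a stale positive integral
while the dose saturates at 0 during a hypothyroid dip, and that stale
integral re-doses the patient the moment FT4 recovers, producing a
sustained limit cycle.

Gains were tuned on the mid-box nominal patient and stress-tested across
seeded cohorts for absence of sustained oscillation: Kp = 0.4 mg per
pmol/L, Ki = 0.015 mg per (pmol/L·day). Larger proportional gains exceed
unit loop gain for high-sensitivity patients at 28-day sampling and
oscillate. With the defaults, at least 38/41 patients of every cohort
seed tried converge into [9.5, 24] pmol/L at all visits after day 200.

## Evaluation

The cost `J` is the per-visit mean of a tracking term `α1(x2−r)²`, a dose
term `α2 u²` and one-sided range penalties `β1 h1 + β2 h2` with
`h1 = (max(m, x2) − x2)²`, `h2 = (min(M, x2) − x2)²`, m = 14.5, M = 19
pmol/L. `u(Ti)` is the dose prescribed *at* visit `Ti` (applied over the
following interval). Presets: tracking (α = (1,0), β = 0), dosing and
tracking (α = (1, 0.05)), target range (β = (1,1)). Policy comparison on
matched cohorts uses paired differences; Shapiro–Wilk at 0.05 selects the
paired t-test (normal) or the Wilcoxon signed-rank test, two-sided, with
significance at p < 0.05. A constant non-zero shift is degenerate for the
normality check and goes to the rank test directly.

## Problem sizes

The test suite fits 20 noiseless and 20 noisy synthetic patients (12
monthly visits each), runs closed loops over 41- and 100-patient cohorts
at 28-day spacing over 420 days, and samples 10,000 TRAb courses for the
archetype statistics; these sizes keep the whole suite comfortably
desk-scale while leaving the statistics well outside their acceptance
margins.

## Known limitations

* The model cannot represent hyperthyroidism that persists at zero TRAb,
  nor T3-toxicosis; the controller is MMI-only (no propylthiouracil,
  no block-and-replace).
* Parameter non-identifiability means fitted constants are not
  biologically interpretable individually; only FT4 predictions are.
* The TSH generator and the complex-TRAb shape are package constructions;
  conclusions that depend on their details should be re-checked against
  data.
* Controller gains are tuned for 28-day nominal spacing; the law handles
  varying intervals, but radically different schedules may warrant
  retuning.
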