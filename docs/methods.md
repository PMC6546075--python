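# Methods

## Model structure and assumptions

The simulator tracks volumes of cell cohorts, not individual cells and not
intracellular state. Three coupled pieces:

1. **Cyclic transit chain.** N equal-duration compartments represent cell-cycle
   position. Transit constants k₁ = (N + ln 2)/t_d and k₂ = N/t_d make the
   uniform state the dominant eigenmode with growth rate a = ln 2/t_d, so the
   drug-free total volume is exactly exponential and doubles every t_d. The
   initial condition is uniform (equal volume per compartment), consistent with
   cells growing at a constant rate through the cycle.
2. **Drug channels.** Per drug: damage moves volume from a proliferating
   compartment to a matching arrested damaged pool at rate
   damage_coef·C(t); repair returns it at first-order rate k_r; apoptosis
   removes proliferating volume irreversibly into a cumulative sink A at
   apoptosis_coef·C(t). Only proliferating cells in the drug's phase of action
   are exposed; damaged cells neither transit nor grow nor (in this model) die.
   Mass is conserved up to growth: d/dt(ΣV + ΣD + A) = a·ΣV.
3. **Proliferating rim.** Tumour size obeys size(t) = size₀ + d·ln V_layer(t)
   with V_layer = ΣV + ΣD; without drug this is the linear law
   size₀ + a·d·t. The law presumes an established non-growing core
   (d < R₀).

### Design choices where the design was open

* **Repair is first-order in damaged volume** (k_r·Dₙ, pool n back to
  compartment n), not a constant flux. A constant repair flux is dimensionally
  inconsistent with the other terms and drives Dₙ negative once damage is
  exhausted; the first-order form is the standard reading of
  "damaged and possibly repaired" and keeps the state nonnegative.
* **Damaged pools are per drug**, so each drug's repair rate applies to its own
  damage — unambiguous when two drugs with different repair rates act on
  different phases, as in all three case studies.
* **Concentration coupling is linear** (k_d = damage_coef·C, likewise
  apoptosis); repair is concentration-independent and so continues after the
  drug clears.
* **Apoptosis acts on proliferating cells only.** Damaged cells must first be
  repaired before they can be killed.
* **Damaged volume counts toward the growing layer** (arrested cells still
  occupy space); apoptotic volume does not.
* **Loss attribution.** The drug-attributable loss (maximum drug-free gain
  minus realised gain) is split into a death fraction A(T)/(A(T)+ΣD(T)) and its
  damage complement, i.e. by the relative sizes of the terminal pools. This is
  the simplest auditable rule; other attributions (e.g. path-integrated) would
  differ for schedules where damage is repaired late.
* **Diameter-loss convention.** The rim derivation is written for the radius,
  but the combination-study tables this package reproduces report their
  headline "diameter loss" in the rim-law size coordinate itself — numerically
  the radius loss as computed here. `diameter_loss(summary, convention=...)`
  exposes both: `"table"` (default; matches the published schedule tables and
  gives a plausible three-week control growth, e.g. 6.32 → 11.7 mm for the
  t_d = 30 h parameterisation) and `"geometric"` (twice the radius loss, the
  literal spherical reading). All other outputs are convention-free.

### Phase allocation

Compartment counts per phase are fraction·N rounded by largest remainder, ties
broken in cycle order G1, S, G2, M; the blocks are contiguous with mitosis
last. A phase whose count would be zero raises with advice to increase N —
silently promoting it would misrepresent the requested fractions by a whole
compartment.

## Pharmacokinetics

Concentrations are closed-form, evaluated analytically and superposed over
doses — never integrated as ODE states — so dosing discontinuities cost
nothing in solver accuracy:

* bolus decay (K-PD): C = Σᵢ dose·e^{−k_e(t−tᵢ)}, dose appearing instantly;
* step/infusion: fixed levels on declared intervals;
* one-compartment: Bateman form dose·k_a/(k_a−k_e)·(e^{−k_e τ}−e^{−k_a τ})
  with unit bioavailability and the analytic k_a → k_e limit
  dose·k_e·τ·e^{−k_e τ}.

Dose amounts are already in free-concentration units (dose/V); mg/kg doses in
source experiments are absorbed into the per-drug coefficients. "Day k" in a
schedule pattern means t = (k−1)·24 h; within a day doses are spaced
24/doses-per-day hours (twice daily = 12 h).

### Case-study schedule readings

Two schedule phrases in the sources are ambiguous and are encoded as follows
(alternatives noted):

* Gemcitabine "once every 3rd [day] of a 7-day cycle": one dose on day 3 of
  each weekly cycle (t = 48, 216, 384 h). Alternative reading — two doses on
  days 1 and 4 of each week — doses the combined arm three times as often as
  the sequenced arm and contradicts the source study's observed near-equivalence
  of the two schedules, so it was not adopted.
* Sequenced arm, gemcitabine "every 3rd day of a 4-day cycle" after a 12-day
  CDK4/6i course: day 3 of each 4-day cycle starting day 13, i.e. days 15 and
  19 (t = 336, 432 h).
* MEKi-first / docetaxel-first arms (case 3): the second drug starts 24 h
  after the first drug's last (or only) dose.

## Numerical integration

Explicit Runge–Kutta (scipy `RK45`), rtol 1e-8, atol 1e-10, max step 1 h;
the system is linear, mildly scaled (rates up to ~k_d·C ≈ 10/h in case 2),
and non-stiff at these sizes. Integration restarts at every dose time so the
concentration is smooth within each solver segment; tests verify that a run
across a dose equals two chained runs to 1e-9 and that halving tolerances
moves the final volume by < 1e-6 relative. Output is reported on a 0.5 h grid
by default (0.1 h for perturbation runs, resolving the ≈ 3.4 h pulse width).
Negative volumes beyond ~1e3·atol abort with a diagnostic; zero-coefficient
drugs are exactly inert.

## Dispersion measurement

The doubling-time spread is measured by placing a perturbation of size N/t_d
in compartment 1 (the same volume change for any N), integrating the drug-free
linear system for 2t_d, and fitting an unconstrained Gaussian
A·exp(−(t−μ)²/2σ²) to V₁(t) over the window [0.5t_d, 1.5t_d] by nonlinear
least squares with moment-based initialisation. The growth factor over the
cycle skews the pulse slightly; the free amplitude lets that skew land in the
residuals. For N = 50, t_d = 24 h the fit gives σ ≈ 3.40 h (closed form
t_d/√N = 3.39 h); the closed forms σ = 1/√N and peak (1/t_d)√(2N/π) are
reproduced by simulation within 5% for N ∈ {25, 50, 100}.

## Control-curve fitting and synthetic overlays

`fit_control` inverts the drug-free law by OLS of radius (= diameter/2) on
time: R₀ from the intercept, layer thickness d from slope/a. It assumes the
overlay really is a control (no treatment effect) and linear growth over the
fitted range. `synthesize_control` generates overlay fixtures from the same
law plus i.i.d. Gaussian diameter noise (default exercises use 0.1 mm at 8
weekly points); it is a synthetic stand-in for an observed control arm, so
round-trip tests demonstrate self-consistency of the fitting path, not
agreement with any animal data.

## What the packaged studies do and do not show

The case-study fixtures carry published parameterisations and dosing arms and
reproduce the source tables' diameter losses (case 1) and qualitative
sequencing findings (cases 2–3: near-equivalent gemcitabine schedules;
modestly different, better-than-monotherapy docetaxel sequences). They are
simulations of calibrated models, not re-fits to animal data: the underlying
experiments' mean growth curves (digitised, with drop-outs at late times) are
not shipped, and no quantitative fit to them is claimed.

## Known limitations

* No checkpoints, cell-size structure, quiescence entry/exit, or resistance;
  growth never saturates, so very long horizons grow unrealistically.
* Damaged cells cannot die without first being repaired; drugs whose damaged
  cells apoptose directly need their apoptosis coefficient to absorb that path.
* Single-compartment PK only; no protein binding or nonlinear clearance.
* The rim law needs d < R₀ and breaks down for shrinkage so severe that the
  layer volume approaches zero (the radius map diverges logarithmically).
* Problem sizes used throughout (N ≤ 100, horizons ≤ 504 h) integrate in
  under a second per arm; the defaults are the study conditions, not solver
  limits.
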