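# Methods

## Model

Two clonal populations — sensitive (*G*) and resistant (*R*) cell numbers —
share one logistic carrying capacity:

```
dG/dt = k_G G (1 − (G+R)/N) + I_G(G,R) − D_G(t)
dR/dt = k_R R (1 − (G+R)/N) + I_R(G,R) − D_R(t)
```

Interaction terms `I` come in two variants.  The **unweighted** form is the
Lotka–Volterra product `C_GR·G·R` (and `C_RG·R·G`), with `C` in
cell⁻¹ day⁻¹.  The **weighted** form, `C·R·G^m/(G+R)^m`, multiplies the
resistant count by the sensitive *share* raised to a cooperativity exponent
*m* ≥ 0; it is degree-1 homogeneous in cell number, so there `C` carries
units day⁻¹.  The constants are stored exactly as configured per variant —
no silent rescaling between the two unit conventions.  At an empty culture
the weighted term's 0/0 is defined as 0 (no cells, no interaction).  At
fixed total the weighted term is proportional to `r(1−r)^m` in the
resistant fraction `r`, maximized at `r = 1/(1+m)` — the exponent selects
the mixture at which cooperation is strongest.

Therapy removes cells at a rate proportional to a normalized concentration
`f(t)`.  Two kill-term orders are implemented:

* `zero_order` (default): `−a·f(t)`, removal independent of population
  size.  This is the form the model family is written in, but with the
  potency normalization `a_G = 1`, `a_R = 1/4` it removes at most one cell
  per day against 10⁵-cell cultures, so it cannot move the dynamics at
  that scale; it is kept as the faithful default for the printed system,
  with states clamped at zero so extinction is absorbing.
* `first_order`: `−a·f(t)·X`, a per-cell kill rate.  The therapy and
  clinical experiment suites use this form; it is the one that produces
  the concentration-dependent steady-state structure the model family is
  used to study, and the normalization `a_G = 1` then reads "one unit of
  concentration kills sensitive cells as fast as they divide".

### Assumptions

Well-mixed cultures (no spatial structure, despite the observed clumping
of real cocultures); interaction strength depending only on instantaneous
counts; therapy acting by direct cell death only (no effector-cell
compartment, no receptor-binding kinetics); no mutation between clones.
Cell counts are continuous; a clone below one cell is treated as extinct
where an absorbing floor is enabled (sweeps and clinical runs), because
sub-cell fractions would otherwise "regrow" after therapy wanes.

## Numerics

Integration uses SciPy's LSODA (adaptive, stiffness-switching) with
rtol = 1e-8 and atol = 1e-2 cells.  These settings reproduce the
closed-form single-clone logistic to six digits, and halving them moves
day-10 states by far less than 0.01%.  States are clamped nonnegative
before derivative evaluation; a clamped coordinate with a negative
derivative reports zero.  A clone seeded at zero is pinned at zero (the
axes are invariant).  Dose administrations are breakpoints: integration
restarts at each dose day so the discontinuous concentration jump is never
smoothed over.  Non-finite states (runaway mutualism — large constants do
drive the system to infinity) raise a `SimulationBlowUp` carrying the
offending time.

Steady-state detection integrates in 25-day chunks until both per-capita
rates satisfy `|dX/dt|/max(X,1) < 1e-6 day⁻¹` — scale-free, so equally
strict for 10⁵-cell cultures and 10¹²-cell tumors.

Concentration sweeps classify the terminal pattern of the sensitive clone
across the grid: **abrupt** if its terminal share drops from above 5% of
the terminal total to extinction between adjacent grid points, **gradual**
if it declines below that share before extinguishing, **none** if it never
extinguishes.  The 5% materiality cutoff and the one-cell extinction floor
are configurable; they operationalize the visual distinction between the
two steady-state regimes seen in phase portraits.

## Rate inference

Each clone's daily counts over days 0–5 are fitted with the standard
three-parameter logistic `y(t) = N_fit/(1 + b·e^{−kt})` (so
`y(0) = N_fit/(1+b)`), by trust-region least squares with deterministic,
data-driven starts: `k₀` from a log-linear regression of the early counts,
`N₀ = 1.05·max(count)`, `b₀` matching the day-0 count.  A constant series
is rejected as unidentifiable; a clone seeded at zero contributes no rate.
The fit is scale-equivariant: scaling counts scales `N_fit` and leaves
`k`, `b` unchanged.

A notable artifact of shared-capacity crowding: in a 1:1 mixture the
*non-interacting* model already yields a fitted resistant rate (≈0.69
day⁻¹) well above the pure-culture value (0.4695 day⁻¹), because the
faster sensitive clone saturates the capacity early and the fit reads the
early flattening as a higher rate with a smaller fitted capacity.
Mixture-rate changes therefore cannot be read as interaction strength
without simulating the null model.

## Calibration

`calibrate_interactions` scores every constant pair on a grid by the
product of the per-clone Pearson correlations between the simulated and
observed rate profiles, subject to both correlations being positive, with
ties broken toward the smallest `|C_GR| + |C_RG|`.  Absent entries (pure
cultures) are dropped pairwise; fewer than three pairs per clone is an
error.  On noiseless on-grid data the truth is recovered exactly.

Pearson correlation is affine-invariant, so the objective sees only the
profile *shape*; the level information that pins down the constants'
magnitude is discarded, and the resulting surface is a ridge.  Under 5%
multiplicative rate noise the argmax wanders of order ±0.2 day⁻¹ along
that ridge — an intrinsic identifiability limit of the correlation-product
objective, documented here because it bounds what any grid resolution can
deliver.  `analysis/04` writes the full surface so the ridge is visible.

Because the available observed profile consists of only four printed
anchor rates (two per clone — fewer than the three pairs Pearson
correlation needs), the experiment suites instead default to
**anchor-rate calibration**: bounded nonnegative least squares choosing
`(C_GR, C_RG)` so the simulated 1:1-mixture fitted rates match the anchor
maxima (1.191 and 0.6045 day⁻¹) as closely as possible, with pure-culture
rates fixed at 1.069 and 0.4695 day⁻¹ and capacity 600,000 cells.  The
anchor pair is not exactly attainable (the crowding artifact above floors
the attainable resistant rate near 0.62 day⁻¹ once the sensitive anchor is
matched), so residuals are at the few-percent level; the solver is
deterministic (fixed start, bounds [0, 5] day⁻¹).

## Pharmacokinetics and clinical scaling

Dosing is one-compartment IV bolus kinetics: each dose decays as
`e^{−k_e t}` with `k_e = ln 2 / 28.4 d ≈ 0.02441 day⁻¹`, doses superpose,
and concentration is normalized so 1.0 is the peak of a single 1000 mg
dose (3.76 µmol/L, kept as metadata only).  The clinical schedule is unit
doses on days 0, 7, 14 and then at each 21-day cycle start through day 147
(treatment ends at day 168); sweeps scale the whole schedule by a
multiplier.

`scale_to_clinical` maps culture constants to tumor scale by preserving
the nondimensionalized dynamics (populations in units of *N*, time in
units of 1/k_G): with `s = k_G_clin/k_G_vitro`, day⁻¹ constants multiply
by `s` and cell⁻¹ day⁻¹ constants by `s·N_vitro/N_clin`.  Clinical
defaults: sensitive growth from the 29-day (0.0239 day⁻¹) or 14-day
(0.0495 day⁻¹) doubling time, capacity 2⁴⁰ ≈ 1.1×10¹² cells, 10⁹ cells at
diagnosis split 9:1.  A helper (`logistic_rate_between`) derives a rate
from two tumor sizes, but it requires an explicit duration — two sizes
alone do not determine a rate.  Therapy potencies are deliberately *not*
rescaled: they are per unit of the dimensionless concentration axis, and
rescaling them by `s` would render the clinical concentration sweeps inert
over their working range.

## Synthetic cultures

The generator emulates the fluorescence coculture design: 100,000 cells
seeded at resistant fractions {0, 0.25, 0.5, 0.75, 1}, counted daily
through day 5, three replicates, with independent multiplicative lognormal
noise per count (mean-one, CV 5% by default — imaging-cytometry error is
roughly proportional to the count) and rounding to whole cells; a clone
seeded at zero stays zero.  The default ground truth is the
anchor-calibrated weighted model at *m* = 2.  Deterministic given the
design seed; replicates differ only in noise draws.

Not emulated: cell clumping, the mid-culture media additions (which may
perturb the effective capacity), fluorescence intensity, transduction
efficiency and sorting purity.  Passing end-to-end tests therefore shows
the inference machinery is sound under proportional measurement noise, not
that real cocultures obey the model.

## Problem sizes

The test suite and scripts run the five-day culture simulations at daily
sampling, taxonomy steady states to at most 1000 days, therapy sweeps on a
0.05-step concentration grid to day 1000, clinical sweeps on 16-point
grids to day 1500, and calibration grids of 21×21 (Monte-Carlo noise
study) or 11×11 (exact-recovery checks and the analysis driver) — sizes at
which every study completes in seconds to a couple of minutes on one CPU.

## Known limitations

* The correlation-product calibration is shape-only (see above); its
  noisy-data precision is bounded by the ridge degeneracy, not by grid
  resolution.
* The zero-order kill term is dimensionally faithful to the written system
  but inert at culture scale under the standard potency normalization.
* Sweep thresholds (extinction concentrations) inherit the anchor-rate
  calibration; only the abrupt/gradual dichotomy in *m* is a structural
  result.
* No stochastic birth–death variant, no spatial structure, no
  effector-cell (ADCC) compartment, no combination-chemotherapy
  pharmacodynamics.
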