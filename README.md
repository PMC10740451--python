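# clonedyn

Two-clone growth dynamics for drug-resistant lymphoma: coupled logistic
ODEs with configurable interclonal interactions, antibody-induced cell
death under realistic dosing, short-horizon growth-rate inference, and
correlation-based calibration of the interaction constants.

## The problem

Diffuse large B-cell lymphoma (DLBCL) tumors are heterogeneous: a
therapy-sensitive parental clone and a drug-resistant clone share one
microenvironment, and the interaction between them shapes both the
untreated composition of the tumor and how much resistant disease survives
antibody therapy.  `clonedyn` models the two clones as populations *G*
(sensitive) and *R* (resistant) growing logistically against a shared
carrying capacity *N*, with an interaction term and an antibody kill term:

```
dG/dt = k_G G (1 - (G+R)/N) + C_GR R G^m/(G+R)^m - a_G f(t) [G]
dR/dt = k_R R (1 - (G+R)/N) + C_RG R G^m/(G+R)^m - a_R f(t) [R]
```

The interaction comes in two variants: the classic Lotka–Volterra product
`C·G·R` and the cooperativity-weighted form above, whose exponent *m* sets
which mixture maximizes the interaction (resistant fraction `1/(1+m)`:
50% at *m* = 1, 33.3% at *m* = 2).  The sign pattern of `(C_GR, C_RG)`
defines mutualism (+/+), parasitism (−/+) and competition (−/−).  The
therapy function *f(t)* is either a constant or one-compartment
pharmacokinetics for repeated IV doses (superposed exponential decay,
`k_e = ln 2 / t_half`); the kill term is either the population-independent
form `−a·f(t)` or the per-cell form `−a·f(t)·X` (bracketed above).

Because per-clone counts are only observable over a few days in culture,
inference works through *interpolated rate constants*: each clone's
five-day track in a mixture is fitted with the standard logistic
`y(t) = N_fit/(1 + b e^{-kt})`, and the fitted *k* as a function of the
initial resistant fraction is the model's short-horizon fingerprint.
Interaction constants are calibrated by maximizing the product of the
per-clone Pearson correlations between simulated and observed rate
profiles.  A synthetic-data module generates the daily GFP/RFP-style
counts (multiplicative lognormal noise) so the whole pipeline runs without
laboratory data.

## Worked example

```python
from clonedyn import (GrowthParams, InteractionParams, ModelParams,
                      simulate, steady_state)

growth = GrowthParams(k_sensitive=1.0, k_resistant=0.5, capacity=6e5)

# no interaction: the capacity splits by the conservation law G ~ R^(kG/kR)
traj = simulate(ModelParams(growth), init=(5e4, 5e4), t_end=10.0)
print(traj.total[-1])                        # 599411.2448950451
print(traj.sensitive[-1] / traj.resistant[-1])  # 2.9983177502207816

# mutualistic coupling: one convergent state past the logistic capacity
mut = ModelParams(growth, InteractionParams(1e-6, 1e-6, weighted=False))
print(steady_state(mut, (5e4, 5e4)).state)
# CloneState(sensitive=333333.3..., resistant=666666.6...)
```

By day 10 the non-interacting culture sits at its 600,000-cell capacity
(599,411 cells, 0.1% short) split 3:1 sensitive:resistant — the square of
the 2:1 rate ratio acting through the conservation law.  Adding equal
mutualistic constants moves the steady state to 10⁶ cells (beyond the
logistic capacity) with the *resistant* clone dominant, and that state is
reached from any starting mixture.

The numbered scripts under `analysis/` run the full studies and write
tables under `results/`; for example

```sh
python analysis/05_therapy_sweeps.py
#   m=0.5: shift= gradual, sensitive extinction at concentration 0.05
#   m=1: shift= gradual, sensitive extinction at concentration 0.50
#   m=2: shift=  abrupt, sensitive extinction at concentration 0.15
#   m=3: shift=  abrupt, sensitive extinction at concentration 0.10
```

shows the central therapy result: with cooperativity exponents above one
the sensitive clone holds a substantial share of the culture right up to a
threshold antibody concentration and vanishes abruptly beyond it, while
exponents at or below one fade gradually.  The threshold *locations*
depend on the calibrated interaction constants; the shift *classes* are
the robust result.

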