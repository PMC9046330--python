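# Methods

This note documents the model implemented by `fallscea`: its structure
and assumptions, the parameters and their defaults, the numerical
choices, the points where the published description left the design
open and how this package resolved them, and what the validation
machinery does and does not establish.

## Population and decision problem

Men aged 68 at model start with non-metastatic prostate cancer on
curative radiotherapy plus adjuvant ADT — a population with elevated
fall and fracture risk from treatment-induced sarcopenia and bone loss.
The intervention is 12 months of twice-weekly supervised group exercise
(AU$767 per participant under the default delivery model); the
comparator is advice-only usual care. Health-system perspective, 2019
AUD, QALYs via health-state utilities, willingness to pay
AU$50,000/QALY, 3-year horizon (1 intervention year plus a 2-year
sustained effect), 3-month cycles (the typical recovery period after a
fall injury), 5% annual discounting of costs and QALYs.

## State space and transition structure

Seven operational states: `AT_RISK_FIRST`, `AT_RISK_RECURRENT`,
`FRACTURE_MAJOR`, `FRACTURE_MINOR`, `INJURY_MAJOR`, `INJURY_MINOR`,
`DEAD`. The fracture/injury states are tunnels occupied for exactly one
cycle; survivors exit to `AT_RISK_RECURRENT` (they never return to
first-fall risk), and `DEAD` is absorbing.

Annual probabilities become per-cycle probabilities through the
constant-rate transform `1 − (1 − p)^f` with `f = 1/4`; linear division
would overshoot for large probabilities.

Conditional on a fall in either at-risk state:

* fracture with probability `p_fracture_annual` = 0.12, split
  major/minor 0.62/0.38;
* otherwise a non-fracture injury with probability `p_nonfx_injury`
  = 0.88, split major/minor 0.06/0.94;
* the uninjured remainder passes to recurrent-fall risk with no cost;
* **only major events can be fatal**: entrants to a major fracture or
  major injury die at event time with the age-band case fatality
  (0.023 / 0.043 / 0.065 for ages 60–64 / 65–69 / 70–74, exact
  fractional age at the cycle boundary). Minor events never kill, per
  the stated modelling assumption. Fatal major events bypass the
  tunnel, so they accrue neither the treatment cost nor the tunnel
  utility.

Non-fallers and tunnel occupants face per-cycle background mortality,
looked up by completed year of age in a packaged table of national male
annual death probabilities for ages 60–75 (clamped outside that range).
These life-table values are approximate external defaults — the cited
national tables print more precision — and are override-able through
the configuration; over a 3-year horizon their effect is small and
symmetric across arms.

### How the exercise effect enters

The published inputs give three relative risks (falls 0.76, fall-related
fractures 0.44, non-fracture injuries 0.70) without stating the exact
nodes they multiply. Several attachments are arithmetically possible;
this package adopts the one that reproduces the published per-arm cost,
QALY and NMB cells (a grid over the candidate structures identifies it
essentially uniquely — see "Structural identification" below):

* the fall RR scales the **annual first-fall probability**
  (0.36 → 0.274); the recurrent-fall probability (0.65) is
  arm-independent — the programme reduces the chance of becoming a
  faller in a year, while fall frequency among established recurrent
  fallers is taken as unchanged;
* the fracture RR is a **marginal annual-risk ratio**, so conditional
  on having fallen the exercise-arm fracture probability is
  `0.12 × 0.44 / 0.76` — the marginal annual fracture risk falls by
  exactly the published RR;
* the injury RR multiplies the **conditional** injury probability
  (0.88 → 0.616);
* fear of falling: the recurrent-risk state uses utility 0.72
  (control) vs 0.74 (exercise).

All three effects persist over the whole horizon (the sustained-effect
assumption), including under horizon extension, where the year-3 values
are carried forward without decay.

## Rewards

State-membership QALYs use the standard life-table half-cycle
correction: occupancy rows 0..N contribute `u(state) × f` weighted ½ at
the first and last row and 1 elsewhere, each row discounted by
`(1+r)^(−t·f)`. Utilities: 0.79 baseline, 0.475/0.565 major/minor
fracture, 0.47/0.765 major/minor injury (tunnel utilities are used
as-is because the sources pre-averaged the at-event and 3-month
scores), 0.72/0.74 recurrent risk by arm, 0 dead.

One-off treatment costs (AU$20,724 / 8,797 / 10,040 / 1,115 for major/
minor fracture and major/minor injury) are charged once on tunnel
entry, in the entry row, discounted by that row's factor, and excluded
from the half-cycle correction (it applies to continuous membership
rewards only). The intervention cost is charged to the exercise arm
once at time zero, undiscounted: the published scenario arithmetic
(base iNMB minus the $3,304-delivery iNMB equals the nominal cost
difference of $2,537) identifies exactly this treatment, and the
package's cost-linearity property `iNMB(c) = iNMB(767) − (c − 767)`
holds to machine precision.

ICERs are suppressed in favour of a dominance flag whenever one arm is
both cheaper and more effective; negative ratios are uninterpretable.
Reports round to whole dollars and two-decimal QALYs; all internal
arithmetic is full precision.

## Structural identification

With the most literal reading — conditional fracture probability
0.12/0.36 = 1/3 and a death branch on every fall — the control arm
costs AU$8,364 and 3-year mortality reaches 12%, roughly double the
published cells. The adopted structure reproduces the published
per-arm QALYs to 0.003 (2.0707/2.1074 vs the implied 2.0647/2.1013),
the incremental QALYs to four decimals (0.0366), and both NMB cells
within ~AU$100; the residual gap in the cost cells (AU$4,474 vs 4,135
control) plausibly reflects the approximate life-table defaults and
remaining unprinted details. This calibration-by-structure uses only
published aggregate outputs, never tuned continuous parameters.

## Uncertainty analysis

**One-way DSA.** Each parameter with a 95% CI is pinned to each bound
with everything else at its mean and the full pipeline re-run; entries
are sorted by iNMB spread. The major/minor splits are varied through
their "major" share with the complement co-varying, preserving
sum-to-one; hence `p_fx_minor`/`p_inj_minor` are not separate entries.
Default ranges are the published CIs; the original figure used wider,
unpublished ranges for some parameters (its cost-of-exercise bar
reaches the AU$3,304 delivery model), so the published influence
ranking is not reproducible from CI ranges alone — under CIs the
fracture RR and the two fear-of-falling utilities dominate instead.

**Scenarios.** Named costings of alternative delivery models: SA2a
(groups of six plus out-of-pocket travel/gym costs, AU$2,338), SA4
(chronic-disease group-exercise item, AU$2,154), SA4a (SA4 plus
out-of-pocket costs, AU$3,304), implemented as pure intervention-cost
substitutions; and horizon extension.

**PSA.** Distributions are fitted by method of moments from each mean
and CI with `SE = (CI width)/3.92`: Beta for probabilities, proportions
and utilities; Gamma for costs; logNormal for RRs with the printed RR
as the median (ratio estimates pool on the log scale). Parameters are
drawn independently (only marginals are published); the major/minor
splits are sampled as a single Beta on the major share; draws that
break a conditional decomposition (e.g. conditional fracture
probability above 1) are rejected and redrawn with a logged count
(clamping would bias the marginals). Sampling uses one integer seed
with a named substream per parameter, so results are invariant to
parameter ordering.

Each iteration is evaluated in one of two modes:

* `individual` (default): one simulated patient per arm per draw, so
  the Monte Carlo distribution carries first-order (between-patient)
  variability — deaths, AU$20k fracture events — on top of parameter
  uncertainty. Per-draw NMB spread is then ~AU$14k, the 95% CI of the
  mean over 10,000 iterations is ~±AU$280 wide, and the probability of
  a positive iNMB at AU$50,000/QALY is ~0.55. These are the statistics
  the published analysis reports (its CI width and 58% probability are
  only consistent with trial-level noise; a parameter-only PSA of this
  model has per-draw iNMB spread ~AU$1k and probability ≈ 1.0).
* `cohort`: textbook second-order PSA, each draw evaluated exactly by
  the cohort engine (vectorised over all draws in one pass).

The mean-NMB 95% CI is the normal-approximation interval
`mean ± 1.96·SE` over draws. The CEAC reports, at each threshold on a
0–100,000 grid (step 1,000), the fraction of draws with
`w·ΔE − ΔC ≥ 0`; ties count as cost-effective.

## Microsimulation validation

`fallscea.microsim` simulates individual trajectories through the
identical stochastic process — same per-cycle probabilities, same
half-cycle weighting of realized membership rewards, same entry-row
event costs and discounting — so the cohort engine is the exact
expectation of the simulated process and means must agree within Monte
Carlo error (checked as z-scores at n = 200,000 per arm, threshold
|z| < 3). The default mode draws next states from the very transition
matrices the cohort engine multiplies, isolating reward-accumulation
bugs; an `event` mode re-derives every branch probability independently
(fall → fracture → severity → death / injury chains) as an end-to-end
cross-check of the probability construction itself.

This machinery validates internal consistency, not external truth: it
shows the deterministic engine integrates the assumed process
correctly, and (in individual PSA mode) it *is* the data-generating
process. It cannot show the assumed process matches real ADT patients
— no individual heterogeneity (frailty, covariates), no
residential-care pathway, no decay of the recurrent-fall probability,
and the injury-conditional structure is an interpretation of ambiguous
published labels.

## Numerical and degenerate-input behaviour

Row-stochasticity is exact by construction and asserted to 1e-12;
occupancy conservation holds to 1e-9 over the horizon. Degenerate
inputs behave sensibly: zero fall probabilities collapse the model to
background mortality with iNMB = −c_intervention; zero discounting and
zero mortality give exactly `u_baseline × horizon` QALYs (2.37);
point-mass CIs produce fixed draws. Config validation names the
offending field; unknown keys are rejected rather than ignored.

## Known limitations

* Background mortality defaults are approximate national male values;
  users needing exact life-table reproduction should override them.
* The published tornado ranking and Fig-level bar lengths are not
  reproducible (unpublished ranges); the package reports its own
  CI-based ranking instead.
* Costs are fixed 2019 AUD; no CPI or currency machinery.
* No EVPI; not part of the original analysis.
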