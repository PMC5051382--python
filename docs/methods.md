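# Methods

`cvdcea` estimates the lifetime cost-effectiveness of an intervention that
lowers 10-year cardiovascular disease (CVD) risk, starting from what a
12-month trial observes: per-arm QRISK2 scores (baseline and follow-up
adjusted for baseline) and per-arm year-0 NHS costs and QALYs.  Everything
beyond year 0 is simulated.

## Model structure

A Markov cohort state-transition model with annual cycles.  States:
event-free; acute first-year states for AMI, stable angina, unstable
angina, TIA and stroke; chronic post-AMI, post-TIA and post-stroke states;
and two absorbing death states (CVD death, other-cause death).  Angina has
no separate post state: it is a chronic condition, so each angina state is
its own post-event state and keeps accruing its own cost and utility from
the year of onset, including secondary-event risk in that first year.
AMI, TIA and stroke acute states last exactly one cycle (first-year
costing), then settle deterministically into their post state.

Every living state is expanded by a lifetime event count capped at three
(entering any acute state increments it; settling into a post state does
not), giving 27 reachable computational states.  At the cap only
persistence and death remain.  Repeat events arise from chronic states by
default; `repeat_from_acute=True` also allows them in the acute year.

Cohorts of 1000 start event-free and cycle until death or age 100; the
transition that would land at age 100 routes all survivors to other-cause
death, so the horizon is `100 − age0` cycles.

## Transition probabilities

Competing risks are ordered: other-cause death first (life-table `qx`
times a CVD-excluded standardised mortality ratio, capped at 1), CVD
dynamics conditional on surviving it.  Primary any-event risk comes from
the risk trajectory; secondary-event risk from an age/sex/from-state
table.  Every event probability splits by age/sex case fatality into a
flow to CVD death and a flow into the acute state.  Event probabilities
within a cycle are exclusive; if they sum above 1 construction fails
loudly rather than rescaling.

## Risk trajectories

Year 0 uses the baseline 10-year score, year 1 the adjusted 12-month
score.  Later years grow the 10-year score multiplicatively by male growth
rates at the attained age (used for both sexes, which keeps female risk
below male risk and paths plausible); from age 85 — beyond the risk
score's validated range — risk instead grows by +1 percentage point per
year.  Both rules cap at 100%.  The additive reading of the over-84 rule
follows its origin as an OLS slope of score on age; the multiplicative
alternative is a one-line swap in `extrapolate_r10`.

Annualization assumes a constant hazard: `p = 1 − (1 − R10)^(1/10)`,
standard practice and order-preserving.  The annual any-event probability
is split into event-specific probabilities by age/sex incidence shares.

Duration-of-effect scenarios (1, 2, 5 years, lifetime): the intervention
arm keeps its own path for model years 1..D, year D+1 averages the two
arms' scores (smoothing the reversion), and later years follow the control
path.  Year 0 is never touched — its outcomes are trial-observed.

## Accrual, half-cycle correction, discounting

Cycle-t accruals weight the trapezoidal average of occupancy at t and t+1
(the standard half-cycle correction), identically for costs and QALYs and
identically in the microsimulation, so both estimators share one estimand.
Utilities are age/sex population norms times a state multiplier (constant
proportional effect).  Discounting is 3.5%/year with cycle t weighted
`1.035^−t`; cycle 0 is undiscounted and its accruals are replaced by the
stratum's trial-observed year-0 cost and QALYs (intervention cost
included).

## Probabilistic sensitivity analysis

1000 iterations; per iteration one joint draw shared by both arms (common
random numbers — only the intervention's risk path and year-0 inputs
differ, isolating the intervention signal).  Costs: gamma with shape
`(mean/SE)²`, scale `SE²/mean`; zero SE means fixed.  Utility multipliers
and the SMR: univariate normals (utilities clamped to [0, 1]).  The
unstable-angina multiplier is 0.9 × the stable-angina *draw*, so the 90%
relationship holds in every iteration; post-event draws are raised to at
least their acute event's draw; repeat events reuse first-event
parameters.  Incidence shares, secondary transitions and case fatality
are fixed (no published uncertainty), as are risk scores (their variance
structure is unpublished) — uncertainty is therefore understated, which
narrows NMB intervals.

Per-iteration RNG substreams are spawned from the seed alone, so scenarios
and arms share draws and scenario contrasts are structural, not
Monte-Carlo noise.  Since risk paths and event/fatality tables are fixed,
the survival-conditional CVD matrices are precomputed once per stratum;
each iteration only rescales the mortality layer and the value vectors.

## Decision outputs

Per-patient arm means, increments, ICER of the means (ratio of means, with
dominance labels), NMB `λΔQ − ΔC`, CEAC (fraction of iterations with
NMB > 0) on a £0–50,000 grid in £500 steps (always including £20,000 and
£30,000), and CE-plane quadrant shares (axis-exact points go to the
costlier/less-effective side).  Both percentile (2.5/97.5) and
SE-of-the-mean intervals are reported; percentile is the headline — note a
percentile interval across iterations is a distributional band, typically
wider than an SE interval of the mean.

## Synthetic data: what it emulates, what it does not

The generator states a world once; its defaults are not tuned.
Trial-anchored values: 80% male, entry ages 67/69, the four arm×sex
risk-score pairs, +£138 cost and +0.012 QALY year-0 increments.  Control
year-0 levels (£2000, 0.79 QALYs) are plausible constants — only
increments drive incremental results.  The parameter tables stand in for
unavailable published appendix values with the right *structure*: acute
costs (£1900–£9500) above chronic costs (£300–£1800) above the zero
event-free cost; utility multipliers with post ≥ acute and unstable
angina = 0.9 × stable; incidence shares normalized per age band and sex
with stroke share rising in age; secondary-event totals of 3–5%/year
rising with age, recurrence of the linked event weighted double; case
fatality ~30% (AMI) and ~25% (stroke) rising with age; Gompertz mortality
calibrated to `qx(70, male) = 0.02` with female rates at 85%; SMR 0.85
(SE 0.05); risk growth 4–6%/year over ages 40–84.  Every table carries a
`provenance` column so transcribed real values can replace it per table.

A green test therefore establishes the *mechanics and orderings* of the
analysis (conservation, estimator agreement, duration monotonicity,
CEAC limits), not the published point estimates, which depend on appendix
values this package does not contain.

## Numerical choices and edge cases

Row-stochasticity enforced to 1e-8 at construction; cohort conservation
checked every cycle; degenerate distributions (SE 0) short-circuit to
their means so a zero-SE PSA is bit-for-bit deterministic; normal draws
clamp (utilities to [0, 1], SMR to ≥ 0); `r10 = 1` annualizes to 1; age
lookups clamp to the covered bands (40–99).  The microsimulation samples
categorically from each cycle's matrix rows and accrues with the cohort
engine's trapezoid weights, so agreement is O(1/√n).

## Known limitations

No within-cycle event timing beyond the half-cycle convention; no tunnel
states beyond the single acute year; no sampling of risk scores, incidence
or fatality parameters; year-0 increments fixed rather than sampled (the
dominant driver of decision uncertainty in short-duration scenarios is
therefore absent, making acceptability probabilities optimistic); no
value-of-information analysis; costs fixed at 2012/13 GBP with no
inflation adjustment.
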