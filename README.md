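# cvdcea

Lifetime cost-effectiveness cohort simulation for interventions that lower
cardiovascular disease (CVD) risk.

A 12-month trial of a risk-lowering intervention (for example a telehealth
service for patients with 10-year QRISK2 risk ≥ 20%) observes only one
year of costs, QALYs and risk-score change.  `cvdcea` extrapolates those
observations over the remaining lifetime of the cohort with a Markov
state-transition model, for analysts who need to know whether the
intervention is cost-effective under different assumptions about how long
its effect lasts.

## Model

Annual-cycle cohort model over an event-free state, acute event states
(AMI, stable/unstable angina, TIA, stroke), chronic post-event states and
two absorbing death states, expanded by a lifetime event count capped at
three.  Trial risk scores are extrapolated over age, converted to annual
any-event probabilities under a constant hazard,

    p = 1 − (1 − R10)^(1/10),

split into event-specific probabilities by age/sex incidence, and combined
with secondary-event, case-fatality and life-table × SMR mortality inputs
into row-stochastic transition tables.  Costs and QALYs accrue with a
half-cycle (trapezoidal) correction, discounted at 3.5%/year; year-0
accruals are the trial-observed values.  A probabilistic sensitivity
analysis (gamma costs, normal utilities and SMR; 1000 iterations) yields

    ICER = ΔC / ΔQ,    NMB(λ) = λ·ΔQ − ΔC,

cost-effectiveness acceptability curves and CE-plane quadrant shares for
durations of intervention effect of 1, 2, 5 years and lifetime.  An
individual-level microsimulation over the same transition tables validates
the cohort engine.  All inputs ship as synthetic stand-ins with documented
structure (see `docs/methods.md`), replaceable table-by-table with
transcribed published values.

## Worked example

```python
from cvdcea import (EffectScenario, generate_cohort_strata,
                    generate_parameter_set, run_psa, summarize)

strata = generate_cohort_strata(1)        # 80% male, ages 67/69, trial risk scores
params = generate_parameter_set(1)        # synthetic stand-in parameter tables
res = run_psa(strata, params, EffectScenario.from_label("lifetime"),
              n_iter=1000, seed=1)
s = summarize(res, thresholds=params.thresholds)
print(f"ΔC=£{s.delta_cost:.0f}  ΔQ={s.delta_qaly:.3f}  ICER=£{s.icer:.0f}  "
      f"P(CE at £20k)={s.prob_ce[20000.0]:.2f}")
```

prints

    ΔC=£77  ΔQ=0.026  ICER=£3004  P(CE at £20k)=1.00

i.e. under a lifetime duration of effect the intervention costs £77 more
per patient, gains 0.026 QALYs, and at £3004 per QALY is cost-effective
with probability 1.00 at the conventional £20,000 threshold.  Shorter
durations give smaller QALY gains and higher ICERs (for example the
1-year scenario: ΔC=£133, ΔQ=0.013, ICER=£10,132).

The same pipeline is available from the shell:

    cvdcea synth --seed 1 --outdir inputs/
    cvdcea run --config inputs/ --outdir results/ --scenario all --n-iter 1000 --seed 1
    cvdcea oracle --config inputs/ --n 50000   # cohort engine vs microsimulation

`run` writes `summary.csv` (per-patient averages, increments, ICER, NMB
and acceptability probabilities per scenario), `ceac.csv` and `plane.csv`
(plot-ready curves and CE-plane points).

## Acceptance script

    python scripts/acceptance.py --seed 1 --out results/acceptance.json

regenerates the synthetic inputs from the seed, runs the full four-scenario
1000-iteration PSA, and prints the per-scenario decision summary table.
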