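# sbpsim

A deterministic, success-rate-oriented simulator comparing two strategies
for preventing cardiovascular events in a virtual population of middle-aged
men: the **high-risk approach** (prescribing antihypertensive medication to
individuals above a systolic blood pressure threshold) and the **population
approach** (a metabolic-syndrome health-promotion program offered to
everyone). It is aimed at epidemiologists and health-policy modellers who
want a transparent, closed-form-checked model of how consultation rates,
treatment adherence and campaign success rates translate into population
incidence reductions.

## Model

All cardiovascular risk factors are projected onto a single exposure,
systolic blood pressure (SBP, mm Hg). The population follows
x ~ N(μ, σ²) with density f(x), and individual risk rises exponentially:

    P(x) = (1/l) · exp((x − m) / k)        [events/year]

The population (cumulative) incidence rate is ∫ f(x) P(x) dx, which has the
closed form (1/l)·exp((μ−m)/k + σ²/2k²) — exactly 0.01 events/year at the
defaults μ=130, σ=20, k=20, l=100, m=140.

**Medication** (high-risk): above an initiation threshold e, a person
consults a physician with probability s(x) = 1 − exp(−(x−a)·b) and, if
treated, has SBP lowered by (x−c)·d, of which 50% is credited to risk
reduction within the convergence horizon:

    IR_post = ∫_L^e f·P dx + ∫_e^H f·P(x − g(x))·s(x) dx + ∫_e^H f·P·(1 − s(x)) dx

**Promotion** (population): a fraction β of everyone (aggregated from a
stratified campaign table: affirmative / motivating / information-only /
indifferent strata) shifts SBP down by α, again 50%-credited:

    IR_post = β·∫ f·P(x − α/2) dx + (1 − β)·∫ f·P dx

Strategies are compared on ΔIR = IR_baseline − IR_post and on
N_HC = 1/ΔIR, the number of annual health checks needed to prevent one
event per year.

## Worked example

The optimistic medication scenario (alarm a=140, access b=0.03, target
c=140, adherence d=0.7, initiation e=150) against the optimistic promotion
campaign (α=10 mm Hg, β=0.275), both with k=20:

```sh
$ sbpsim medication --a 140 --b 0.03 --c 140 --d 0.7 --e 150
baseline IR = 0.01
post IR     = 0.009
delta IR    = 0.000997
N_HC        = 1003

$ sbpsim promotion --alpha 10 --beta 0.275
baseline IR = 0.01
post IR     = 0.00939
delta IR    = 0.000608
N_HC        = 1644

$ sbpsim compare
medication delta IR = 0.000997 (N_HC = 1003)
promotion  delta IR = 0.000608 (N_HC = 1644)
delta ratio (med/promo) = 1.64
winner: medication
```

Reading: the baseline population suffers 0.01 events/year. Medicating
hypertensives above 150 mm Hg removes about 1.0 × 10⁻³ events/year, so
roughly a thousand annual health checks prevent one event per year. The
optimistic campaign removes 6.1 × 10⁻⁴ events/year; the high-risk strategy
prevents ~1.6× more events on this baseline, and the advantage grows with
steeper risk curves.

Sensitivity grids over all scenarios (`sbpsim table2`, `sbpsim table3`)
write CSV files plus full-precision JSON twins; `sbpsim figures` renders
the risk, consultation and pre/post curves. Parameters can also come from
a YAML/JSON config file (`--config`); an empty file means all defaults.

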