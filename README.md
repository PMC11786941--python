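# carechoice

Structural discrete-choice analysis of the joint decision to work and to
provide informal care, with counterfactual simulation of financial
incentives for caregiving.

## The problem

Population aging raises the demand for informal (family-provided)
long-term care, and a recurring policy question is whether financial
incentives can persuade more *potential carers* — people who face a
caregiving decision — to provide care. Caregiving competes with paid
work for time, so its opportunity cost depends on the individual's wage;
but preferences and social norms (who is "expected" to care) matter too.
A structural model of the joint labor-supply/caregiving choice can
disentangle the two: opportunity costs enter through the budget set,
everything else through preference coefficients.

## The model

Each individual chooses one of nine alternatives crossing weekly work
hours hw ∈ {0, 30, 40} with weekly informal care hours hc ∈ {0, 7, 14}.
Leisure is the residual of a 112-hour week, l = 112 − hw − hc. The
utility of alternative j for individual i is quadratic,

    U_ij = l_j β_li + C_ij β_ci + hc_j β_hc + l_j² β_l2 + C_ij² β_c2
           + X_i′ S_j β_X + ε_ij,

where C_ij = t(w_i·hw_j + I_i) is net monthly household income under a
(stylized, configurable) tax–transfer schedule t(·), X_i′S_j collects
interactions of individual covariates (gender, age, East Germany,
migration background, children, household size) with the alternative's
income, leisure and care hours, and ε_ij is iid type-I extreme value.
The income and leisure coefficients are random across individuals,
β_ci ~ N(β_c, sd_c²), β_li ~ N(β_l, sd_l²), capturing unobserved
preference heterogeneity. Hourly wages of non-workers are imputed by a
Heckman two-step selection correction.

The mixed-logit choice probability P_ik = ∫ L_ik(β) f(β) dβ has no
closed form; it is simulated as the average of conditional-logit
probabilities over R Halton draws, and the simulated log-likelihood

    SLL = Σ_i Σ_j d_ij ln (1/R) Σ_r L_ij(β_ir)

is maximized (BHHH quasi-Newton with analytic scores).

Counterfactuals hold each individual's coefficients *and* error terms
fixed: calibration draws (β_i, ε_i) consistent with the observed
baseline choice (accept–reject over Gumbel vectors), and scenarios only
change budget sets — a 1% wage increase (elasticities), compensating
every care hour at the individual's own gross wage taxed as labor income
(reform A), or adding a revenue-neutral fixed net benefit to every
caring alternative (reform B). Effects are aggregated by exogenous
subgroups with parametric-bootstrap confidence intervals.

Because the survey microdata behind such analyses are restricted, the
package ships a synthetic-data generator that emulates the relevant
cross-section (demographic margins, gender-gapped log-normal wages,
selective wage missingness) and simulates observed choices from the
model itself at known true parameters — so estimation, calibration and
the counterfactuals are all testable against ground truth.

## Worked example

```python
import carechoice as cc

cs, sched = cc.build_choice_set(), cc.TaxSchedule()
data = cc.generate_dataset(cc.GeneratorConfig(n=2000, seed=21), cs, sched)
data = data.assign(gross_wage=cc.impute_wages(cc.fit_heckman(data), data))

result = cc.estimate(data, cs, sched, R=200, seed=3, n_starts=1)
analysis = cc.run_scenario_analysis(
    result, data, cs, sched, cc.ReformSpec("wage_compensation"),
    n_reps=30, seed=4)
print(analysis["table"].loc["all"].round(3))
```

prints (seed 21):

```
d_labor_participation_pp           -0.984
d_work_hours_pct                   -1.584
d_care_participation_pp            10.371
post_care_participation_pct        36.797
baseline_care_participation_pct    26.426
retained_share                      1.000
```

Reading: compensating informal care hours at the individual's own gross
wage raises care participation by about 10 percentage points in this
synthetic population (from 26.4% to 36.8%), while labor-force
participation falls slightly (−1.0 pp) and total working hours fall by
1.6% — care becomes financially equivalent to work, so some carers
reduce market hours. `retained_share` is the fraction of calibrated
individual-replicates for which consistent error terms were found; all
outcome tables are computed on that retained sample.

The same pipeline is available from a shell:

```bash
carechoice-simulate --reform wage_comp --n 2000 --reps 50 --seed 7 --out results/
```

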