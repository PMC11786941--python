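# Methods

## Choice set and time budget

The decision unit is one potential carer allocating a weekly time
endowment of T = 112 hours (7 days minus 8 hours of sleep per day)
across market work hw ∈ {0, 30, 40}, informal care hc ∈ {0, 7, 14} and
residual leisure l = T − hw − hc. The nine alternatives are ordered
work-outer/care-inner, and every downstream matrix (incomes, utilities,
calibrated errors) uses that fixed ordering. Observed continuous hours
are snapped to the grid by thresholds (work: <15 → 0, 15–35 → 30,
>35 → 40; care: <1 → 0, 1–10.5 → 7, >10.5 → 14). The thresholds are a
package convention (configurable); survey instruments rarely document a
canonical discretization.

## Utility specification

Deterministic utility is a quadratic polynomial in net monthly household
income C, leisure l and care hours hc, with 17 mean coefficients (linear
terms, two quadratics, income×leisure, and interactions of C, l, hc
with individual covariates; age interacts in years and as age²/100) and
independent normal random coefficients on the linear income and leisure
terms (2 standard deviations, 19 free parameters in total). There are no
alternative-specific constants: identification comes entirely from the
variation of (C, l, hc) across the nine cells. Care hours enter
separately from leisure so that caregiving can carry utility or
disutility beyond its time cost; the care coefficients absorb
preferences and norms.

## Tax–transfer schedule

Net household income is C_ij = t(w_i·hw_j·4.345 + I_i), with 4.345 weeks
per month. The default t(·) is deliberately stylized: a basic allowance
of 1000 €/month, marginal rates 15/25/35% on taxable income 0–2000 /
2000–4500 / >4500 above the allowance, a flat 20% social contribution on
gross labor income, and a 900 €/month transfer floor. It is continuous
and non-decreasing in gross income, which is all the model requires;
replacing it with a detailed national microsimulation only changes the
budget sets, not the machinery. Statutory long-term-care cash benefit
amounts (316–901 €/month by care level) are kept as documented constants
but unused by default. Under reform A, the care compensation
w_i·hc_j·4.345 is added to gross *labor* income at every alternative
(paid regardless of work status) and taxed jointly with it; under reform
B a fixed amount is added net of tax to every caring alternative.

## Wage imputation

Hourly wages are missing for non-workers, and employment is treated as
selective. A probit of wage observation on demographics plus the number
of adults in the household (the exclusion restriction — it enters
selection only) is followed by OLS of log wage on demographics and the
inverse Mills ratio. Imputations are exp(x′β̂) from the corrected wage
equation, excluding the Mills term (the object of interest is the
unconditional wage offer) and without smearing retransformation
(configurable choice; at the generator's log-normal errors the
retransformation constant is common to all and irrelevant for relative
comparisons). Observed wages are never modified. The selection
covariates are a package convention; published applications typically do
not report theirs.

## Estimation

The simulated log-likelihood averages conditional-logit probabilities
over R Halton draws (bases 2 and 3, first 10 points discarded, inverse-
normal transformed; each individual takes a consecutive block of R
points of one long sequence). Plain — not scrambled — Halton is used;
the draws are deterministic given (R, burn), so the likelihood surface
is fixed and results are exactly reproducible. R defaults to 500 (the
analysis code here mostly runs R = 200, which recovery experiments show
is ample at these sample sizes).

Numerical choices:

* **Scaling.** Design columns are rescaled to unit root-mean-square
  before optimization (raw scales — income in thousands of euros against
  leisure near 100 hours, and their squares — are severely
  ill-conditioned); estimates and covariance are mapped back to natural
  units (per euro, per hour) for reporting.
* **Optimizer.** BHHH quasi-Newton: steps solve (Σ g_i g_i′) d = Σ g_i
  with analytic per-individual scores and a backtracking (Armijo) line
  search; warm start at the conditional-logit maximum (degenerate
  mixture, a single zero draw). Convergence at max-gradient 1e-5, or
  relative SLL change 1e-9 with a loose gradient check; because the
  likelihood is an even, extremely flat function of each sd near a
  boundary optimum (true sd = 0), two consecutive negligible-improvement
  steps also terminate. Three starts by
  default (the warm start plus two jittered copies) to guard against
  local optima; non-convergence is flagged on the result and warned,
  never silently returned.
* **Standard deviations** of the random coefficients are estimated
  unconstrained; absolute values are applied at reporting (the
  likelihood is even in each sd).
* **Standard errors** are the H⁻¹BH⁻¹ sandwich with B the outer product
  of scores and H a central-finite-difference Hessian of the analytic
  gradient.
* **Weights** are not used in the likelihood; they enter descriptive and
  outcome aggregation only.
* AIC = 2k − 2·SLL with k = 19.

Posterior individual-level coefficients are likelihood-weighted means
over the draw set, E[β_i | choice] = Σ_r β_r L_i(β_r) / Σ_r L_i(β_r);
marginal-utility sign diagnostics (shares of individuals with positive
dU/dC, dU/dl, dU/dhc at the observed alternative; a zero derivative
counts as not positive) are evaluated at these posterior means.

## Calibration

Counterfactuals require per-individual (β_i, ε_i) consistent with the
observed baseline choice. For each individual and replicate, a
coefficient draw is sampled from the estimation draws with probability
proportional to L_i(β_r) (consistent with the posterior means; a
"population" mode drawing unconditionally from the estimated normals is
also available), then ε is drawn by accept–reject over iid standard
Gumbel vectors until argmax_j(V_ij + ε_ij) equals the observed choice,
capped at max_attempts = 1000 (default n_reps = 50 replicates).
Accept–reject was chosen for transparency — it makes the conditioning
explicit — and the closed-form conditional law (the chosen alternative's
error is Gumbel located at −ln P_ik) serves as an independent test
oracle. Replicates exhausting the cap are flagged invalid and excluded
from aggregation; every outcome table reports the retained share, and
post-scenario participation equals baseline participation plus the
effect only within that retained sample.

## Counterfactual scenarios and aggregation

Scenarios change budget sets only: wage change (elasticities use +1%),
reform A (care hours compensated at the individual gross wage, taxed as
labor income), reform B (a fixed net benefit on caring alternatives;
when no amount is configured it is set revenue-neutral as the weighted,
replicate-averaged mean net income gain from reform A among individuals
choosing a care alternative under reform A — a documented convention
with scope switches for baseline carers or everyone, since "mean net
compensation" is ambiguous). Outcomes: labor-force participation
(weighted share hw > 0, pp), working hours (percent change of the
weighted mean over all individuals, zeros included — the labor-supply
convention; a workers-only variant is a one-line change in the
aggregation), care participation (weighted share hc > 0, pp). Subgroups
use exogenous variables only: gender, weighted-median wage split (on the
full analysis sample after imputation), age ≤/> 50, and the gender×wage
cells. Confidence intervals are parametric bootstrap: parameter vectors
from N(θ̂, Σ̂) (covariance eigenvalue-clipped to PSD if necessary, count
reported), the calibrate-and-simulate pipeline re-run per draw with one
fixed error seed so the intervals isolate parameter uncertainty, and
5th/95th percentiles reported for 90% intervals.

## Synthetic data generator

The generator emulates the cross-section the model consumes: Bernoulli
demographics (female 0.50, East 0.20, migration 0.25, children 0.19),
truncated-normal age (mean 51.5, sd 11, bounds 18–65), log-normal hourly
wages with a male intercept of 2.90 log-euros, a −0.15 female gap and
sd 0.40 (implying means near 19.8/16.9 €/h for men/women), gamma other
household income (mean 2800 €/month, chosen so mean net household income
lands near 4000 €/month under the default schedule), and 1–3 adults per
household. Employment (wage observation) follows a probit latent index
correlated with the wage residual (ρ = 0.5 by default, giving the
selection correction a real structure to detect; ρ = 0 gives the null
case), with an ~87% employment rate. Observed choices are simulated from
the utility model itself: coefficients drawn from their normals, Gumbel
errors added, argmax taken. Default true parameters follow the published
signs and magnitudes of comparable estimates (income 0.002, leisure
0.932, leisure² −0.004, care×female 0.105, sd_income 0.001, sd_leisure
0.136, …); they are study conditions, not estimates.

What the generator does **not** emulate: panel structure and attrition,
survey weighting design (weights default to 1), measurement error in
hours or wages, household joint decisions, and any dependence of wage
missingness on the *simulated* choice (missingness follows the probit
rule, so a synthetic non-worker can hold an observed work choice —
harmless for testing, but unlike survey data where the two coincide).
Passing tests therefore demonstrate internal correctness and estimator
performance under the model's own assumptions, not fit to any real
population.

## Problem sizes and reproducibility

Analyses in the test suite and the acceptance script run at n =
2000–3000 individuals, R = 200 draws, 50 calibration replicates and
reduced bootstrap sizes; recovery studies use 12–20 replications at
n = 3000. These sizes were chosen as the point where Monte-Carlo noise
is clearly smaller than the effects being checked while a full run
remains a desk-scale computation. All randomness flows through explicit
seeds (numpy Generator); Halton draws are deterministic by construction.

## Known limitations

* The tax–transfer schedule is a stylized stand-in; effect magnitudes on
  synthetic data should not be read as policy estimates for any country.
* Random coefficients are independent normals on income and leisure
  only; correlated or non-normal heterogeneity is out of scope.
* The calibration accept–reject can be slow for individuals whose
  observed choice has very low model probability; the cap makes this a
  flagged-data problem rather than a runtime one, at the cost of
  excluding exactly those observations the model fits worst (the
  retained-share column keeps this visible).
* Revenue neutrality of reform B is computed against reform A's
  simulated take-up, not against a government budget with administrative
  costs.
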