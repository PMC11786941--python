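"""Counterfactual scenarios on calibrated states, with bootstrap CIs.

Three scenarios are supported, all evaluated with every individual's
coefficient draws and error terms frozen at their calibrated baseline
values (only budget sets change):

* a uniform percentage change in gross hourly wages (the elasticity
  experiment: +1% by convention);
* **reform A** — every informal care hour is compensated at the
  individual's own gross hourly wage and taxed as labor income;
* **reform B** — a single revenue-neutral net amount (the mean net gain
  generated by reform A among its care choosers) added to household
  income in every caring alternative.

Outcomes per subgroup: labor-force participation (weighted share with
positive work hours, percentage points), total working hours (percent
change in the weighted mean over everyone, zeros included), informal
care participation (weighted share with positive care hours, percentage
points) and the post-scenario care-participation level.  Subgroups are
defined from exogenous variables only: everyone, below/above the
weighted median wage, women/men, their four gender-by-wage cells, and
age up to / above 50.  Confidence intervals come from a parametric
bootstrap: parameter vectors drawn from the estimated sampling normal,
the full calibrate-and-simulate pipeline re-run per draw with a fixed
error seed (isolating parameter uncertainty), percentiles reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import CalibratedState, calibrate, state_utilities
from .choice_set import ChoiceSet
from .estimation import EstimationResult, build_mean_design
from .tax_transfer import ReformSpec, TaxSchedule, income_matrix
from .utility_model import UtilityParams

SUBGROUP_ORDER = (
    "all",
    "wage<=p50",
    "wage>p50",
    "women",
    "men",
    "women & wage<=p50",
    "women & wage>p50",
    "men & wage<=p50",
    "men & wage>p50",
    "age<=50",
    "age>50",
)

OUTCOME_COLUMNS = (
    "d_labor_participation_pp",
    "d_work_hours_pct",
    "d_care_participation_pp",
    "post_care_participation_pct",
    "retained_share",
)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cw, 0.5 * cw[-1])])


def subgroup_masks(data: pd.DataFrame) -> dict[str, np.ndarray]:
    """Exogenous subgroup masks (gender, wage median split, age 50)."""
    wage = data["gross_wage"].to_numpy(dtype=float)
    if np.any(np.isnan(wage)):
        raise ValueError("subgrouping needs complete wages: impute first")
    w = data["weight"].to_numpy(dtype=float)
    p50 = weighted_median(wage, w)
    female = data["female"].to_numpy() == 1
    age = data["age"].to_numpy(dtype=float)
    low = wage <= p50
    return {
        "all": np.ones(len(data), dtype=bool),
        "wage<=p50": low,
        "wage>p50": ~low,
        "women": female,
        "men": ~female,
        "women & wage<=p50": female & low,
        "women & wage>p50": female & ~low,
        "men & wage<=p50": ~female & low,
        "men & wage>p50": ~female & ~low,
        "age<=50": age <= 50,
        "age>50": age > 50,
    }


def scenario_income_matrix(
    data: pd.DataFrame,
    choice_set: ChoiceSet,
    schedule: TaxSchedule,
    reform: ReformSpec | None,
) -> np.ndarray:
    return income_matrix(
        data["gross_wage"].to_numpy(dtype=float),
        data["other_income"].to_numpy(dtype=float),
        choice_set, schedule, reform=reform,
    )


def apply_scenario(
    calibrated: CalibratedState,
    reform: ReformSpec | None,
    data: pd.DataFrame,
    choice_set: ChoiceSet,
    schedule: TaxSchedule,
) -> np.ndarray:
    """Optimal alternative per (individual, replicate) under a scenario.

    Recomputes the income matrix under the reform, re-evaluates
    V_ij + eps_ij at the frozen coefficient draws and errors, and takes
    the argmax.  With a null reform the calibrated baseline choices are
    reproduced exactly on every valid replicate.
    """
    C = scenario_income_matrix(data, choice_set, schedule, reform)
    A = build_mean_design(data, choice_set, C)
    V = state_utilities(
        calibrated.theta, calibrated.b_income, calibrated.b_leisure,
        A, C, choice_set.leisure_hours,
    )
    return np.argmax(V + calibrated.eps, axis=2)


def _cell_outcomes(choices, valid, weights, hw, hc, mask):
    """Weighted outcome levels over valid cells of a subgroup."""
    cell_w = np.broadcast_to(weights[:, None], valid.shape) * valid * mask[:, None]
    total = cell_w.sum()
    if total == 0:
        raise ValueError("empty subgroup (or no valid replicates in it)")
    work = (cell_w * (hw[choices] > 0)).sum() / total
    hours = (cell_w * hw[choices]).sum() / total
    care = (cell_w * (hc[choices] > 0)).sum() / total
    retained = cell_w.sum() / (np.broadcast_to(weights[:, None], valid.shape)
                               * mask[:, None]).sum()
    return work, hours, care, retained


def aggregate_effects(
    baseline_choices: np.ndarray,
    scenario_choices: np.ndarray,
    calibrated: CalibratedState,
    data: pd.DataFrame,
    choice_set: ChoiceSet,
) -> pd.DataFrame:
    """Outcome table by subgroup (effects averaged over valid replicates).

    Participation effects are percentage-point changes in weighted
    shares; the working-hours effect is the percent change in the
    weighted mean of hours over all individuals (zeros included).  The
    table also reports the post-scenario care-participation level and
    the retained share of (individual, replicate) cells, so the identity
    post = baseline + delta holds within the retained sample.
    """
    weights = data["weight"].to_numpy(dtype=float)
    hw = choice_set.work_hours
    hc = choice_set.care_hours
    masks = subgroup_masks(data)
    rows = []
    for name in SUBGROUP_ORDER:
        mask = masks[name]
        wb, hb, cb, retained = _cell_outcomes(
            baseline_choices, calibrated.valid, weights, hw, hc, mask)
        ws, hs, cs, _ = _cell_outcomes(
            scenario_choices, calibrated.valid, weights, hw, hc, mask)
        rows.append(
            {
                "subgroup": name,
                "d_labor_participation_pp": 100 * (ws - wb),
                "d_work_hours_pct": 100 * (hs - hb) / hb if hb > 0 else np.nan,
                "d_care_participation_pp": 100 * (cs - cb),
                "post_care_participation_pct": 100 * cs,
                "baseline_care_participation_pct": 100 * cb,
                "retained_share": retained,
            }
        )
    return pd.DataFrame(rows).set_index("subgroup")


def revenue_neutral_benefit(
    calibrated: CalibratedState,
    data: pd.DataFrame,
    choice_set: ChoiceSet,
    schedule: TaxSchedule,
    scope: str = "reform_choosers",
) -> float:
    """Fixed net benefit making reform B revenue-neutral against reform A.

    The mean (weight- and replicate-averaged) net household income gain
    attributable to the wage compensation, evaluated at the alternative
    chosen under reform A.  ``scope`` selects whose gains are averaged:
    ``'reform_choosers'`` (default; individuals choosing a care
    alternative under reform A), ``'baseline_carers'`` or ``'all'``
    (everyone, zero gains at non-care choices included).
    """
    if scope not in {"reform_choosers", "baseline_carers", "all"}:
        raise ValueError(f"unknown scope {scope!r}")
    reform_a = ReformSpec(kind="wage_compensation")
    C_base = scenario_income_matrix(data, choice_set, schedule, None)
    C_a = scenario_income_matrix(data, choice_set, schedule, reform_a)
    choices = apply_scenario(calibrated, reform_a, data, choice_set, schedule)
    rows = np.arange(len(data))[:, None]
    gain = (C_a - C_base)[rows, choices]            # (n, reps)
    weights = np.broadcast_to(
        data["weight"].to_numpy(dtype=float)[:, None], gain.shape)
    cares = choice_set.care_hours[choices] > 0
    if scope == "reform_choosers":
        keep = calibrated.valid & cares
    elif scope == "baseline_carers":
        baseline_cares = choice_set.care_hours[calibrated.observed] > 0
        keep = calibrated.valid & baseline_cares[:, None]
    else:
        keep = calibrated.valid
    if not keep.any():
        raise ValueError("no carers to average the compensation over")
    w = weights * keep
    return float((w * gain).sum() / w.sum())


def bootstrap_ci(
    result: EstimationResult,
    data: pd.DataFrame,
    choice_set: ChoiceSet,
    schedule: TaxSchedule,
    reform: ReformSpec,
    B: int = 500,
    level: float = 90.0,
    seed: int = 0,
    n_reps: int = 50,
    max_attempts: int = 1000,
    calibration_seed: int | None = None,
) -> dict:
    """Parametric-bootstrap confidence intervals for an outcome table.

    Draws ``B`` parameter vectors from N(theta_hat, Sigma_hat) (the
    covariance is eigenvalue-clipped to positive semi-definite if
    needed, with the clip count reported), re-runs calibration and the
    scenario for each draw with one fixed error seed, and reports the
    (100-level)/2 and (100+level)/2 percentiles per table cell.

    Returns ``{"lower": DataFrame, "upper": DataFrame, "draws": ndarray,
    "n_clipped_eigenvalues": int}``.
    """
    if B <= 1:
        raise ValueError("B must exceed 1")
    rng = np.random.default_rng(seed)
    if calibration_seed is None:
        calibration_seed = seed + 1
    evals, evecs = np.linalg.eigh(0.5 * (result.covariance + result.covariance.T))
    n_clipped = int((evals < 0).sum())
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    C_base = scenario_income_matrix(data, choice_set, schedule, None)
    tables = []
    for _ in range(B):
        theta_b = result.theta + root @ rng.standard_normal(len(result.theta))
        theta_b[-2:] = np.abs(theta_b[-2:])
        result_b = replace(
            result, theta=theta_b, params=UtilityParams.from_vector(theta_b))
        cal_b = calibrate(
            result_b, data, choice_set, C_base, n_reps=n_reps,
            max_attempts=max_attempts, seed=calibration_seed,
        )
        base_b = apply_scenario(cal_b, None, data, choice_set, schedule)
        scen_b = apply_scenario(cal_b, reform, data, choice_set, schedule)
        tables.append(
            aggregate_effects(base_b, scen_b, cal_b, data, choice_set))
    stacked = np.stack([t.to_numpy(dtype=float) for t in tables])
    alpha = (100.0 - level) / 2.0
    lower = np.percentile(stacked, alpha, axis=0)
    upper = np.percentile(stacked, 100.0 - alpha, axis=0)
    template = tables[0]
    return {
        "lower": pd.DataFrame(lower, index=template.index, columns=template.columns),
        "upper": pd.DataFrame(upper, index=template.index, columns=template.columns),
        "draws": stacked,
        "n_clipped_eigenvalues": n_clipped,
    }


def run_scenario_analysis(
    result: EstimationResult,
    data: pd.DataFrame,
    choice_set: ChoiceSet,
    schedule: TaxSchedule,
    reform: ReformSpec,
    n_reps: int = 50,
    max_attempts: int = 1000,
    seed: int = 0,
    bootstrap_draws: int = 0,
) -> dict:
    """Calibrate, simulate one scenario, aggregate, optionally bootstrap.

    For the fixed-benefit reform with a non-positive configured amount,
    the revenue-neutral benefit is computed from reform A first.
    Returns the point-estimate table, the resolved reform, the
    calibrated retained share, and (if requested) CI tables.
    """
    C_base = scenario_income_matrix(data, choice_set, schedule, None)
    calibrated = calibrate(
        result, data, choice_set, C_base,
        n_reps=n_reps, max_attempts=max_attempts, seed=seed,
    )
    if reform.kind == "fixed_benefit" and reform.fixed_benefit_amount <= 0:
        amount = revenue_neutral_benefit(calibrated, data, choice_set, schedule)
        reform = ReformSpec(kind="fixed_benefit", fixed_benefit_amount=amount)
    baseline = apply_scenario(calibrated, None, data, choice_set, schedule)
    scenario = apply_scenario(calibrated, reform, data, choice_set, schedule)
    table = aggregate_effects(baseline, scenario, calibrated, data, choice_set)
    out = {
        "table": table,
        "reform": reform,
        "retained_share": calibrated.retained_share,
        "calibrated": calibrated,
    }
    if bootstrap_draws > 1:
        out["ci"] = bootstrap_ci(
            result, data, choice_set, schedule, reform,
            B=bootstrap_draws, seed=seed + 100, n_reps=n_reps,
            max_attempts=max_attempts,
        )
    return out
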