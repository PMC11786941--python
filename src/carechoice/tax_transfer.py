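"""Stylized tax-and-transfer schedule mapping gross to net household income.

The behavioral model values each alternative by the net household income
it yields, ``C_ij = t(w_i * hw_j + I_i)``.  The full national
tax-and-transfer microsimulation behind the original analysis is out of
scope here; this module provides a configurable stylized stand-in: a
piecewise-linear progressive income tax above a basic allowance, a flat
social contribution on gross labor income, and a transfer floor
(guaranteed minimum net income).

All money amounts are euros per month.  Weekly hours are converted to
monthly with a fixed factor of 4.345 weeks per month.

Two hypothetical reforms are supported when building income matrices:

* **wage compensation** (reform A): every informal care hour is paid at
  the individual's own gross hourly wage and taxed as labor income, so
  gross labor income at alternative j becomes ``w_i * (hw_j + hc_j)``;
* **fixed benefit** (reform B): a single net amount ``B`` is added to
  household income at every alternative with positive care hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .choice_set import ChoiceSet

#: Average number of weeks per month used to convert weekly hours.
WEEKS_PER_MONTH = 4.345

#: Long-term care insurance cash benefits by care level (euros/month,
#: 2019 values), kept as documented constants only; the stylized default
#: schedule does not use them.
LTCI_CASH_BENEFITS = {2: 316.0, 3: 545.0, 4: 728.0, 5: 901.0}


@dataclass(frozen=True)
class TaxSchedule:
    """Piecewise-linear tax schedule with contributions and a floor.

    ``brackets`` are (lower threshold, marginal rate) pairs applied to
    taxable income above the basic allowance; thresholds must start at 0
    and increase strictly.  ``social_contribution_rate`` applies to gross
    labor income only.  Net income never falls below ``transfer_floor``.
    """

    basic_allowance: float = 1000.0
    brackets: tuple[tuple[float, float], ...] = (
        (0.0, 0.15),
        (2000.0, 0.25),
        (4500.0, 0.35),
    )
    social_contribution_rate: float = 0.20
    transfer_floor: float = 900.0
    #: If True, care compensation is taxed as labor income (reform A);
    #: if False it would be added net of tax.  The default follows the
    #: "treated as additional labor income" definition.
    tax_care_compensation: bool = True

    def __post_init__(self):
        thresholds = [b[0] for b in self.brackets]
        rates = [b[1] for b in self.brackets]
        if thresholds[0] != 0.0:
            raise ValueError("first bracket threshold must be 0")
        if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
            raise ValueError("bracket thresholds must increase strictly")
        if any(not (0.0 <= r < 1.0) for r in rates):
            raise ValueError("marginal rates must lie in [0, 1)")
        if not (0.0 <= self.social_contribution_rate < 1.0):
            raise ValueError("social contribution rate must lie in [0, 1)")
        if self.transfer_floor < 0 or self.basic_allowance < 0:
            raise ValueError("allowance and floor must be non-negative")

    def tax(self, taxable: np.ndarray | float) -> np.ndarray | float:
        """Piecewise-linear tax on income above the basic allowance."""
        base = np.maximum(np.asarray(taxable, dtype=float) - self.basic_allowance, 0.0)
        thresholds = np.array([b[0] for b in self.brackets])
        rates = np.array([b[1] for b in self.brackets])
        uppers = np.append(thresholds[1:], np.inf)
        # tax in each bracket: rate * clip(base - lo, 0, hi - lo)
        inside = np.clip(base[..., None] - thresholds, 0.0, uppers - thresholds)
        return inside @ rates


@dataclass(frozen=True)
class ReformSpec:
    """Counterfactual scenario: exactly one kind is active.

    kinds: ``wage_change`` (scale all gross hourly wages by
    ``wage_change_pct`` percent), ``wage_compensation`` (reform A),
    ``fixed_benefit`` (reform B with amount ``fixed_benefit_amount``).
    """

    kind: str = "wage_change"
    wage_change_pct: float = 0.0
    fixed_benefit_amount: float = 0.0

    def __post_init__(self):
        if self.kind not in {"wage_change", "wage_compensation", "fixed_benefit"}:
            raise ValueError(f"unknown reform kind: {self.kind!r}")


def net_income(
    gross_labor: float | np.ndarray,
    other_income: float | np.ndarray,
    schedule: TaxSchedule,
) -> float | np.ndarray:
    """Net monthly household income under the stylized schedule.

    ``net = max(floor, gross_total - contributions - tax(gross_total))``
    with contributions levied on labor income only.  Continuous and
    non-decreasing in both income arguments.
    """
    gross_labor = np.asarray(gross_labor, dtype=float)
    other_income = np.asarray(other_income, dtype=float)
    if np.any(gross_labor < 0) or np.any(other_income < 0):
        raise ValueError("incomes must be non-negative")
    gross_total = gross_labor + other_income
    contributions = schedule.social_contribution_rate * gross_labor
    net = gross_total - contributions - schedule.tax(gross_total)
    out = np.maximum(net, schedule.transfer_floor)
    return out if out.ndim else float(out)


def income_matrix(
    wage: float | np.ndarray,
    other_income: float | np.ndarray,
    choice_set: ChoiceSet,
    schedule: TaxSchedule,
    reform: Optional[ReformSpec] = None,
) -> np.ndarray:
    """Net household income at every alternative, shape (n, J).

    ``wage`` and ``other_income`` may be scalars (one individual) or
    1-d arrays.  Baseline monthly gross labor income at alternative j is
    ``w_i * hw_j * 4.345``; reforms modify it as documented in the
    module docstring.  Wages must be present (no NaN) — impute first.
    """
    wage = np.atleast_1d(np.asarray(wage, dtype=float))
    other = np.atleast_1d(np.asarray(other_income, dtype=float))
    if np.any(np.isnan(wage)):
        raise ValueError("missing wages: impute before building income matrices")
    hw = choice_set.work_hours
    hc = choice_set.care_hours
    if reform is not None and reform.kind == "wage_change":
        wage = wage * (1.0 + reform.wage_change_pct / 100.0)
    paid_hours = hw[None, :]
    if reform is not None and reform.kind == "wage_compensation":
        paid_hours = (hw + hc)[None, :]
    gross_labor = wage[:, None] * paid_hours * WEEKS_PER_MONTH
    C = net_income(gross_labor, other[:, None], schedule)
    if reform is not None and reform.kind == "fixed_benefit":
        C = C + reform.fixed_benefit_amount * (hc > 0)[None, :]
    return C
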