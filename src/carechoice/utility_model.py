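"""Quadratic random-utility model of joint work and care choices.

The deterministic utility an individual i derives from alternative j is
a quadratic form in net household income C, leisure l and care hours hc,
with observed-heterogeneity interactions and two random coefficients:

    V_ij = l_j * b_li + C_ij * b_ci + hc_j * b_hc
           + l_j^2 * b_l2 + C_ij^2 * b_c2
           + C_ij * l_j * b_cl
           + C_ij * east_i * b_c_east + C_ij * hh_gt2_i * b_c_hh
           + l_j * (female, age, age^2/100, children, adults, migration)_i . b
           + hc_j * (female, age, children)_i . b

where the income and leisure coefficients are random across individuals,
b_ci ~ N(beta_c, sd_c^2) and b_li ~ N(beta_l, sd_l^2), independent
normals, and all other coefficients are fixed.  An iid type-I
extreme-value error epsilon_ij completes the utility; this module
evaluates V only.

There are no alternative-specific constants: identification comes from
the variation of (C, l, hc) across the nine alternatives.  Age enters
interactions in years, with the quadratic as age^2/100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Ordered names of the 17 mean coefficients.  This is the model's
#: parameter schema; serialization validates strictly against it.
MEAN_PARAM_NAMES = (
    "income",            # beta_c, per euro/month
    "leisure",           # beta_l, per hour/week
    "care",              # beta_hc, per hour/week
    "income_x_leisure",
    "income_sq",
    "income_x_east",
    "income_x_hh_gt2",
    "leisure_sq",
    "leisure_x_female",
    "leisure_x_age",
    "leisure_x_age_sq",  # interacts with age^2 / 100
    "leisure_x_children",
    "leisure_x_adults",
    "leisure_x_migration",
    "care_x_female",
    "care_x_age",
    "care_x_children",
)

SD_PARAM_NAMES = ("sd_income", "sd_leisure")

PARAM_NAMES = MEAN_PARAM_NAMES + SD_PARAM_NAMES

#: Individual covariate columns the interactions consume.
COVARIATE_COLUMNS = (
    "female",
    "age",
    "east",
    "migration",
    "children_in_hh",
    "n_adults",
    "hh_gt2",
)


@dataclass(frozen=True)
class UtilityParams:
    """All coefficients of the quadratic utility (17 means + 2 SDs)."""

    income: float = 0.0
    leisure: float = 0.0
    care: float = 0.0
    income_x_leisure: float = 0.0
    income_sq: float = 0.0
    income_x_east: float = 0.0
    income_x_hh_gt2: float = 0.0
    leisure_sq: float = 0.0
    leisure_x_female: float = 0.0
    leisure_x_age: float = 0.0
    leisure_x_age_sq: float = 0.0
    leisure_x_children: float = 0.0
    leisure_x_adults: float = 0.0
    leisure_x_migration: float = 0.0
    care_x_female: float = 0.0
    care_x_age: float = 0.0
    care_x_children: float = 0.0
    sd_income: float = 0.0
    sd_leisure: float = 0.0

    def __post_init__(self):
        if self.sd_income < 0 or self.sd_leisure < 0:
            raise ValueError("random-coefficient standard deviations must be >= 0")

    def to_vector(self) -> np.ndarray:
        d = asdict(self)
        return np.array([d[name] for name in PARAM_NAMES])

    @classmethod
    def from_vector(cls, theta: Iterable[float]) -> "UtilityParams":
        theta = np.asarray(list(theta), dtype=float)
        if theta.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, theta)))

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "UtilityParams":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing parameter names: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class IndividualDraw:
    """Realized random coefficients (one individual, one draw)."""

    b_income: float
    b_leisure: float


def _covariates(X) -> dict:
    """Pull covariate values from a mapping, Series or object."""
    if isinstance(X, Mapping):
        return {c: float(X[c]) for c in COVARIATE_COLUMNS}
    if isinstance(X, pd.Series):
        return {c: float(X[c]) for c in COVARIATE_COLUMNS}
    return {c: float(getattr(X, c)) for c in COVARIATE_COLUMNS}


def mean_design_row(C, l, hc, X) -> np.ndarray:
    """Design row against MEAN_PARAM_NAMES, vectorized over C/l/hc.

    ``C``, ``l``, ``hc`` may be scalars or equal-shaped arrays; ``X`` is
    one individual's covariates.  Returns an array of shape
    ``(*broadcast_shape, 17)`` such that ``row @ theta_mean`` equals the
    mean-coefficient part of V.
    """
    x = _covariates(X)
    C, l, hc = np.broadcast_arrays(
        np.asarray(C, dtype=float), np.asarray(l, dtype=float),
        np.asarray(hc, dtype=float),
    )
    cols = [
        C,
        l,
        hc,
        C * l,
        C ** 2,
        C * x["east"],
        C * x["hh_gt2"],
        l ** 2,
        l * x["female"],
        l * x["age"],
        l * (x["age"] ** 2 / 100.0),
        l * x["children_in_hh"],
        l * x["n_adults"],
        l * x["migration"],
        hc * x["female"],
        hc * x["age"],
        hc * x["children_in_hh"],
    ]
    return np.stack(cols, axis=-1)


def utility(params: UtilityParams, draw: IndividualDraw, C, l, hc, X) -> np.ndarray:
    """Deterministic utility V for given coefficients and a draw.

    The random-coefficient realizations in ``draw`` replace the means
    ``beta_c`` and ``beta_l`` on the linear income and leisure terms;
    all other coefficients come from ``params``.
    """
    theta = params.to_vector()[: len(MEAN_PARAM_NAMES)].copy()
    theta[MEAN_PARAM_NAMES.index("income")] = draw.b_income
    theta[MEAN_PARAM_NAMES.index("leisure")] = draw.b_leisure
    row = mean_design_row(C, l, hc, X)
    out = row @ theta
    return out if np.ndim(out) else float(out)


def marginal_utilities(
    params: UtilityParams, draw: IndividualDraw, C, l, hc, X
) -> tuple:
    """Analytic first derivatives (dV/dC, dV/dl, dV/dhc).

    dV/dC = b_c + 2 b_c2 C + b_cl l + b_c_east east + b_c_hh hh_gt2
    dV/dl = b_l + 2 b_l2 l + b_cl C + interactions(X)
    dV/dhc = b_hc + interactions(X)   (independent of C and l: the
    specification has no care-by-income or care-by-leisure terms)
    """
    x = _covariates(X)
    C = np.asarray(C, dtype=float)
    l = np.asarray(l, dtype=float)
    dC = (
        draw.b_income
        + 2.0 * params.income_sq * C
        + params.income_x_leisure * l
        + params.income_x_east * x["east"]
        + params.income_x_hh_gt2 * x["hh_gt2"]
    )
    dl = (
        draw.b_leisure
        + 2.0 * params.leisure_sq * l
        + params.income_x_leisure * C
        + params.leisure_x_female * x["female"]
        + params.leisure_x_age * x["age"]
        + params.leisure_x_age_sq * (x["age"] ** 2 / 100.0)
        + params.leisure_x_children * x["children_in_hh"]
        + params.leisure_x_adults * x["n_adults"]
        + params.leisure_x_migration * x["migration"]
    )
    dhc = (
        params.care
        + params.care_x_female * x["female"]
        + params.care_x_age * x["age"]
        + params.care_x_children * x["children_in_hh"]
    ) * np.ones_like(C)
    return dC, dl, dhc


def positive_share_report(
    params: UtilityParams,
    draws: np.ndarray,
    population: pd.DataFrame,
    income_at_observed: np.ndarray,
    leisure_at_observed: np.ndarray,
    care_at_observed: np.ndarray,
    weights: np.ndarray | None = None,
) -> dict:
    """Weighted shares of individuals with positive marginal utilities.

    Evaluated at each individual's observed alternative, using the
    supplied per-individual coefficient realizations ``draws`` (shape
    (n, 2): income then leisure coefficient — typically posterior
    means).  A derivative of exactly zero does not count as positive
    (strict inequality).  Returns shares on the 0-1 scale for the
    income, leisure and care dimensions.
    """
    n = len(population)
    draws = np.asarray(draws, dtype=float)
    if draws.shape != (n, 2):
        raise ValueError("draws must have shape (n, 2)")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    pos = np.zeros((n, 3))
    for i in range(n):
        d = IndividualDraw(draws[i, 0], draws[i, 1])
        dC, dl, dhc = marginal_utilities(
            params, d,
            income_at_observed[i], leisure_at_observed[i],
            care_at_observed[i], population.iloc[i],
        )
        pos[i] = [dC > 0, dl > 0, dhc > 0]
    shares = (weights[:, None] * pos).sum(axis=0) / weights.sum()
    return {
        "income": float(shares[0]),
        "leisure": float(shares[1]),
        "care": float(shares[2]),
    }
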