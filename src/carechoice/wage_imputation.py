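"""Heckman two-step imputation of gross hourly wages for non-workers.

Net income at every work alternative requires an hourly wage for every
individual, but wages are only observed for workers, and employment is
plausibly selective.  The classic two-step correction is used:

1. a probit of wage observation (employment) on selection covariates,
   including at least one exclusion restriction that does not enter the
   wage equation (default: number of adults in the household);
2. least squares of log hourly wage on the wage covariates plus the
   inverse Mills ratio evaluated at the probit index.

Imputed wages are ``exp(x'b)`` from the corrected wage equation (no
smearing retransformation and no idiosyncratic draw by default).
Observed wages are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_SELECTION_COVARS = (
    "female", "age", "east", "migration", "children_in_hh", "n_adults",
)
DEFAULT_WAGE_COVARS = ("female", "age", "east", "migration")


def inverse_mills(z) -> np.ndarray | float:
    """Inverse Mills ratio phi(z)/Phi(z), numerically stable.

    Computed as exp(logpdf - logcdf) so the far-left tail (where both
    phi and Phi underflow) stays finite and follows the asymptote ~ -z.
    """
    z = np.asarray(z, dtype=float)
    out = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    return out if out.ndim else float(out)


@dataclass
class WageModel:
    """Fitted two-step selection model for log hourly wages."""

    selection_covars: tuple[str, ...]
    wage_covars: tuple[str, ...]
    selection_coefs: pd.Series
    wage_coefs: pd.Series           # includes "const" and "mills"
    mills_coef: float
    mills_se: float
    residual_scale: float           # RMSE of the log-wage step
    n_workers: int
    n_nonworkers: int

    def to_report(self) -> dict:
        return {
            "selection": {k: float(v) for k, v in self.selection_coefs.items()},
            "wage": {k: float(v) for k, v in self.wage_coefs.items()},
            "mills_coef": self.mills_coef,
            "mills_se": self.mills_se,
            "residual_scale": self.residual_scale,
            "n_workers": self.n_workers,
            "n_nonworkers": self.n_nonworkers,
        }


def fit_heckman(
    data: pd.DataFrame,
    selection_covars: Sequence[str] = DEFAULT_SELECTION_COVARS,
    wage_covars: Sequence[str] = DEFAULT_WAGE_COVARS,
    wage_col: str = "gross_wage",
) -> WageModel:
    """Two-step Heckman fit; employment = wage observed (non-missing).

    Requires variation in employment and an exclusion restriction (a
    selection covariate absent from the wage equation); raises if every
    individual is a worker or a non-worker.
    """
    employed = data[wage_col].notna().to_numpy()
    if employed.all() or not employed.any():
        raise ValueError("need both workers and non-workers to fit the selection step")
    if not set(selection_covars) - set(wage_covars):
        raise ValueError("no exclusion restriction: selection covariates "
                         "must include one not in the wage equation")

    Xs = sm.add_constant(data.loc[:, list(selection_covars)].astype(float))
    probit = sm.Probit(employed.astype(float), Xs).fit(disp=0)
    mills = inverse_mills(probit.fittedvalues)  # linear index x'gamma

    workers = data.loc[employed]
    Xw = sm.add_constant(workers.loc[:, list(wage_covars)].astype(float))
    Xw = Xw.assign(mills=mills[employed])
    logw = np.log(workers[wage_col].astype(float))
    ols = sm.OLS(logw, Xw).fit()

    return WageModel(
        selection_covars=tuple(selection_covars),
        wage_covars=tuple(wage_covars),
        selection_coefs=probit.params,
        wage_coefs=ols.params,
        mills_coef=float(ols.params["mills"]),
        mills_se=float(ols.bse["mills"]),
        residual_scale=float(np.sqrt(ols.mse_resid)),
        n_workers=int(employed.sum()),
        n_nonworkers=int((~employed).sum()),
    )


def impute_wages(
    model: WageModel,
    data: pd.DataFrame,
    wage_col: str = "gross_wage",
) -> pd.Series:
    """Fill missing wages with exp(x'b) from the corrected wage equation.

    The selection correction is used at the fitting stage only; the
    prediction is the exponentiated linear index over the wage
    covariates (Mills term excluded, as the counterfactual wage offer is
    wanted, not the wage conditional on working).  Observed wages pass
    through untouched; every output is strictly positive.
    """
    missing = data[wage_col].isna()
    out = data[wage_col].astype(float).copy()
    if missing.any():
        X = data.loc[missing, list(model.wage_covars)].astype(float)
        beta = model.wage_coefs.drop("mills")
        linpred = beta["const"] + X.to_numpy() @ beta.drop("const").to_numpy()
        out.loc[missing] = np.exp(linpred)
    return out
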