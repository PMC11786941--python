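import os

# cap BLAS pools before numpy loads: the linear algebra here is many
# small operations, where extra threads only add contention
for _v in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pandas as pd
import pytest

from carechoice import (
    GeneratorConfig,
    TaxSchedule,
    UtilityParams,
    build_choice_set,
    generate_population,
    simulate_choices,
)

#: Schedule with no taxes, contributions or floor: net income = gross.
ZERO_TAX = TaxSchedule(
    basic_allowance=0.0, brackets=((0.0, 0.0),),
    social_contribution_rate=0.0, transfer_floor=0.0,
)


@pytest.fixture(scope="session")
def choice_set():
    return build_choice_set()


@pytest.fixture(scope="session")
def schedule():
    return TaxSchedule()


@pytest.fixture(scope="session")
def zero_tax():
    return ZERO_TAX


@pytest.fixture(scope="session")
def one_person():
    """A single individual's covariates, as a Series."""
    return pd.Series(
        {
            "id": 0, "female": 1, "age": 52.0, "east": 0, "migration": 0,
            "children_in_hh": 1, "n_adults": 2, "hh_gt2": 1,
            "gross_wage": 18.0, "other_income": 2500.0,
            "observed_alt": 4, "weight": 1.0,
        }
    )


def make_result(params: UtilityParams, R: int = 50, covariance=None):
    """EstimationResult wrapper around known coefficients (no fitting).

    Lets calibration/counterfactual tests run at the generator's true
    parameters, isolating them from estimation error.
    """
    from carechoice import EstimationResult

    theta = params.to_vector()
    return EstimationResult(
        params=params, theta=theta,
        covariance=np.zeros((19, 19)) if covariance is None else covariance,
        se=np.zeros(19), loglik=0.0, aic=0.0, n_obs=0, R=R, burn=10,
        converged=True, n_starts=1, message="constructed from known truth",
    )


@pytest.fixture(scope="session")
def small_data(choice_set, schedule):
    """800 individuals with complete wages and simulated choices."""
    cfg = GeneratorConfig(n=800, seed=101)
    pop = generate_population(cfg)
    return simulate_choices(pop, cfg.true_params, choice_set, schedule, seed=102)
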