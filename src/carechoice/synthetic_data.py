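"""Synthetic populations of potential carers with known true preferences.

The restricted survey microdata behind the original analysis cannot be
shipped, so every downstream stage is exercised on generated data whose
ground truth is known.  The generator emulates a cross-section of
potential carers (people facing a caregiving decision): demographic
margins near the survey descriptives (about half female, mean age in the
early fifties, roughly 4000 euros/month net household income), gender-
gapped log-normal hourly wages (means near 17.6 / 19.8 euros for women /
men), wage missingness for non-workers driven by a probit-style latent
rule correlated with the wage equation (so the selection correction has
a real structure to detect), and observed joint work/care choices
simulated from the package's own random-utility model at configurable
true parameters.

The default true utility parameters follow the published signs and
rough magnitudes (positive income and leisure means, negative
quadratics, positive care-by-female); they seed plausible simulations
and are not estimates of anything.

Panel structure, attrition and survey-weight construction are not
emulated; weights default to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .choice_set import ChoiceSet, build_choice_set
from .tax_transfer import TaxSchedule, income_matrix
from .utility_model import UtilityParams

#: Default true preference parameters (published signs and magnitudes).
DEFAULT_TRUE_PARAMS = UtilityParams(
    income=0.002,
    leisure=0.932,
    care=0.004,
    income_x_leisure=2.0e-6,
    income_sq=-1.0e-7,
    income_x_east=0.001,
    income_x_hh_gt2=0.0002,
    leisure_sq=-0.004,
    leisure_x_female=0.074,
    leisure_x_age=-0.019,
    leisure_x_age_sq=0.022,
    leisure_x_children=0.063,
    leisure_x_adults=0.005,
    leisure_x_migration=0.046,
    care_x_female=0.105,
    care_x_age=-0.005,
    care_x_children=0.036,
    sd_income=0.001,
    sd_leisure=0.136,
)

#: Canonical column order of the individual-level table.
DATA_COLUMNS = (
    "id", "female", "age", "east", "migration", "children_in_hh",
    "n_adults", "hh_gt2", "gross_wage", "other_income", "observed_alt",
    "weight",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic population, with survey-like defaults."""

    n: int = 2000
    seed: int = 0
    share_female: float = 0.50
    share_east: float = 0.20
    share_migration: float = 0.25
    share_children: float = 0.19
    age_mean: float = 51.5
    age_sd: float = 11.0
    age_min: float = 18.0
    age_max: float = 65.0
    #: log hourly wage: male intercept, female gap, per-decade age slope
    log_wage_male: float = 2.90
    log_wage_female_gap: float = -0.15
    log_wage_age_slope: float = 0.05
    log_wage_sd: float = 0.40
    #: employment probit: intercept, female, per-decade age, per extra adult
    sel_const: float = 1.10
    sel_female: float = -0.20
    sel_age: float = -0.20
    sel_adults: float = 0.30
    #: correlation of the wage residual with the selection latent
    selection_corr: float = 0.5
    other_income_shape: float = 2.0
    other_income_scale: float = 1400.0
    true_params: UtilityParams = DEFAULT_TRUE_PARAMS

    def __post_init__(self):
        for name in ("share_female", "share_east", "share_migration",
                     "share_children"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not (-1.0 <= self.selection_corr <= 1.0):
            raise ValueError("selection correlation outside [-1, 1]")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["true_params"] = self.true_params.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["true_params"] = UtilityParams.from_dict(d["true_params"])
        return cls(**d)


def generate_population(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a population of potential carers (wages complete).

    Returns a DataFrame with the canonical columns plus two generator-
    internal columns: ``employed`` (the probit-driven wage-observation
    flag) and ``gross_wage`` still filled for everyone so that choices
    can be simulated from ground truth.  Apply
    :func:`mask_nonworker_wages` to obtain the analysis-ready table with
    missing wages for non-workers.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n
    female = (rng.random(n) < config.share_female).astype(int)
    east = (rng.random(n) < config.share_east).astype(int)
    migration = (rng.random(n) < config.share_migration).astype(int)
    children = (rng.random(n) < config.share_children).astype(int)
    # truncated-normal age via rejection (cheap at these bounds)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    bad = (age < config.age_min) | (age > config.age_max)
    while bad.any():
        age[bad] = rng.normal(config.age_mean, config.age_sd, size=int(bad.sum()))
        bad = (age < config.age_min) | (age > config.age_max)
    n_adults = 1 + rng.binomial(2, 0.5, size=n)
    hh_gt2 = ((n_adults >= 3) | ((n_adults == 2) & (children == 1))).astype(int)

    # wage equation and correlated selection latent
    rho = config.selection_corr
    u = rng.standard_normal(n)             # standardized wage residual
    v = rho * u + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(n)
    log_wage = (
        config.log_wage_male
        + config.log_wage_female_gap * female
        + config.log_wage_age_slope * (age - config.age_mean) / 10.0
        + config.log_wage_sd * u
    )
    latent = (
        config.sel_const
        + config.sel_female * female
        + config.sel_age * (age - config.age_mean) / 10.0
        + config.sel_adults * (n_adults - 2)
        + v
    )
    employed = (latent > 0).astype(int)
    other_income = rng.gamma(config.other_income_shape,
                             config.other_income_scale, size=n)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "female": female,
            "age": age,
            "east": east,
            "migration": migration,
            "children_in_hh": children,
            "n_adults": n_adults,
            "hh_gt2": hh_gt2,
            "gross_wage": np.exp(log_wage),
            "other_income": other_income,
            "observed_alt": -1,
            "weight": 1.0,
            "employed": employed,
        }
    )


def simulate_choices(
    population: pd.DataFrame,
    params: UtilityParams,
    choice_set: ChoiceSet,
    tax_schedule: TaxSchedule,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill ``observed_alt`` by forward-simulating the utility model.

    For each individual the random coefficients are drawn from their
    normals and an iid type-I extreme-value error is added per
    alternative; the observed choice is the utility argmax.  Wages must
    be complete.  Returns a copy; deterministic under the seed.
    """
    from .estimation import build_mean_design  # local import: no cycle at module load

    rng = np.random.default_rng(seed)
    data = population.copy()
    n = len(data)
    if n == 0:
        return data
    C = income_matrix(
        data["gross_wage"].to_numpy(dtype=float),
        data["other_income"].to_numpy(dtype=float),
        choice_set, tax_schedule,
    )
    A = build_mean_design(data, choice_set, C)
    theta = params.to_vector()
    b_c = params.income + params.sd_income * rng.standard_normal(n)
    b_l = params.leisure + params.sd_leisure * rng.standard_normal(n)
    theta_mean = theta[:17].copy()
    theta_mean[0] = 0.0   # income and leisure linear terms enter via draws
    theta_mean[1] = 0.0
    V = A @ theta_mean + b_c[:, None] * C + b_l[:, None] * choice_set.leisure_hours
    eps = rng.gumbel(size=V.shape)
    data["observed_alt"] = np.argmax(V + eps, axis=1)
    return data


def mask_nonworker_wages(population: pd.DataFrame) -> pd.DataFrame:
    """Analysis-ready table: wages of non-workers set to missing.

    Emulates that hourly wages are only observed for workers; the
    ``employed`` helper column is kept so tests can compare against the
    generator's truth.
    """
    data = population.copy()
    data.loc[data["employed"] == 0, "gross_wage"] = np.nan
    return data


def generate_dataset(
    config: GeneratorConfig,
    choice_set: ChoiceSet | None = None,
    tax_schedule: TaxSchedule | None = None,
) -> pd.DataFrame:
    """Generate, simulate choices from truth, then mask non-worker wages.

    Convenience wrapper producing the analysis-ready table in one call;
    choice simulation uses a seed derived from the config seed.
    """
    cs = choice_set or build_choice_set()
    schedule = tax_schedule or TaxSchedule()
    pop = generate_population(config)
    pop = simulate_choices(pop, config.true_params, cs, schedule,
                           seed=config.seed + 1)
    return mask_nonworker_wages(pop)


def write_dataset(data: pd.DataFrame, path) -> None:
    """Write the individual-level table as CSV (canonical column order)."""
    cols = [c for c in DATA_COLUMNS if c in data.columns]
    extra = [c for c in data.columns if c not in cols]
    data.loc[:, cols + extra].to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path)
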