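"""Conditional calibration of error terms for deterministic counterfactuals.

Counterfactuals are evaluated holding each individual's preferences
*and* random utility component fixed.  For that, every individual needs
coefficient realizations (b_c, b_l) and an extreme-value error vector
epsilon over the alternatives that together reproduce the observed
baseline choice:

    argmax_j [ V_ij(b_i) + eps_ij ] = observed alternative.

Coefficients are drawn from the estimation draw set proportionally to
the conditional likelihood L_i(beta_r) (consistent with the posterior
individual-level parameters); epsilon is then drawn by accept-reject
over iid standard Gumbel vectors.  Replicates for which no consistent
epsilon is found within ``max_attempts`` are flagged invalid and
excluded from outcome aggregation, and outcome tables always report the
retained share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .choice_set import ChoiceSet
from .estimation import EstimationResult, N_MEAN, halton_draws, logit_prob
from .utility_model import MEAN_PARAM_NAMES

_IDX_INCOME = MEAN_PARAM_NAMES.index("income")
_IDX_LEISURE = MEAN_PARAM_NAMES.index("leisure")


@dataclass
class CalibratedState:
    """Per-individual, per-replicate frozen preferences and errors."""

    b_income: np.ndarray      # (n, reps)
    b_leisure: np.ndarray     # (n, reps)
    eps: np.ndarray           # (n, reps, J)
    valid: np.ndarray         # (n, reps) bool
    observed: np.ndarray      # (n,)
    theta: np.ndarray         # parameter vector used (19,)
    seed: int

    @property
    def n_reps(self) -> int:
        return self.b_income.shape[1]

    @property
    def retained_individuals(self) -> np.ndarray:
        """Individuals with at least one valid replicate."""
        return self.valid.any(axis=1)

    @property
    def retained_share(self) -> float:
        """Unweighted share of valid (individual, replicate) cells."""
        return float(self.valid.mean())

    def to_frame(self) -> pd.DataFrame:
        """Flat table (one row per individual x replicate) for caching."""
        n, reps, J = self.eps.shape
        i, r = np.meshgrid(np.arange(n), np.arange(reps), indexing="ij")
        df = pd.DataFrame(
            {
                "individual": i.ravel(),
                "rep": r.ravel(),
                "b_income": self.b_income.ravel(),
                "b_leisure": self.b_leisure.ravel(),
                "valid": self.valid.ravel(),
            }
        )
        for j in range(J):
            df[f"eps_{j}"] = self.eps[:, :, j].ravel()
        return df


def state_utilities(
    state_theta: np.ndarray,
    b_income: np.ndarray,
    b_leisure: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    leisure_hours: np.ndarray,
) -> np.ndarray:
    """Deterministic utilities (n, reps, J) at frozen coefficient draws.

    The linear income and leisure terms use the per-replicate draws; all
    other coefficients come from the mean vector.
    """
    theta_mean = state_theta[:N_MEAN].copy()
    theta_mean[_IDX_INCOME] = 0.0
    theta_mean[_IDX_LEISURE] = 0.0
    base = A @ theta_mean                                    # (n, J)
    return (
        base[:, None, :]
        + b_income[:, :, None] * C[:, None, :]
        + b_leisure[:, :, None] * leisure_hours[None, None, :]
    )


def calibrate(
    result: EstimationResult,
    data: pd.DataFrame,
    choice_set: ChoiceSet,
    C: np.ndarray,
    n_reps: int = 50,
    max_attempts: int = 1000,
    seed: int = 0,
    mode: str = "posterior",
) -> CalibratedState:
    """Build a calibrated state reproducing every observed baseline choice.

    ``mode='posterior'`` (default) samples each individual's coefficient
    replicates from the estimation Halton draws with probabilities
    proportional to the conditional likelihood of the observed choice;
    ``mode='population'`` draws fresh coefficients from the estimated
    population normals, ignoring the observed choice.

    Accept-reject caps at ``max_attempts`` Gumbel vectors per replicate;
    exhausted replicates are flagged invalid, never fatal.
    """
    from .estimation import build_mean_design

    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if mode not in {"posterior", "population"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(data)
    J = len(choice_set)
    theta = result.theta
    A = build_mean_design(data, choice_set, C)
    chosen = data["observed_alt"].to_numpy(dtype=int)
    sd_c, sd_l = theta[N_MEAN], theta[N_MEAN + 1]

    if mode == "population":
        b_c = theta[_IDX_INCOME] + sd_c * rng.standard_normal((n, n_reps))
        b_l = theta[_IDX_LEISURE] + sd_l * rng.standard_normal((n, n_reps))
    else:
        z = halton_draws(n, result.R, burn=result.burn)
        V = state_utilities(
            theta,
            theta[_IDX_INCOME] + sd_c * z[:, :, 0],
            theta[_IDX_LEISURE] + sd_l * z[:, :, 1],
            A, C, choice_set.leisure_hours,
        )
        Pk = logit_prob(V)[np.arange(n), :, chosen]      # (n, R)
        w = Pk / Pk.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        u = rng.random((n, n_reps))
        idx = np.minimum((u[:, :, None] > cum[:, None, :]).sum(axis=2),
                         result.R - 1)
        rows = np.arange(n)[:, None]
        b_c = theta[_IDX_INCOME] + sd_c * z[:, :, 0][rows, idx]
        b_l = theta[_IDX_LEISURE] + sd_l * z[:, :, 1][rows, idx]

    V = state_utilities(theta, b_c, b_l, A, C, choice_set.leisure_hours)
    eps = np.zeros((n, n_reps, J))
    valid = np.zeros((n, n_reps), dtype=bool)
    target = np.broadcast_to(chosen[:, None], (n, n_reps))
    pending = ~valid
    attempts = 0
    while pending.any() and attempts < max_attempts:
        ii, rr = np.where(pending)
        trial = rng.gumbel(size=(len(ii), J))
        ok = np.argmax(V[ii, rr] + trial, axis=1) == target[ii, rr]
        eps[ii[ok], rr[ok]] = trial[ok]
        valid[ii[ok], rr[ok]] = True
        pending = ~valid
        attempts += 1
    return CalibratedState(
        b_income=b_c,
        b_leisure=b_l,
        eps=eps,
        valid=valid,
        observed=chosen,
        theta=theta.copy(),
        seed=seed,
    )
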