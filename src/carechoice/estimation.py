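"""Mixed-logit estimation by maximum simulated likelihood.

The choice probability of alternative k for individual i is the mixture

    P_ik = E_beta[ exp(V_ik(beta)) / sum_j exp(V_ij(beta)) ]

over the two independent normal random coefficients (income, leisure).
The integral is simulated as an average over R quasi-random draws from a
two-dimensional Halton sequence (bases 2 and 3, burn-in discarded,
inverse-normal transformed; each individual takes a consecutive block of
R points from one long sequence).  The simulated log-likelihood

    SLL(theta) = sum_i log( (1/R) sum_r L_ik(beta_ir) )

is maximized by BHHH quasi-Newton steps (the outer product of the
analytic individual scores as information matrix, with backtracking
line search), warm-started from the conditional-logit fit.  The
random-coefficient standard deviations are estimated unconstrained; the
absolute value is applied at reporting.  Standard errors come from the
H^{-1} B H^{-1} sandwich with B the outer product of individual scores
and H a finite-difference Hessian of the analytic gradient.

Internally all design columns are rescaled to unit root-mean-square
(raw scales — income in thousands of euros against leisure near 100
hours — are badly conditioned); every reported coefficient is
transformed back to the natural per-euro / per-hour units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .choice_set import ChoiceSet
from .tax_transfer import TaxSchedule, income_matrix
from .utility_model import (
    MEAN_PARAM_NAMES,
    PARAM_NAMES,
    SD_PARAM_NAMES,
    UtilityParams,
)

N_MEAN = len(MEAN_PARAM_NAMES)
N_PARAMS = len(PARAM_NAMES)
_IDX_INCOME = MEAN_PARAM_NAMES.index("income")
_IDX_LEISURE = MEAN_PARAM_NAMES.index("leisure")


# --------------------------------------------------------------------------
# Halton draws
# --------------------------------------------------------------------------

def _radical_inverse(indices: np.ndarray, base: int) -> np.ndarray:
    """Van der Corput radical inverse of integer indices in a prime base."""
    indices = np.asarray(indices, dtype=np.int64)
    out = np.zeros(indices.shape, dtype=float)
    f = 1.0 / base
    i = indices.copy()
    while np.any(i > 0):
        out += f * (i % base)
        i //= base
        f /= base
    return out


def halton_sequence(n_points: int, primes=(2, 3), burn: int = 0) -> np.ndarray:
    """Points of the multidimensional Halton sequence, shape (n, d).

    The sequence starts at index 1 (base-2 coordinate 1/2, 1/4, 3/4, ...);
    the first ``burn`` points are discarded.
    """
    if len(set(primes)) != len(primes):
        raise ValueError("prime bases must be distinct")
    idx = np.arange(1 + burn, 1 + burn + n_points)
    return np.column_stack([_radical_inverse(idx, int(p)) for p in primes])


def halton_draws(
    n_individuals: int, R: int, dims: int = 2, primes=(2, 3), burn: int = 10
) -> np.ndarray:
    """Standard-normal Halton draws, shape (n_individuals, R, dims).

    Deterministic given the settings.  Individual i receives the
    consecutive block [i*R, (i+1)*R) of the burned sequence, pushed
    through the inverse normal CDF.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if len(primes) != dims:
        raise ValueError("need one prime base per dimension")
    u = halton_sequence(n_individuals * R, primes=primes, burn=burn)
    z = stats.norm.ppf(u)
    return z.reshape(n_individuals, R, dims)


# --------------------------------------------------------------------------
# Probabilities and likelihood
# --------------------------------------------------------------------------

def logit_prob(V: np.ndarray) -> np.ndarray:
    """Conditional-logit probabilities along the last axis.

    Max-shifted exponentials for numerical stability; invariant to
    adding a constant to all utilities.
    """
    V = np.asarray(V, dtype=float)
    shifted = V - V.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def build_mean_design(
    data: pd.DataFrame, choice_set: ChoiceSet, C: np.ndarray
) -> np.ndarray:
    """Design tensor (n, J, 17) against MEAN_PARAM_NAMES.

    ``C`` is the (n, J) net-income matrix; alternative attributes come
    from the choice set and covariates from ``data`` columns.
    """
    n = len(data)
    l = choice_set.leisure_hours
    hc = choice_set.care_hours
    J = len(choice_set)
    if C.shape != (n, J):
        raise ValueError("income matrix shape mismatch")
    col = lambda name: data[name].to_numpy(dtype=float)[:, None]
    lB = np.broadcast_to(l, (n, J))
    hcB = np.broadcast_to(hc, (n, J))
    A = np.empty((n, J, N_MEAN))
    A[:, :, 0] = C
    A[:, :, 1] = lB
    A[:, :, 2] = hcB
    A[:, :, 3] = C * lB
    A[:, :, 4] = C ** 2
    A[:, :, 5] = C * col("east")
    A[:, :, 6] = C * col("hh_gt2")
    A[:, :, 7] = lB ** 2
    A[:, :, 8] = lB * col("female")
    A[:, :, 9] = lB * col("age")
    A[:, :, 10] = lB * (col("age") ** 2 / 100.0)
    A[:, :, 11] = lB * col("children_in_hh")
    A[:, :, 12] = lB * col("n_adults")
    A[:, :, 13] = lB * col("migration")
    A[:, :, 14] = hcB * col("female")
    A[:, :, 15] = hcB * col("age")
    A[:, :, 16] = hcB * col("children_in_hh")
    return A


def _utilities(theta: np.ndarray, A: np.ndarray, C: np.ndarray,
               l_row: np.ndarray, z: np.ndarray) -> np.ndarray:
    """V tensor (n, R, J) for a full parameter vector theta (19,)."""
    mean_part = A @ theta[:N_MEAN]                      # (n, J)
    sd_c, sd_l = theta[N_MEAN], theta[N_MEAN + 1]
    V = mean_part[:, None, :] \
        + sd_c * z[:, :, 0][:, :, None] * C[:, None, :] \
        + sd_l * z[:, :, 1][:, :, None] * l_row[None, None, :]
    return V


def _scores(theta, A, C, l_row, z, chosen):
    """Per-individual log-likelihood scores and values.

    Returns (sll, scores) where scores has shape (n, 19).  The gradient
    of log L_i follows from d P_ikr / d theta = P_ikr (x_ikr - sum_j
    P_ijr x_ijr) with the draw-specific columns handled separately.
    """
    n, J, _ = A.shape
    R = z.shape[1]
    V = _utilities(theta, A, C, l_row, z)
    P = logit_prob(V)                                    # (n, R, J)
    ar = np.arange(n)
    Pk = P[ar, :, chosen]                                # (n, R)
    L = Pk.mean(axis=1)
    L = np.maximum(L, 1e-300)
    sll = float(np.log(L).sum())

    inv = 1.0 / (R * L)                                  # (n,)
    # mean-coefficient block
    s_tot = Pk.sum(axis=1)                               # (n,)
    s_j = np.einsum("nr,nrj->nj", Pk, P)                 # (n, J)
    Ak = A[ar, chosen, :]                                # (n, 17)
    g_mean = inv[:, None] * (s_tot[:, None] * Ak - np.einsum("nj,njk->nk", s_j, A))
    # sd blocks: dV/dsd = z_dim * attr
    scores = np.empty((n, N_PARAMS))
    scores[:, :N_MEAN] = g_mean
    for d, attr in ((0, C), (1, np.broadcast_to(l_row, (n, J)))):
        u = Pk * z[:, :, d]                              # (n, R)
        m = np.einsum("nrj,nj->nr", P, attr)             # (n, R)
        ak = attr[ar, chosen]                            # (n,)
        scores[:, N_MEAN + d] = inv * (ak * u.sum(axis=1) - (u * m).sum(axis=1))
    return sll, scores


def simulated_prob(
    params: UtilityParams,
    individual,
    choice_set: ChoiceSet,
    income_row: np.ndarray,
    draws: np.ndarray,
) -> np.ndarray:
    """Simulated mixed-logit probability vector for one individual.

    ``income_row`` has shape (J,); ``draws`` is (R, 2) standard normals
    for the (income, leisure) random coefficients.  With both SDs zero
    this equals the conditional-logit probability exactly for any R.
    """
    data = pd.DataFrame([dict(individual)]) if not isinstance(individual, pd.DataFrame) \
        else individual
    C = np.asarray(income_row, dtype=float)[None, :]
    A = build_mean_design(data, choice_set, C)
    z = np.asarray(draws, dtype=float)[None, :, :]
    V = _utilities(params.to_vector(), A, C, choice_set.leisure_hours, z)
    return logit_prob(V)[0].mean(axis=0)


def simulated_loglik(
    params: UtilityParams,
    data: pd.DataFrame,
    choice_set: ChoiceSet,
    C: np.ndarray,
    draws: np.ndarray,
) -> float:
    """Simulated log-likelihood of observed choices (``observed_alt``)."""
    A = build_mean_design(data, choice_set, C)
    chosen = data["observed_alt"].to_numpy(dtype=int)
    sll, _ = _scores(
        params.to_vector(), A, C, choice_set.leisure_hours,
        np.asarray(draws, dtype=float), chosen,
    )
    return sll


# --------------------------------------------------------------------------
# Estimation
# --------------------------------------------------------------------------

@dataclass
class EstimationResult:
    """Fitted mixed logit: coefficients, covariance and diagnostics."""

    params: UtilityParams
    theta: np.ndarray
    covariance: np.ndarray
    se: np.ndarray
    loglik: float
    aic: float
    n_obs: int
    R: int
    burn: int
    converged: bool
    n_starts: int
    message: str

    @property
    def k(self) -> int:
        return len(self.theta)

    def summary(self) -> pd.DataFrame:
        """Coefficient table (estimate, SE, z, significance stars)."""
        se = np.where(self.se > 0, self.se, np.nan)
        zval = self.theta / se
        pval = 2 * stats.norm.sf(np.abs(zval))
        stars = np.select(
            [pval < 0.01, pval < 0.05, pval < 0.10], ["***", "**", "*"], ""
        )
        return pd.DataFrame(
            {
                "coef": self.theta,
                "se": self.se,
                "z": zval,
                "p": pval,
                "stars": stars,
            },
            index=list(PARAM_NAMES),
        )

    def to_report(self) -> dict:
        """JSON-style report: named coefficients, SEs, fit statistics."""
        return {
            "coefficients": dict(zip(PARAM_NAMES, map(float, self.theta))),
            "standard_errors": dict(zip(PARAM_NAMES, map(float, self.se))),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_draws": self.R,
            "converged": self.converged,
            "covariance": self.covariance.tolist(),
        }


def _bhhh_maximize(score_fn, x0, maxiter=200, gtol=1e-5, ftol=1e-9):
    """Maximize a sum-of-scores likelihood by BHHH with backtracking.

    ``score_fn(x)`` returns (sll, per-individual scores).  Convergence:
    max |gradient| below ``gtol``, or relative SLL change below ``ftol``
    with a loose gradient norm.  Returns (x, sll, converged, message).
    """
    x = np.asarray(x0, dtype=float).copy()
    sll, sc = score_fn(x)
    k = len(x)
    flat = 0
    for _ in range(maxiter):
        g = sc.sum(axis=0)
        if np.abs(g).max() < gtol:
            return x, sll, True, "gradient norm below tolerance"
        B = sc.T @ sc
        d = np.linalg.solve(B + 1e-8 * np.eye(k), g)
        t, improved = 1.0, False
        while t > 1e-10:
            sll_new, sc_new = score_fn(x + t * d)
            if sll_new > sll + 1e-4 * t * (g @ d):
                improved = True
                break
            t /= 2.0
        if not improved:
            return x, sll, np.abs(g).max() < 1e-2, "line search stalled"
        rel = abs(sll_new - sll) / (abs(sll) + 1e-12)
        x, sll, sc = x + t * d, sll_new, sc_new
        # the surface can be extremely flat along the sd directions near
        # a boundary optimum: repeated negligible improvement terminates
        flat = flat + 1 if rel < ftol else 0
        if flat >= 2 or (rel < ftol and np.abs(g).max() < 1e-2):
            return x, sll, True, "relative SLL change below tolerance"
    return x, sll, False, "maximum iterations reached"


def estimate(
    data: pd.DataFrame,
    choice_set: ChoiceSet,
    tax_schedule: TaxSchedule | None = None,
    C: np.ndarray | None = None,
    R: int = 500,
    burn: int = 10,
    seed: int = 0,
    start: UtilityParams | None = None,
    n_starts: int = 3,
    gtol: float = 1e-5,
    maxiter: int = 200,
    compute_covariance: bool = True,
) -> EstimationResult:
    """Fit the mixed logit by maximum simulated likelihood.

    ``data`` needs the covariate columns, ``observed_alt``, and (if no
    precomputed income matrix ``C`` is given) ``gross_wage`` and
    ``other_income`` with no missing wages.  Halton draws are fixed by
    (R, burn), so the likelihood is deterministic; ``seed`` only jitters
    the additional optimizer starts beyond the first.

    Unless ``start`` is given, the mean coefficients are warm-started at
    the conditional-logit maximum (both SDs zero), which is cheap since
    the degenerate mixture needs a single draw.  Non-convergence of the
    best start is flagged on the result (and a warning emitted), never
    silently ignored.
    """
    if C is None:
        if tax_schedule is None:
            raise ValueError("provide either a tax schedule or an income matrix")
        C = income_matrix(
            data["gross_wage"].to_numpy(dtype=float),
            data["other_income"].to_numpy(dtype=float),
            choice_set, tax_schedule,
        )
    n = len(data)
    A = build_mean_design(data, choice_set, C)
    chosen = data["observed_alt"].to_numpy(dtype=int)
    l_row = choice_set.leisure_hours
    z = halton_draws(n, R, burn=burn)

    # column scaling to unit RMS
    scale = np.empty(N_PARAMS)
    scale[:N_MEAN] = np.sqrt((A ** 2).mean(axis=(0, 1)))
    scale[N_MEAN] = np.sqrt((C ** 2).mean())
    scale[N_MEAN + 1] = np.sqrt((l_row ** 2).mean())
    scale[scale == 0] = 1.0
    A_s = A / scale[:N_MEAN]
    C_s = C / scale[N_MEAN]
    l_s = l_row / scale[N_MEAN + 1]

    score_fn = lambda t: _scores(t, A_s, C_s, l_s, z, chosen)

    if start is not None:
        base = start.to_vector() * scale
    else:
        # conditional-logit warm start: degenerate mixture, one zero draw
        z1 = np.zeros((n, 1, 2))
        def clogit_scores(t17):
            sll, sc = _scores(
                np.concatenate([t17, [0.0, 0.0]]), A_s, C_s, l_s, z1, chosen)
            return sll, sc[:, :N_MEAN]
        x_cl, _, _, _ = _bhhh_maximize(clogit_scores, np.zeros(N_MEAN),
                                       maxiter=maxiter, gtol=gtol)
        base = np.concatenate([x_cl, [0.05, 0.05]])
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(max(0, n_starts - 1)):
        starts.append(base + rng.normal(scale=0.25, size=N_PARAMS))

    best = None
    for x0 in starts:
        x, sll_x, ok, msg = _bhhh_maximize(score_fn, x0, maxiter=maxiter,
                                           gtol=gtol)
        if best is None or sll_x > best[1]:
            best = (x, sll_x, ok, msg)
    theta_s, _, converged, message = best
    if not converged:
        warnings.warn(f"optimizer did not converge: {message}")

    # sandwich covariance H^-1 B H^-1 in the scaled parameterization
    sll, scores = _scores(theta_s, A_s, C_s, l_s, z, chosen)
    if compute_covariance:
        B = scores.T @ scores
        H = _numerical_hessian(
            lambda t: _scores(t, A_s, C_s, l_s, z, chosen)[1].sum(axis=0),
            theta_s,
        )
        try:
            Hinv = np.linalg.inv(H)
            cov_s = Hinv @ B @ Hinv.T
        except np.linalg.LinAlgError:
            cov_s = np.linalg.pinv(B)
        cov_s = 0.5 * (cov_s + cov_s.T)
    else:
        cov_s = np.zeros((N_PARAMS, N_PARAMS))

    theta = theta_s / scale
    cov = cov_s / np.outer(scale, scale)
    # sign normalization: SDs estimated unconstrained, reported as |.|
    theta[N_MEAN:] = np.abs(theta[N_MEAN:])
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    aic = 2 * N_PARAMS - 2 * sll
    return EstimationResult(
        params=UtilityParams.from_vector(theta),
        theta=theta,
        covariance=cov,
        se=se,
        loglik=sll,
        aic=aic,
        n_obs=n,
        R=R,
        burn=burn,
        converged=converged,
        n_starts=len(starts),
        message=message,
    )


def _numerical_hessian(grad_fn, x, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    k = len(x)
    H = np.empty((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = h
        H[:, j] = (grad_fn(x + step) - grad_fn(x - step)) / (2 * h)
    return 0.5 * (H + H.T)


# --------------------------------------------------------------------------
# Posterior individual-level coefficients
# --------------------------------------------------------------------------

def individual_parameters(
    result: EstimationResult,
    data: pd.DataFrame,
    choice_set: ChoiceSet,
    C: np.ndarray,
    draws: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior mean random coefficients per individual, shape (n, 2).

    Conditional on the observed choice, the expectation over the draw
    set is the likelihood-weighted mean

        E[beta_i | choice] = sum_r beta_r L_i(beta_r) / sum_r L_i(beta_r)

    which collapses to the population mean when the conditional
    likelihood is flat across draws (in particular when both SDs are 0).
    """
    theta = result.theta
    n = len(data)
    if draws is None:
        draws = halton_draws(n, result.R, burn=result.burn)
    A = build_mean_design(data, choice_set, C)
    chosen = data["observed_alt"].to_numpy(dtype=int)
    V = _utilities(theta, A, C, choice_set.leisure_hours, draws)
    P = logit_prob(V)
    Pk = P[np.arange(n), :, chosen]                      # (n, R)
    w = Pk / Pk.sum(axis=1, keepdims=True)
    b_c = theta[_IDX_INCOME] + theta[N_MEAN] * draws[:, :, 0]
    b_l = theta[_IDX_LEISURE] + theta[N_MEAN + 1] * draws[:, :, 1]
    return np.column_stack([(w * b_c).sum(axis=1), (w * b_l).sum(axis=1)])
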