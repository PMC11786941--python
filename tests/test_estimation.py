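import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carechoice import (
    GeneratorConfig,
    UtilityParams,
    estimate,
    generate_population,
    halton_draws,
    halton_sequence,
    income_matrix,
    individual_parameters,
    logit_prob,
    simulate_choices,
    simulated_loglik,
    simulated_prob,
)
from carechoice.estimation import build_mean_design
from carechoice.utility_model import mean_design_row


# ---------------------------------------------------------------- logit_prob

def test_logit_prob_uniform_over_equal_utilities():
    p = logit_prob(np.full(9, 3.7))
    assert np.allclose(p, 1 / 9, atol=1e-15)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_logit_prob_direct_softmax_value():
    V = np.zeros(9)
    V[0] = np.log(2.0)
    p = logit_prob(V)
    assert p[0] == pytest.approx(0.2, abs=1e-14)
    assert np.allclose(p[1:], 0.1, atol=1e-14)


@given(st.lists(st.floats(-50, 50), min_size=2, max_size=9),
       st.floats(-100, 100))
@settings(max_examples=100)
def test_logit_prob_shift_invariance(V, c):
    V = np.array(V)
    assert np.allclose(logit_prob(V), logit_prob(V + c), atol=1e-12)
    assert logit_prob(V).sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------- Halton

def test_halton_base2_sequence_start():
    pts = halton_sequence(3, primes=(2,))
    assert list(pts[:, 0]) == [0.5, 0.25, 0.75]


def test_halton_draws_deterministic_and_centered():
    z1 = halton_draws(50, 100)
    z2 = halton_draws(50, 100)
    assert np.array_equal(z1, z2)
    assert z1.shape == (50, 100, 2)
    assert abs(z1.mean()) < 0.01  # LLN: transformed mean near 0


def test_halton_draw_validation():
    with pytest.raises(ValueError):
        halton_draws(10, 0)
    with pytest.raises(ValueError):
        halton_sequence(5, primes=(2, 2))


# ---------------------------------------------------------------- design

def test_design_tensor_matches_per_row_builder(small_data, choice_set, schedule):
    sub = small_data.head(5)
    C = income_matrix(sub["gross_wage"].to_numpy(), sub["other_income"].to_numpy(),
                      choice_set, schedule)
    A = build_mean_design(sub, choice_set, C)
    for i in range(len(sub)):
        row = mean_design_row(C[i], choice_set.leisure_hours,
                              choice_set.care_hours, sub.iloc[i])
        assert np.allclose(A[i], row, rtol=1e-14)


# ---------------------------------------------------------------- simulated_prob

def _toy_individual():
    return {"female": 0, "age": 40.0, "east": 0, "migration": 0,
            "children_in_hh": 0, "n_adults": 2, "hh_gt2": 0}


def test_degenerate_mixture_equals_conditional_logit(choice_set, schedule, one_person):
    params = UtilityParams(income=0.002, leisure=0.8, care=0.05,
                           leisure_sq=-0.004, sd_income=0.0, sd_leisure=0.0)
    C = income_matrix(one_person["gross_wage"], one_person["other_income"],
                      choice_set, schedule)[0]
    A = mean_design_row(C, choice_set.leisure_hours, choice_set.care_hours,
                        one_person)
    V = A @ params.to_vector()[:17]
    expected = logit_prob(V)
    for R in (1, 7, 64):
        got = simulated_prob(params, one_person, choice_set, C,
                             halton_draws(1, R)[0])
        assert np.allclose(got, expected, atol=1e-14)


def test_single_draw_equals_logit_at_that_draw(choice_set, schedule, one_person):
    params = UtilityParams(income=0.002, leisure=0.8, sd_income=0.001,
                           sd_leisure=0.1)
    C = income_matrix(one_person["gross_wage"], one_person["other_income"],
                      choice_set, schedule)[0]
    z = np.array([[0.41, -1.3]])
    got = simulated_prob(params, one_person, choice_set, C, z)
    A = mean_design_row(C, choice_set.leisure_hours, choice_set.care_hours,
                        one_person)
    theta = params.to_vector()[:17].copy()
    theta[0] += params.sd_income * z[0, 0]
    theta[1] += params.sd_leisure * z[0, 1]
    assert np.allclose(got, logit_prob(A @ theta), atol=1e-14)


def test_mixture_matches_gauss_hermite_quadrature():
    """1 random coefficient, 2 alternatives: Halton average vs quadrature."""
    from carechoice import build_choice_set

    cs = build_choice_set([0, 40], [0], T=112)
    person = _toy_individual()
    params = UtilityParams(income=1.0, sd_income=0.8)
    C_row = np.array([0.3, 1.1])  # incomes scaled so utilities are O(1)
    z = halton_draws(1, 2000)[0]
    z[:, 1] = 0.0
    sim = simulated_prob(params, person, cs, C_row, z)

    nodes, weights = np.polynomial.hermite.hermgauss(40)
    b = params.income + params.sd_income * np.sqrt(2) * nodes
    pq = np.zeros(2)
    for bb, w in zip(b, weights):
        pq += w / np.sqrt(np.pi) * logit_prob(bb * C_row)
    assert np.allclose(sim, pq, atol=1e-3)


# ---------------------------------------------------------------- loglik

def test_uniform_probability_loglik(choice_set, one_person):
    data = pd.DataFrame([one_person])
    C = np.zeros((1, 9))
    z = halton_draws(1, 5)
    assert simulated_loglik(UtilityParams(), data, choice_set, C, z) == \
        pytest.approx(np.log(1 / 9))


def test_loglik_additive_and_matches_brute_force(small_data, choice_set, schedule):
    params = UtilityParams(income=0.002, leisure=0.7, care=0.02,
                           leisure_sq=-0.003, sd_income=0.0008, sd_leisure=0.1)
    sub = small_data.head(5).reset_index(drop=True)
    C = income_matrix(sub["gross_wage"].to_numpy(), sub["other_income"].to_numpy(),
                      choice_set, schedule)
    R = 13
    z = halton_draws(5, R)
    got = simulated_loglik(params, sub, choice_set, C, z)

    # brute-force double loop over individuals and draws
    total = 0.0
    theta = params.to_vector()
    for i in range(5):
        probs = np.zeros(9)
        for r in range(R):
            row = mean_design_row(C[i], choice_set.leisure_hours,
                                  choice_set.care_hours, sub.iloc[i])
            t = theta[:17].copy()
            t[0] += theta[17] * z[i, r, 0]
            t[1] += theta[18] * z[i, r, 1]
            probs += logit_prob(row @ t)
        total += np.log(probs[sub.loc[i, "observed_alt"]] / R)
    assert got == pytest.approx(total, rel=1e-12)

    # additivity over independent subsamples
    a = simulated_loglik(params, sub.iloc[:2].reset_index(drop=True),
                         choice_set, C[:2], z[:2])
    b = simulated_loglik(params, sub.iloc[2:].reset_index(drop=True),
                         choice_set, C[2:], z[2:])
    assert got == pytest.approx(a + b, rel=1e-12)


def test_loglik_invariant_to_individual_ordering(small_data, choice_set, schedule):
    params = UtilityParams(income=0.002, leisure=0.7, sd_leisure=0.1)
    sub = small_data.head(40).reset_index(drop=True)
    C = income_matrix(sub["gross_wage"].to_numpy(), sub["other_income"].to_numpy(),
                      choice_set, schedule)
    z = halton_draws(40, 11)
    sll = simulated_loglik(params, sub, choice_set, C, z)
    perm = np.random.default_rng(0).permutation(40)
    sll_p = simulated_loglik(params, sub.iloc[perm].reset_index(drop=True),
                             choice_set, C[perm], z[perm])
    assert sll == pytest.approx(sll_p, rel=1e-12)


def test_monte_carlo_stabilizes_as_draws_double(small_data, choice_set, schedule):
    # evaluated at the data-generating parameters, where the chosen-
    # alternative probabilities are well behaved
    params = GeneratorConfig().true_params
    sub = small_data.head(200).reset_index(drop=True)
    C = income_matrix(sub["gross_wage"].to_numpy(), sub["other_income"].to_numpy(),
                      choice_set, schedule)
    slls = [simulated_loglik(params, sub, choice_set, C, halton_draws(200, R))
            for R in (25, 50, 100, 200, 800)]
    deltas = np.abs(np.diff(slls))
    assert deltas[-1] < deltas[0]
    assert deltas[-1] < 0.5


# ---------------------------------------------------------------- estimate

def test_estimate_smoke_and_aic_identity(choice_set, schedule):
    cfg = GeneratorConfig(n=700, seed=31)
    data = simulate_choices(generate_population(cfg), cfg.true_params,
                            choice_set, schedule, seed=32)
    res = estimate(data, choice_set, schedule, R=60, seed=1, n_starts=1,
                   compute_covariance=True)
    assert res.converged
    assert res.aic == pytest.approx(2 * res.k - 2 * res.loglik)
    assert res.k == 19
    # covariance symmetric with non-negative diagonal
    assert np.allclose(res.covariance, res.covariance.T)
    assert (np.diag(res.covariance) >= 0).all()
    assert (res.se >= 0).all()
    # reported SDs non-negative by construction
    assert res.params.sd_income >= 0 and res.params.sd_leisure >= 0
    # sanity: leisure and income coefficients in the truth's ballpark
    assert res.params.income == pytest.approx(cfg.true_params.income, abs=0.002)
    assert res.params.leisure == pytest.approx(cfg.true_params.leisure, abs=0.5)
    summary = res.summary()
    assert list(summary.columns) == ["coef", "se", "z", "p", "stars"]
    assert len(summary) == 19


# ------------------------------------------------- individual_parameters

def test_posterior_coefficients_collapse_without_heterogeneity(
        small_data, choice_set, schedule):
    from dataclasses import replace
    sub = small_data.head(50).reset_index(drop=True)
    C = income_matrix(sub["gross_wage"].to_numpy(), sub["other_income"].to_numpy(),
                      choice_set, schedule)
    theta = UtilityParams(income=0.002, leisure=0.7).to_vector()
    res = _fake_result(theta, R=30)
    post = individual_parameters(res, sub, choice_set, C)
    assert np.allclose(post[:, 0], 0.002, atol=1e-15)
    assert np.allclose(post[:, 1], 0.7, atol=1e-15)


def test_posterior_coefficients_brute_force_and_flat_limit(
        small_data, choice_set, schedule):
    sub = small_data.head(3).reset_index(drop=True)
    C = income_matrix(sub["gross_wage"].to_numpy(), sub["other_income"].to_numpy(),
                      choice_set, schedule)
    theta = UtilityParams(income=0.002, leisure=0.7, sd_income=0.001,
                          sd_leisure=0.12).to_vector()
    res = _fake_result(theta, R=10)
    z = halton_draws(3, 10)
    post = individual_parameters(res, sub, choice_set, C, draws=z)
    for i in range(3):
        b_c = theta[0] + theta[17] * z[i, :, 0]
        b_l = theta[1] + theta[18] * z[i, :, 1]
        L = np.zeros(10)
        for r in range(10):
            row = mean_design_row(C[i], choice_set.leisure_hours,
                                  choice_set.care_hours, sub.iloc[i])
            t = theta[:17].copy()
            t[0], t[1] = b_c[r], b_l[r]
            L[r] = logit_prob(row @ t)[sub.loc[i, "observed_alt"]]
        assert post[i, 0] == pytest.approx((b_c * L).sum() / L.sum(), rel=1e-10)
        assert post[i, 1] == pytest.approx((b_l * L).sum() / L.sum(), rel=1e-10)

    # flat likelihood across draws (income random but all incomes zero)
    # -> posterior mean is the plain mean of the draws
    flat = _fake_result(
        UtilityParams(income=0.003, leisure=0.5, sd_income=0.001).to_vector(),
        R=10)
    post_flat = individual_parameters(flat, sub, choice_set,
                                      np.zeros_like(C), draws=z)
    for i in range(3):
        assert post_flat[i, 0] == pytest.approx(
            0.003 + 0.001 * z[i, :, 0].mean())
        assert post_flat[i, 1] == pytest.approx(0.5)


def _fake_result(theta, R):
    from carechoice import EstimationResult

    return EstimationResult(
        params=UtilityParams.from_vector(theta), theta=np.asarray(theta),
        covariance=np.zeros((19, 19)), se=np.zeros(19), loglik=0.0, aic=0.0,
        n_obs=0, R=R, burn=10, converged=True, n_starts=1, message="synthetic",
    )
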