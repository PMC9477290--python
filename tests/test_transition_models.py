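"""Splines, design rows, ordered-probit/probit likelihoods, estimation, AMEs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from ticsim.errors import DomainError, EstimationError
from ticsim.synthetic_cohort import single_transition_dataset
from ticsim.transition_models import (
    DEFAULT_SPEC,
    FitResult,
    OrderedProbitParams,
    ProbitParams,
    age_spline_basis,
    average_marginal_effects,
    bmi_spline_basis,
    build_design_row,
    fit_ordered_probit,
    fit_probit,
    op_category_probabilities,
    op_loglik,
    probit_loglik,
)


@pytest.mark.parametrize(
    "age,knots,expected",
    [
        (60, (65, 75), (60, 0, 0)),
        (70, (65, 75), (65, 5, 0)),
        (90, (65, 75, 85), (65, 10, 10, 5)),
        (65, (65, 75), (65, 0, 0)),
    ],
)
def test_age_spline_segments(age, knots, expected):
    assert age_spline_basis(age, knots) == pytest.approx(expected)


def test_age_spline_rejects_unordered_knots():
    with pytest.raises(DomainError):
        age_spline_basis(70, (75, 65))


@pytest.mark.parametrize(
    "bmi,expected",
    [
        (30, (math.log(30), 0.0)),
        (25, (math.log(25), 0.0)),
        (36, (math.log(30), math.log(36) - math.log(30))),
    ],
)
def test_bmi_spline_knot(bmi, expected):
    assert bmi_spline_basis(math.log(bmi)) == pytest.approx(expected)


def _reference_person(**overrides):
    state = {
        "lag_tics": 15,
        "lag4_tics": 16,
        "race_ethnicity": "nh_white",
        "education": "hs",
        "male": 0,
        "age": 70,
        "heart_ever": 0,
        "stroke_ever": 0,
        "cancer_ever": 0,
        "hypertension_ever": 0,
        "diabetes_ever": 0,
        "lung_ever": 0,
        "chf_ever": 0,
        "heart_attack_2yr": 0,
        "working": 1,
        "widowed": 0,
        "smoke_ever": 0,
        "smoke_current": 0,
        "verified_ever": 0,
        "interview_gap_years": 2.0,
        "delta_age": 0.0,
        "lag_log_bmi": math.log(27),
        "adl_count": 0,
        "iadl_count": 0,
        "heart50": 0,
        "stroke50": 0,
        "cancer50": 0,
        "hypertension50": 0,
        "diabetes50": 0,
        "lung50": 0,
        "smoke_ever50": 0,
        "smoke_current50": 0,
    }
    state.update(overrides)
    return state


def test_design_row_reference_categories_and_splines():
    row = build_design_row(_reference_person(), "tics")
    assert row["nh_black"] == 0 and row["hispanic"] == 0
    assert row["lt_hs"] == 0 and row["some_college"] == 0
    assert (row["age_spline_lt65"], row["age_spline_65_75"], row["age_spline_75p"]) == (65, 5, 0)
    assert row["delta_age"] == 0.0
    mrow = build_design_row(_reference_person(age=90), "mortality")
    assert (
        mrow["age_spline_lt65"],
        mrow["age_spline_65_75"],
        mrow["age_spline_75_85"],
        mrow["age_spline_85p"],
    ) == (65, 10, 10, 5)


def test_design_row_names_missing_covariate():
    state = _reference_person()
    del state["lag_tics"]
    with pytest.raises(EstimationError, match="lag_tics"):
        build_design_row(state, "tics")


# ---------------------------------------------------------------------------
# Category probabilities and likelihoods
# ---------------------------------------------------------------------------


def test_three_category_probabilities_closed_form():
    params = OrderedProbitParams(beta=[1.0], names=["x"], kappa=[-1.0, 1.0])
    probs = op_category_probabilities(params, np.array([1.0]))
    expected = (ndtr(-2.0), ndtr(0.0) - ndtr(-2.0), 1 - ndtr(0.0))
    assert probs == pytest.approx(expected, abs=1e-12)


def test_category_probabilities_normalize():
    rng = np.random.default_rng(0)
    params = OrderedProbitParams(
        beta=rng.normal(size=3), names=list("abc"), kappa=np.sort(rng.normal(size=27))
    )
    X = rng.normal(size=(50, 3))
    probs = op_category_probabilities(params, X)
    assert probs.min() >= 0
    assert np.abs(probs.sum(axis=1) - 1).max() < 1e-10


def test_index_shift_gives_stochastic_dominance():
    params = OrderedProbitParams(beta=[1.0], names=["x"], kappa=np.linspace(-2, 2, 9))
    base = np.cumsum(op_category_probabilities(params, np.array([0.0])))
    for delta in (0.1, 0.5, 1.0, 2.5):
        shifted = np.cumsum(op_category_probabilities(params, np.array([delta])))
        assert np.all(shifted <= base + 1e-12)


def test_loglik_single_row_and_empty():
    params = OrderedProbitParams(beta=[0.0], names=["x"], kappa=[0.0, 1.0])
    # category 1 of 3 has probability ndtr(1) - ndtr(0)
    ll = op_loglik(params, np.array([[0.0]]), np.array([1]))
    assert ll == pytest.approx(math.log(ndtr(1.0) - ndtr(0.0)))
    assert op_loglik(params, np.empty((0, 1)), np.empty(0, int)) == 0.0
    pp = ProbitParams(gamma=[0.0], names=["x"], intercept=0.0)
    assert probit_loglik(pp, np.array([[3.0]]), np.array([1.0])) == pytest.approx(math.log(0.5))
    assert probit_loglik(pp, np.empty((0, 1)), np.empty(0)) == 0.0


def test_true_parameters_beat_perturbed_on_large_sample():
    X, names, y, truth = single_transition_dataset(50_000, 9)
    ll_true = op_loglik(truth, X, y)
    for scale in (0.9, 1.1):
        perturbed = OrderedProbitParams(
            beta=truth.beta * scale, names=names, kappa=truth.kappa
        )
        assert ll_true > op_loglik(perturbed, X, y)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _small_op_data(seed, n=4000, p=3, n_cat=6):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.array([0.5, -0.3, 0.2])[:p]
    kappa = np.linspace(-1.2, 1.2, n_cat - 1)
    z = X @ beta + rng.standard_normal(n)
    y = np.searchsorted(kappa, z)
    return X, y, beta, kappa


def test_ordered_probit_row_order_invariance_and_duplication():
    X, y, *_ = _small_op_data(1)
    fit = fit_ordered_probit(X, y)
    perm = np.random.default_rng(2).permutation(len(y))
    fit_perm = fit_ordered_probit(X[perm], y[perm])
    assert fit.params.beta == pytest.approx(fit_perm.params.beta, abs=1e-6)
    dup = fit_ordered_probit(np.vstack([X, X]), np.concatenate([y, y]))
    assert dup.params.beta == pytest.approx(fit.params.beta, abs=1e-6)
    # doubling the data shrinks standard errors by sqrt(2)
    ratio = fit.standard_errors.to_numpy() / dup.standard_errors.to_numpy()
    assert ratio == pytest.approx(np.full(len(ratio), math.sqrt(2)), rel=0.01)


def test_coefficient_recovery_bias_within_monte_carlo_error():
    """Across seeded replications the estimator is unbiased (2 MC SEs)."""
    reps = 20
    ests = []
    beta = kappa = None
    for s in range(reps):
        X, y, beta, kappa = _small_op_data(100 + s, n=20_000)
        fit = fit_ordered_probit(X, y, compute_se=False)
        ests.append(fit.params.beta)
    ests = np.array(ests)
    bias = ests.mean(axis=0) - beta
    mc_se = ests.std(axis=0, ddof=1) / math.sqrt(reps)
    assert np.all(np.abs(bias) <= 2 * mc_se + 1e-4)


def test_two_category_ordered_probit_reproduces_probit():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(3000, 2))
    y = (X @ [0.8, -0.5] + 0.3 + rng.standard_normal(3000) > 0).astype(int)
    op = fit_ordered_probit(X, y)
    pr = fit_probit(X, y)
    assert op.params.beta == pytest.approx(pr.params.gamma, abs=1e-6)
    assert op.params.kappa[0] == pytest.approx(-pr.params.intercept, abs=1e-6)


def test_estimates_match_statsmodels_oracle():
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    X, y, *_ = _small_op_data(4, n=2500, n_cat=5)
    ours = fit_ordered_probit(X, y)
    ref = OrderedModel(y, X, distr="probit").fit(method="bfgs", disp=False)
    assert ours.params.beta == pytest.approx(ref.params[:3], abs=2e-4)
    assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-3)

    rng = np.random.default_rng(5)
    Xb = rng.normal(size=(3000, 2))
    yb = (Xb @ [0.6, -0.4] - 0.2 + rng.standard_normal(3000) > 0).astype(float)
    ours_b = fit_probit(Xb, yb)
    ref_b = sm.Probit(yb, sm.add_constant(Xb)).fit(disp=False)
    assert ours_b.params.intercept == pytest.approx(ref_b.params[0], abs=2e-5)
    assert ours_b.params.gamma == pytest.approx(ref_b.params[1:], abs=2e-5)
    ses = ours_b.standard_errors
    assert ses["intercept"] == pytest.approx(ref_b.bse[0], rel=1e-3)


def test_probit_separation_raises():
    X = np.random.default_rng(6).normal(size=(100, 2))
    with pytest.raises(EstimationError):
        fit_probit(X, np.zeros(100))


def test_rank_deficiency_lists_columns():
    rng = np.random.default_rng(7)
    x = rng.normal(size=1000)
    X = np.column_stack([x, 2 * x])
    y = (x + rng.standard_normal(1000) > 0).astype(int)
    with pytest.raises(EstimationError, match="rank"):
        fit_ordered_probit(X, y, names=["a", "b"])


def test_unobserved_levels_are_merged_out():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(2000, 1))
    y = np.where(X[:, 0] + 0.5 * rng.standard_normal(2000) > 0, 20, 5)  # only 2 levels
    fit = fit_ordered_probit(X, y)
    assert fit.extras["n_categories"] == 2
    assert np.array_equal(fit.params.levels, [5, 20])
    probs = op_category_probabilities(fit.params, X[:5])
    assert probs.shape == (5, 2)


# ---------------------------------------------------------------------------
# Average marginal effects
# ---------------------------------------------------------------------------


def test_probit_ame_closed_form_and_zero():
    n = 500
    X = np.zeros((n, 2))
    X[:, 1] = 0.0
    params = ProbitParams(gamma=[0.7, 0.0], names=["x", "z"], intercept=0.0)
    fit = FitResult(
        params=params,
        standard_errors=pd.Series([0.1, 0.1], index=["x", "z"]),
        log_likelihood=0.0,
        converged=True,
        n_obs=n,
    )
    X[:, 0] = np.random.default_rng(9).normal(size=n) * 1e-9  # x'gamma ~ 0
    ame = average_marginal_effects(fit, X)
    assert ame["x"] == pytest.approx(0.7 / math.sqrt(2 * math.pi), rel=1e-6)
    assert ame["z"] == 0.0


def test_ordered_probit_ame_matches_finite_differences():
    X, names, y, truth = single_transition_dataset(2000, 10)
    fit = fit_ordered_probit(X, y, names=names, compute_se=False)
    fit.converged = True
    ame = average_marginal_effects(fit, X, names=names)
    params = fit.params
    levels = params.levels.astype(float)

    def mean_score(Xq):
        probs = op_category_probabilities(params, Xq)
        return float((probs @ levels).mean())

    k = names.index("lag_tics")
    h = 1e-5
    Xp, Xm = X.copy(), X.copy()
    Xp[:, k] += h
    Xm[:, k] -= h
    fd = (mean_score(Xp) - mean_score(Xm)) / (2 * h)
    assert ame["lag_tics"] == pytest.approx(fd, abs=1e-6)
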