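"""Logistic MLE, Wald and likelihood-ratio tests, and the selection ladder.

The fitted coefficients are checked against two independent routes: a
brute-force coarse-to-fine grid search maximizing the Bernoulli
log-likelihood, and statsmodels' Logit.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from picurisk.glm import (
    LogisticFit,
    ModelSpec,
    fit_logistic,
    fit_logistic_xy,
    likelihood_ratio_test,
    selection_ladder,
    wald_test,
)
from picurisk.synth import default_profiles, generate_cohort

from conftest import make_cohort


def bernoulli_loglik(y, eta):
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def grid_search_mle(y, x, span=8.0, width=101, passes=6):
    """Coarse-to-fine grid maximization of the 2-parameter log-likelihood."""
    c0, c1 = 0.0, 0.0
    h0 = h1 = span
    for _ in range(passes):
        b0 = np.linspace(c0 - h0, c0 + h0, width)
        b1 = np.linspace(c1 - h1, c1 + h1, width)
        eta = b0[:, None, None] + b1[None, :, None] * x[None, None, :]
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c0, c1 = b0[i], b1[j]
        h0 *= 2.2 / width
        h1 *= 2.2 / width
    return c0, c1


@pytest.fixture(scope="module")
def fixture_20():
    rng = np.random.default_rng(7)
    x = rng.normal(1.0, 1.5, 20)
    eta = -1.0 + 1.2 * x
    y = (rng.random(20) < 1 / (1 + np.exp(-eta))).astype(float)
    assert 0 < y.sum() < 20
    return y, x


def test_intercept_only_closed_form():
    cohort = make_cohort(mid=np.zeros(4), outcome=[1, 0, 0, 0])
    fit = fit_logistic(cohort, ModelSpec(()))
    assert fit.coef("intercept") == pytest.approx(np.log(1 / 3), abs=1e-8)


def test_coefficients_match_grid_search_oracle(fixture_20):
    y, x = fixture_20
    X = np.column_stack([np.ones(20), x])
    fit = fit_logistic_xy(y, X)
    b0, b1 = grid_search_mle(y, x)
    assert fit.params[0] == pytest.approx(b0, abs=1e-4)
    assert fit.params[1] == pytest.approx(b1, abs=1e-4)


def test_wald_p_matches_numerical_hessian(fixture_20):
    y, x = fixture_20
    X = np.column_stack([np.ones(20), x])
    fit = fit_logistic_xy(y, X)
    # independent SE: numerical Hessian of the log-likelihood at the optimum
    h = 1e-4

    def ll(b):
        return bernoulli_loglik(y, X @ b)

    b = fit.params
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei, ej = np.eye(2)[i] * h, np.eye(2)[j] * h
            H[i, j] = (
                ll(b + ei + ej) - ll(b + ei - ej) - ll(b - ei + ej) + ll(b - ei - ej)
            ) / (4 * h * h)
    se_num = np.sqrt(np.diag(np.linalg.inv(-H)))
    z = b[1] / se_num[1]
    p_oracle = stats.chi2.sf(z * z, 1)
    spec_fit = fit_logistic_xy(y, X, spec=ModelSpec(("x",)))
    p_pkg = wald_test(spec_fit, "x").p_value
    assert p_pkg == pytest.approx(p_oracle, abs=1e-3)


def test_matches_statsmodels(fixture_20):
    sm = pytest.importorskip("statsmodels.api")
    y, x = fixture_20
    X = np.column_stack([np.ones(20), x])
    ours = fit_logistic_xy(y, X)
    ref = sm.Logit(y, X).fit(disp=0)
    assert np.allclose(ours.params, ref.params, atol=1e-6)
    assert np.allclose(ours.bse, ref.bse, atol=1e-5)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-8)


def test_zero_predictor_is_degenerate(fixture_20):
    y, _ = fixture_20
    cohort = make_cohort(mid=np.zeros(20), outcome=y.astype(int))
    fit = fit_logistic(cohort, ModelSpec(("MID",)))
    null = fit_logistic(cohort, ModelSpec(()))
    assert fit.coef("intercept") == pytest.approx(null.coef("intercept"), abs=1e-6)
    assert np.isnan(fit.se("MID"))


def test_separation_is_flagged_not_raised():
    y = np.array([0.0] * 10 + [1.0] * 10)
    x = np.concatenate([np.linspace(0, 1, 10), np.linspace(2, 3, 10)])
    fit = fit_logistic_xy(y, np.column_stack([np.ones(20), x]))
    assert fit.separation_flag


@pytest.mark.parametrize(
    "z, expected_p",
    [(0.0, 1.0), (1.959964, 0.05)],
)
def test_wald_normal_quantile_identity(z, expected_p):
    fit = LogisticFit(
        spec=ModelSpec(("MID",)),
        names=("intercept", "MID"),
        params=np.array([0.0, z]),
        bse=np.array([1.0, 1.0]),
        loglik=-1.0,
        n=10,
        converged=True,
        separation_flag=False,
        n_iter=1,
    )
    assert wald_test(fit, "MID").p_value == pytest.approx(expected_p, abs=1e-6)


def test_wald_requires_predictor_in_model(fixture_20):
    y, x = fixture_20
    cohort = make_cohort(mid=x * 10 + 40, outcome=y.astype(int))
    fit = fit_logistic(cohort, ModelSpec(("MID",)))
    with pytest.raises(ValueError, match="PIM2"):
        wald_test(fit, "PIM2")


def test_lrt_identical_models_is_null_result(fixture_20):
    y, x = fixture_20
    cohort = make_cohort(mid=x * 10 + 40, outcome=y.astype(int))
    fit = fit_logistic(cohort, ModelSpec(("MID",)))
    res = likelihood_ratio_test(fit, fit)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_lrt_rejects_non_nested_and_mismatched_n(fixture_20):
    y, x = fixture_20
    rng = np.random.default_rng(0)
    cohort = make_cohort(
        mid=x * 10 + 40, outcome=y.astype(int), pim2=rng.uniform(0, 20, 20)
    )
    f_mid = fit_logistic(cohort, ModelSpec(("MID",)))
    f_pim = fit_logistic(cohort, ModelSpec(("PIM2",)))
    with pytest.raises(ValueError, match="not nested"):
        likelihood_ratio_test(f_mid, f_pim)
    smaller = fit_logistic(cohort.subset(np.arange(20) < 15), ModelSpec(()))
    with pytest.raises(ValueError, match="complete-case"):
        likelihood_ratio_test(smaller, f_mid)


def test_affine_invariance(fixture_20):
    y, x = fixture_20
    X = np.column_stack([np.ones(20), x])
    base = fit_logistic_xy(y, X)
    shifted = fit_logistic_xy(y, np.column_stack([np.ones(20), x + 5.0]))
    assert shifted.params[1] == pytest.approx(base.params[1], abs=1e-8)
    assert shifted.params[0] == pytest.approx(
        base.params[0] - 5.0 * base.params[1], abs=1e-7
    )
    scaled = fit_logistic_xy(y, np.column_stack([np.ones(20), 4.0 * x]))
    assert scaled.params[1] == pytest.approx(base.params[1] / 4.0, abs=1e-8)
    assert scaled.bse[1] == pytest.approx(base.bse[1] / 4.0, rel=1e-6)


def _simulated_cohort(beta_mid, beta_pim2, n=800, seed=11):
    rng = np.random.default_rng(seed)
    mid = np.clip(rng.normal(15, 15, n), 0, 100)
    pim2 = np.clip(rng.normal(5, 6, n), 0, 100)
    eta = -4.0 + beta_mid * mid + beta_pim2 * pim2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return make_cohort(mid=mid, outcome=y, pim2=pim2, tiss28=rng.uniform(5, 40, n))


def test_ladder_selects_single_informative_index():
    cohort = _simulated_cohort(beta_mid=0.09, beta_pim2=0.0)
    report = selection_ladder(cohort)
    assert report.selected.predictors == ("MID",)
    assert report.subjective_best.predictors == ("MID",)


def test_ladder_selects_hybrid_when_both_carry_signal():
    cohort = _simulated_cohort(beta_mid=0.08, beta_pim2=0.18)
    report = selection_ladder(cohort)
    assert set(report.selected.predictors) == {"MID", "PIM2"}


def test_ladder_returns_null_when_nothing_is_informative():
    cohort = _simulated_cohort(beta_mid=0.0, beta_pim2=0.0, seed=5)
    report = selection_ladder(cohort)
    assert report.selected.predictors == ()


def test_mid_vs_null_is_strongly_significant_on_calibrated_cohort():
    oviedo, _ = default_profiles()
    cohort, _ = generate_cohort(oviedo, seed=42)
    null = fit_logistic(cohort, ModelSpec(()))
    mid = fit_logistic(cohort, ModelSpec(("MID",)))
    res = likelihood_ratio_test(null, mid)
    assert res.p_value < 0.001
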