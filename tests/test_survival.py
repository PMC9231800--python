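"""Survival distributions, censored MLE and model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from durvacea.survival import (
    DAYS_PER_MONTH,
    FAMILIES,
    IPDRecord,
    SurvivalCurve,
    SurvivalModelError,
    conditional_transition_prob,
    fit_parametric,
    hazard,
    median_survival,
    select_best,
    survival,
)

from .conftest import PPS, PUBLISHED_CURVES

EXAMPLE_CURVES = {
    "exponential": SurvivalCurve("exponential", (0.1,)),
    "weibull": SurvivalCurve("weibull", (1.4, 12.0)),
    "lognormal": SurvivalCurve("lognormal", (3.0448, 1.1876)),
    "loglogistic": SurvivalCurve("loglogistic", (1.8, 9.0)),
    "gompertz": SurvivalCurve("gompertz", (0.02, 0.05)),
    "gengamma": SurvivalCurve("gengamma", (0.6274, 0.5416, -4.0697)),
}


@pytest.mark.parametrize("family", FAMILIES)
def test_survival_at_zero_is_one(family):
    assert survival(EXAMPLE_CURVES[family], 0.0) == 1.0


@pytest.mark.parametrize("family", FAMILIES)
def test_survival_monotone_and_bounded(family):
    t = np.linspace(0, 480, 1000)
    s = survival(EXAMPLE_CURVES[family], t)
    assert np.all((0 <= s) & (s <= 1))
    assert np.all(np.diff(s) <= 1e-12)


def test_lognormal_median_from_published_pps_row():
    # closed form: the log-normal median is e^mu
    t_med = math.exp(3.0448)
    assert survival(PPS, t_med) == pytest.approx(0.5, abs=1e-12)
    assert median_survival(PPS) == pytest.approx(t_med, rel=1e-8)


def test_exponential_closed_forms():
    lam = 0.1
    c = EXAMPLE_CURVES["exponential"]
    t = np.array([0.5, 3.0, 17.0])
    assert survival(c, t) == pytest.approx(np.exp(-lam * t))
    assert hazard(c, 7.7) == pytest.approx(lam)
    assert median_survival(c) == pytest.approx(math.log(2) / lam, rel=1e-8)
    # cross-check S against numerical integration of the (constant) hazard
    grid = np.linspace(1e-6, 20, 4001)
    cumh = np.trapezoid(np.atleast_1d(hazard(c, grid)), grid)
    assert math.exp(-cumh) == pytest.approx(survival(c, 20.0), rel=1e-6)


@pytest.mark.parametrize("family", ["weibull", "lognormal", "loglogistic", "gompertz", "gengamma"])
def test_hazard_matches_finite_difference_of_log_survival(family):
    curve = EXAMPLE_CURVES[family]
    for t in [0.7, 4.0, 15.0, 40.0]:
        eps = 1e-5 * t
        fd = -(math.log(survival(curve, t + eps)) - math.log(survival(curve, t - eps))) / (2 * eps)
        assert hazard(curve, t) == pytest.approx(fd, rel=1e-6)


def test_gengamma_hazard_nonnegative_on_extrapolation_range():
    c = PUBLISHED_CURVES["durvalumab"]["pfs"]
    t = np.linspace(0.01, 480, 500)
    assert np.all(np.atleast_1d(hazard(c, t)) >= 0)


def test_conditional_transition_prob_exponential_memoryless():
    lam = 0.1
    c = EXAMPLE_CURVES["exponential"]
    for t0, t1 in [(0, 1), (5, 9), (30, 30.5)]:
        assert conditional_transition_prob(c, t0, t1) == pytest.approx(
            1 - math.exp(-lam * (t1 - t0)), rel=1e-12
        )


def test_conditional_transition_prob_vanishes_for_short_intervals():
    c = EXAMPLE_CURVES["weibull"]
    assert conditional_transition_prob(c, 5.0, 5.0 + 1e-9) < 1e-8


def test_conditional_transition_prob_bsc_pfs_14_days():
    # direct re-evaluation: 1 - S(14 days) from the BSC PFS row
    c = PUBLISHED_CURVES["bsc"]["pfs"]
    t1 = 14 / DAYS_PER_MONTH
    assert conditional_transition_prob(c, 0.0, t1) == pytest.approx(
        1 - survival(c, t1), rel=1e-12
    )


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    t0=st.floats(0.0, 50.0),
    d1=st.floats(0.01, 30.0),
    d2=st.floats(0.01, 30.0),
    family=st.sampled_from(sorted(EXAMPLE_CURVES)),
)
def test_conditional_transition_prob_is_additive(t0, d1, d2, family):
    """1 - S(t2)/S(t0) composes multiplicatively through any midpoint t1."""
    c = EXAMPLE_CURVES[family]
    t1, t2 = t0 + d1, t0 + d1 + d2
    p02 = conditional_transition_prob(c, t0, t2)
    p01 = conditional_transition_prob(c, t0, t1)
    p12 = conditional_transition_prob(c, t1, t2)
    assert 1 - p02 == pytest.approx((1 - p01) * (1 - p12), abs=1e-12)


def test_conditional_transition_prob_rejects_bad_interval():
    with pytest.raises(SurvivalModelError):
        conditional_transition_prob(EXAMPLE_CURVES["exponential"], 3.0, 3.0)


def test_survival_rejects_negative_time():
    with pytest.raises(SurvivalModelError):
        survival(EXAMPLE_CURVES["exponential"], -1.0)


def test_curve_rejects_invalid_parameters():
    with pytest.raises(SurvivalModelError):
        SurvivalCurve("lognormal", (1.0, -0.5))
    with pytest.raises(SurvivalModelError):
        SurvivalCurve("gengamma", (0.5, 1.0, 0.0))
    with pytest.raises(SurvivalModelError):
        SurvivalCurve("weibull", (float("nan"), 1.0))


def test_gengamma_nests_lognormal_in_small_q_limit():
    # convergence is first order in Q with leading coefficient phi(0)/3
    # (the gamma skewness term), so the deviation at |Q| = 1e-3 is ~1.3e-4
    t = np.array([0.5, 2.0, 8.0, 30.0, 100.0])
    ln = survival(SurvivalCurve("lognormal", (2.0, 0.8)), t)
    for q in (1e-3, -1e-3):
        gg = survival(SurvivalCurve("gengamma", (2.0, 0.8, q)), t)
        assert gg == pytest.approx(ln, abs=2e-4)
        coarse = survival(SurvivalCurve("gengamma", (2.0, 0.8, 10 * q)), t)
        ratio = np.max(np.abs(coarse - ln)) / np.max(np.abs(gg - ln))
        assert ratio == pytest.approx(10.0, rel=0.05)


def test_gengamma_equals_weibull_at_q_one():
    mu, sigma = 2.3, 0.7
    t = np.array([0.5, 2.0, 8.0, 30.0, 100.0])
    gg = survival(SurvivalCurve("gengamma", (mu, sigma, 1.0)), t)
    wb = survival(SurvivalCurve("weibull", (1 / sigma, math.exp(mu))), t)
    assert gg == pytest.approx(wb, abs=1e-6)


def test_bsc_pfs_median_is_single_digit_months():
    # parameterization sanity gate: the comparator arm progresses in months,
    # not days or years, matching the trial's clinical scale
    m = median_survival(PUBLISHED_CURVES["bsc"]["pfs"])
    assert 1.0 < m < 10.0
    assert median_survival(PUBLISHED_CURVES["durvalumab"]["pfs"]) > m


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _simulate_censored(curve, n, censor_q, seed):
    from durvacea.simulate import sample_survival_times

    rng = np.random.default_rng(seed)
    t = sample_survival_times(curve, n, rng)
    c = np.quantile(t, 1 - censor_q)
    return [IPDRecord(min(x, c), int(x <= c)) for x in t]


def test_fit_recovers_lognormal_within_three_se():
    truth = (3.0448, 1.1876)
    data = _simulate_censored(SurvivalCurve("lognormal", truth), 2000, 0.30, seed=7)
    fit = fit_parametric(data, "lognormal")
    assert fit.converged
    se = fit.stderr()
    assert se is not None
    for est, tru, s in zip(fit.curve.params, truth, se):
        assert abs(est - tru) < 3 * s


def test_weibull_fit_on_exponential_data_gives_unit_shape():
    data = _simulate_censored(SurvivalCurve("exponential", (0.08,)), 2000, 0.30, seed=11)
    fit = fit_parametric(data, "weibull")
    shape, se_shape = fit.curve.params[0], fit.stderr()[0]
    assert abs(shape - 1.0) < 3 * se_shape


def test_fitted_loglik_at_least_that_of_truth():
    truth = SurvivalCurve("weibull", (1.5, 10.0))
    data = _simulate_censored(truth, 1000, 0.30, seed=3)
    fit = fit_parametric(data, "weibull")
    t = np.array([r.time for r in data])
    e = np.array([r.event for r in data])
    from durvacea.survival import log_density

    ll_truth = float(
        np.sum(
            np.where(
                e == 1,
                log_density(truth, np.maximum(t, 1e-9)),
                np.log(np.maximum(np.atleast_1d(survival(truth, t)), 1e-300)),
            )
        )
    )
    assert fit.loglik >= ll_truth - 1e-6


def test_fit_information_criterion_identities():
    data = _simulate_censored(SurvivalCurve("exponential", (0.2,)), 200, 0.2, seed=1)
    fit = fit_parametric(data, "exponential")
    assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik, abs=1e-10)
    assert fit.bic == pytest.approx(math.log(fit.n) - 2 * fit.loglik, abs=1e-10)


def test_fit_cross_checked_against_lifelines():
    lifelines = pytest.importorskip("lifelines")
    data = _simulate_censored(SurvivalCurve("weibull", (1.3, 15.0)), 1500, 0.25, seed=5)
    fit = fit_parametric(data, "weibull")
    t = np.array([r.time for r in data])
    e = np.array([r.event for r in data])
    wf = lifelines.WeibullFitter().fit(np.maximum(t, 1e-9), e)
    assert fit.curve.params[0] == pytest.approx(wf.rho_, rel=1e-3)
    assert fit.curve.params[1] == pytest.approx(wf.lambda_, rel=1e-3)


def test_fit_rejects_degenerate_data():
    with pytest.raises(SurvivalModelError):
        fit_parametric([IPDRecord(1.0, 1)] * 5, "exponential")
    with pytest.raises(SurvivalModelError):
        fit_parametric([IPDRecord(1.0, 0)] * 20, "exponential")


def test_select_best_single_and_tiebreak():
    data = _simulate_censored(SurvivalCurve("exponential", (0.2,)), 100, 0.2, seed=2)
    f_exp = fit_parametric(data, "exponential")
    assert select_best([f_exp]) is f_exp
    f_wb = fit_parametric(data, "weibull")
    f_gg = fit_parametric(data, "gengamma")
    # artificial exact tie: fewer parameters win
    f_gg.aic = f_wb.aic
    assert select_best([f_gg, f_wb], "aic") is f_wb


def test_select_best_rejects_mixed_data():
    d1 = _simulate_censored(SurvivalCurve("exponential", (0.2,)), 100, 0.2, seed=2)
    d2 = _simulate_censored(SurvivalCurve("exponential", (0.2,)), 120, 0.2, seed=2)
    with pytest.raises(SurvivalModelError):
        select_best([fit_parametric(d1, "exponential"), fit_parametric(d2, "weibull")])


def test_median_not_reached_reports_infinity():
    # a defective Gompertz with negative shape plateaus above 0.5
    c = SurvivalCurve("gompertz", (-0.5, 0.05))
    assert median_survival(c) == math.inf
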