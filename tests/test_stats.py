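"""Unit and oracle tests for the survival / exact-test statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats as sps

from survcut import (
    SurvivalData,
    cox_ph,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    univariate_hr,
)
from survcut.errors import (
    DataError,
    SingularMatrixError,
    UndefinedTestError,
)
from survcut.stats import cox_partial_loglik

from conftest import random_survival


# ---------------------------------------------------------------------------
# SurvivalData contract


@pytest.mark.parametrize(
    "time,event",
    [
        ([1, 2], [1]),              # length mismatch
        ([0, 2], [1, 0]),           # non-positive time
        ([np.inf, 2], [1, 0]),      # non-finite time
        ([1, 2], [2, 0]),           # non-binary event
        ([], []),                   # empty
    ],
)
def test_survival_data_rejects_malformed_input(time, event):
    with pytest.raises(DataError):
        SurvivalData(np.asarray(time, float), np.asarray(event))


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_hand_worked_example():
    s = SurvivalData(np.array([1.0, 2, 3, 4]), np.array([1, 1, 0, 1]))
    km = km_estimate(s)
    assert np.allclose(km.event_times, [1, 2, 4])
    assert np.allclose(km.survival, [3 / 4, 1 / 2, 0.0])
    assert list(km.at_risk) == [4, 3, 1]
    assert list(km.events) == [1, 1, 1]


def test_km_all_censored_is_identically_one():
    s = SurvivalData(np.array([3.0, 5, 9]), np.array([0, 0, 0]))
    km = km_estimate(s)
    assert len(km.event_times) == 0  # no factors: estimate stays at 1


def test_km_doubling_every_record_gives_identical_curve(rng):
    s = random_survival(rng, 25)
    doubled = SurvivalData(np.tile(s.time, 2), np.tile(s.event, 2))
    a, b = km_estimate(s), km_estimate(doubled)
    assert np.allclose(a.event_times, b.event_times)
    assert np.allclose(a.survival, b.survival)


def test_km_without_censoring_equals_one_minus_ecdf(rng):
    time = rng.exponential(10, 40)
    s = SurvivalData(time, np.ones(40, int))
    km = km_estimate(s)
    ecdf = np.searchsorted(np.sort(time), km.event_times, side="right") / 40
    assert np.allclose(km.survival, 1 - ecdf)


# ---------------------------------------------------------------------------
# logrank


def _naive_logrank(a: SurvivalData, b: SurvivalData):
    """Textbook O-E/V logrank by an explicit per-event-time loop."""
    time = np.concatenate([a.time, b.time])
    event = np.concatenate([a.event, b.event])
    grp = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    o = e = v = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & (grp == 0)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (grp == 0)).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v


def test_logrank_identical_groups_gives_zero_statistic(toy_survival):
    res = logrank_test(toy_survival, toy_survival)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_two_sided == pytest.approx(1.0)


@pytest.mark.parametrize("tie_prob", [0.0, 1.0])
def test_logrank_matches_naive_loop_oracle(rng, tie_prob):
    for _ in range(10):
        a = random_survival(rng, 15, tie_prob=tie_prob)
        b = random_survival(rng, 12, tie_prob=tie_prob)
        res = logrank_test(a, b)
        assert res.statistic == pytest.approx(_naive_logrank(a, b), rel=1e-10)


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    for _ in range(5):
        a = random_survival(rng, 20, tie_prob=0.5)
        b = random_survival(rng, 18, tie_prob=0.5)
        res = logrank_test(a, b)
        ref = ll_logrank(a.time, b.time, a.event, b.event)
        assert res.p_two_sided == pytest.approx(ref.p_value, rel=1e-6)


def test_logrank_one_sided_direction_rule():
    # group A dies early, group B is censored late: A is clearly adverse
    a = SurvivalData(np.array([1.0, 2, 3]), np.array([1, 1, 1]))
    b = SurvivalData(np.full(7, 100.0), np.zeros(7, int))
    res_adv = logrank_test(a, b, adverse_group="a")
    assert res_adv.p_one_sided == pytest.approx(res_adv.p_two_sided / 2)
    assert res_adv.p_one_sided < res_adv.p_two_sided
    res_wrong = logrank_test(a, b, adverse_group="b")
    assert res_wrong.p_one_sided == pytest.approx(1 - res_adv.p_two_sided / 2)


def test_logrank_errors():
    s = SurvivalData(np.array([1.0, 2]), np.array([1, 1]))
    with pytest.raises(DataError):
        logrank_test(s, s.subset(np.zeros(2, bool)))
    censored = SurvivalData(np.array([1.0, 2]), np.array([0, 0]))
    with pytest.raises(UndefinedTestError):
        logrank_test(censored, censored)


# ---------------------------------------------------------------------------
# Cox proportional hazards


def test_univariate_identical_groups_hr_one(toy_survival):
    fit = univariate_hr(toy_survival, toy_survival)
    assert fit.hr[0] == pytest.approx(1.0, abs=1e-6)


def test_univariate_label_swap_inverts_hr(rng):
    a, b = random_survival(rng, 30), random_survival(rng, 25)
    f, g = univariate_hr(a, b), univariate_hr(b, a)
    assert f.hr[0] * g.hr[0] == pytest.approx(1.0, abs=1e-9)


def test_univariate_complete_separation_is_non_estimable():
    dead = SurvivalData(np.array([1.0, 2, 3, 4]), np.ones(4, int))
    alive = SurvivalData(np.full(4, 50.0), np.zeros(4, int))
    fit = univariate_hr(dead, alive)
    assert not fit.estimable
    assert fit.message


def test_cox_coefficient_matches_partial_likelihood_oracle(rng):
    """8-case toy: Newton-Raphson solution equals an independent maximizer."""
    x = rng.normal(size=8)
    s = random_survival(rng, 8)
    fit = cox_ph(pd.DataFrame({"x": x}), s)
    res = optimize.minimize_scalar(
        lambda b: -cox_partial_loglik(np.array([b]), x, s),
        bounds=(-10, 10),
        method="bounded",
        options={"xatol": 1e-10},
    )
    assert fit.coef[0] == pytest.approx(res.x, abs=1e-6)


def test_cox_single_binary_covariate_reduces_to_univariate(rng):
    a, b = random_survival(rng, 20), random_survival(rng, 22)
    time = np.concatenate([a.time, b.time])
    event = np.concatenate([a.event, b.event])
    grp = np.concatenate([np.zeros(20), np.ones(22)])
    joint = cox_ph(pd.DataFrame({"g": grp}), SurvivalData(time, event))
    uni = univariate_hr(a, b)
    assert joint.hr[0] == pytest.approx(uni.hr[0], abs=1e-9)


def test_cox_matches_lifelines_without_ties(rng):
    # Efron and Breslow coincide when no event times tie
    from lifelines import CoxPHFitter

    x1, x2 = rng.normal(size=60), rng.normal(size=60)
    s = random_survival(rng, 60)
    df = pd.DataFrame({"t": s.time, "e": s.event, "x1": x1, "x2": x2})
    ref = CoxPHFitter().fit(df, "t", "e")
    fit = cox_ph(df[["x1", "x2"]], s)
    assert np.allclose(fit.coef, ref.params_.to_numpy(), atol=1e-5)
    assert np.allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-5)


def test_cox_returned_coefficients_are_a_local_maximum(rng):
    X = rng.normal(size=(50, 2))
    s = random_survival(rng, 50)
    fit = cox_ph(pd.DataFrame(X, columns=["a", "b"]), s)
    ll = cox_partial_loglik(fit.coef, X, s)
    for _ in range(100):
        assert ll >= cox_partial_loglik(fit.coef + rng.normal(0, 0.1, 2), X, s)


def test_cox_rejects_degenerate_covariates(rng):
    s = random_survival(rng, 20)
    with pytest.raises(SingularMatrixError, match="zeros"):
        cox_ph(pd.DataFrame({"zeros": np.zeros(20)}), s)
    x = rng.normal(size=20)
    with pytest.raises(SingularMatrixError):
        cox_ph(pd.DataFrame({"a": x, "b": 2 * x}), s)
    with pytest.raises(DataError):
        cox_ph(pd.DataFrame({"a": np.r_[np.nan, x[1:]]}), s)


def test_cox_ci_brackets_hr(rng):
    X = rng.normal(size=(80, 2))
    s = random_survival(rng, 80)
    fit = cox_ph(pd.DataFrame(X, columns=["a", "b"]), s)
    assert np.all(fit.ci_lower <= fit.hr) and np.all(fit.hr <= fit.ci_upper)
    assert np.all(fit.hr > 0)


# ---------------------------------------------------------------------------
# Fisher's exact test


def _fisher_oracle(a, b, c, d):
    """Sum of hypergeometric probabilities <= observed (full enumeration)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return pmf[pmf <= p_obs * (1 + 1e-7)].sum()


def test_fisher_balanced_table_p_one():
    assert fisher_exact_2x2([[1, 1], [1, 1]]).p_two_sided == 1.0


def test_fisher_invariances():
    t = [[3, 9], [5, 2]]
    p = fisher_exact_2x2(t).p_two_sided
    assert fisher_exact_2x2(np.transpose(t)).p_two_sided == pytest.approx(p)
    swapped = [[2, 5], [9, 3]]  # simultaneous row and column swap
    assert fisher_exact_2x2(swapped).p_two_sided == pytest.approx(p)


def test_fisher_rejects_bad_counts():
    with pytest.raises(DataError):
        fisher_exact_2x2([[-1, 2], [3, 4]])
    with pytest.raises(DataError):
        fisher_exact_2x2([[0.5, 2], [3, 4]])
    with pytest.raises(DataError):
        fisher_exact_2x2([[0, 0], [0, 0]])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 25)] * 4).filter(lambda t: sum(t) > 0))
def test_fisher_matches_enumeration_oracle(table):
    a, b, c, d = table
    p = fisher_exact_2x2([[a, b], [c, d]]).p_two_sided
    assert p == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12)
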