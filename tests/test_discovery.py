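"""Tests for CV significance profiling, peak selection and cutoff lockdown."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survcut import (
    CutoffSignificanceCV,
    LockedCutoff,
    MaximallySelectedCutoff,
    PercentileCutoff,
    ProfileConfig,
    SignificanceProfile,
    SurvivalData,
    cv_significance_profile,
    find_peaks,
    lock_cutoff,
    maximal_logrank_cutoff,
    percentile_cutoff_value,
    select_supported_peak,
)
from survcut.errors import CohortTooSmallError, ConstraintError, DataError, SpecError
from survcut.stats import _logrank_terms

from conftest import random_survival


def _profile(fracs, grid=None):
    grid = grid or tuple(range(10, 10 + 5 * len(fracs), 5))
    f = np.asarray(fracs, float)
    return SignificanceProfile(
        percentiles=tuple(float(g) for g in grid),
        fraction=f,
        n_significant=(f * 100).astype(int),
        n_valid=np.full(len(f), 100),
        n_reps=100,
        alpha=0.05,
    )


# ---------------------------------------------------------------------------
# configuration contract


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_reps=0),
        dict(alpha=0.0),
        dict(alpha=1.0),
        dict(split_fraction=0.0),
        dict(percentile_grid=(30, 20)),
        dict(percentile_grid=(5, 50)),
        dict(percentile_grid=()),
    ],
)
def test_profile_config_rejects_invalid_settings(kwargs):
    with pytest.raises(SpecError):
        ProfileConfig(**kwargs)


def test_profile_requires_twenty_cases(rng):
    s = random_survival(rng, 15)
    with pytest.raises(CohortTooSmallError):
        cv_significance_profile(rng.normal(size=15), s, n_reps=5)


# ---------------------------------------------------------------------------
# CV profile behaviour


def test_profile_reproducible_and_order_invariant(rng):
    n = 60
    expr = rng.normal(size=n)
    s = random_survival(rng, n)
    cfg = ProfileConfig(n_reps=40, seed=17)
    a = cv_significance_profile(expr, s, cfg)
    b = cv_significance_profile(expr, s, cfg)
    assert np.array_equal(a.n_significant, b.n_significant)

    perm = rng.permutation(n)
    c = cv_significance_profile(expr[perm], s.subset(perm), cfg)
    assert np.array_equal(a.n_significant, c.n_significant)
    assert np.array_equal(a.n_valid, c.n_valid)


def test_profile_estimator_exposes_profile_and_peaks(rng):
    n = 50
    est = CutoffSignificanceCV(n_reps=20, random_state=3)
    est.fit(rng.normal(size=n), random_survival(rng, n))
    assert len(est.profile_.fraction) == 17
    assert all(10 <= p <= 90 for p in est.peaks_)
    assert np.all((0 <= est.profile_.fraction) & (est.profile_.fraction <= 1))


def test_profile_strong_effect_concentrates_near_planted_percentile():
    from survcut import preset, simulate_cohort

    c = simulate_cohort(preset("planted"), seed=6)
    prof = cv_significance_profile(
        c.expression.loc["BAALC"].to_numpy(), c.os, n_reps=1000, seed=6
    )
    assert abs(prof.argmax_percentile() - 30) <= 5


def test_argmax_percentile_tie_break_is_median_position():
    prof = _profile([0.1, 0.9, 0.9, 0.9, 0.2])   # ties at 15, 20, 25
    assert prof.argmax_percentile() == 20
    prof = _profile([0.1, 0.9, 0.9, 0.2])        # even tie: lower middle
    assert prof.argmax_percentile() == 15


# ---------------------------------------------------------------------------
# peaks and verification support


def test_find_peaks_worked_example():
    prof = _profile([1, 5, 2, 3, 9, 4], grid=(10, 15, 20, 25, 30, 35))
    assert find_peaks(prof) == [15, 30]


def test_find_peaks_monotone_and_flat_profiles():
    increasing = _profile([1, 2, 3, 4])
    assert find_peaks(increasing) == [25.0]
    flat = _profile([2, 2, 2, 2])
    assert find_peaks(flat) == []


def test_select_supported_peak_prefers_verified_training_peak():
    grid = tuple(range(10, 95, 5))
    train = np.full(17, 0.01)
    verify = np.full(17, 0.01)
    i30, i75 = grid.index(30), grid.index(75)
    train[i30], train[i75] = 0.23, 0.47
    verify[i30], verify[i75] = 0.23, 0.07
    chosen = select_supported_peak(_profile(train, grid), _profile(verify, grid))
    assert chosen == 30


def test_select_supported_peak_none_without_support():
    grid = (10, 15, 20)
    train = _profile([0.1, 0.5, 0.1], grid)
    verify = _profile([0.02, 0.05, 0.02], grid)
    assert select_supported_peak(train, verify, min_support=0.20) is None
    assert select_supported_peak(train, verify, min_support=0.05) == 15


def test_select_supported_peak_tie_breaks_to_lower_percentile():
    grid = (10, 15, 20, 25, 30)
    train = _profile([0.0, 0.5, 0.1, 0.5, 0.0], grid)
    verify = _profile([0.0, 0.3, 0.0, 0.3, 0.0], grid)
    assert select_supported_peak(train, verify) == 15


def test_select_supported_peak_grid_mismatch():
    with pytest.raises(ValueError):
        select_supported_peak(_profile([1, 2]), _profile([1, 2, 3]))


# ---------------------------------------------------------------------------
# maximal logrank cutoff


def _brute_force_max(expr, s, min_high):
    distinct = np.unique(expr)
    best = (-np.inf, None)
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = (lo + hi) / 2
        mask = expr > thr
        nh = mask.sum()
        if not (min_high <= nh <= len(expr) // 2):
            continue
        o, e, v, _ = _logrank_terms(s.time, s.event, mask)
        stat = 0.0 if v <= 0 else (o - e) ** 2 / v
        if stat > best[0] or (stat == best[0] and thr > best[1]):
            best = (stat, thr)
    return best


def test_maximal_cutoff_perfect_separation_toy():
    expr = np.array([10.0] * 3 + [0.0] * 7)
    s = SurvivalData(
        np.array([1.0, 2, 3] + [100.0] * 7), np.array([1, 1, 1] + [0] * 7)
    )
    cut = maximal_logrank_cutoff(expr, s, min_high=2, gene="EVI1")
    assert cut.threshold == pytest.approx(5.0)
    assert cut.provenance["n_high"] == 3
    assert cut.method == "maximal-logrank"


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_maximal_cutoff_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 61))
    expr = np.round(rng.normal(size=n), 1)  # rounding forces duplicate values
    s = random_survival(rng, n)
    if len(np.unique(expr)) < 3:
        return
    min_high = int(rng.integers(2, 5))
    try:
        cut = maximal_logrank_cutoff(expr, s, min_high=min_high)
    except ConstraintError:
        assert _brute_force_max(expr, s, min_high)[1] is None
        return
    stat, thr = _brute_force_max(expr, s, min_high)
    assert cut.provenance["statistic"] == pytest.approx(stat, rel=1e-12)
    assert cut.threshold == pytest.approx(thr)


def test_maximal_cutoff_lowering_min_high_never_decreases_statistic(rng):
    expr = rng.normal(size=40)
    s = random_survival(rng, 40)
    stats = [
        maximal_logrank_cutoff(expr, s, min_high=mh).provenance["statistic"]
        for mh in (8, 5, 3, 2)
    ]
    assert all(b >= a - 1e-12 for a, b in zip(stats, stats[1:]))


def test_maximal_cutoff_no_candidate_raises():
    expr = np.array([1.0, 1.0, 1.0, 2.0])
    s = SurvivalData(np.array([1.0, 2, 3, 4]), np.array([1, 1, 1, 1]))
    with pytest.raises(ConstraintError):
        maximal_logrank_cutoff(expr, s, min_high=2)


def test_maximal_cutoff_estimator_predict(rng):
    expr = rng.normal(size=30)
    s = random_survival(rng, 30)
    est = MaximallySelectedCutoff(min_high=3).fit(expr, s)
    labels = est.predict(expr)
    assert set(labels) <= {"low", "high"}
    assert (labels == "high").sum() == est.n_high_


# ---------------------------------------------------------------------------
# lockdown


def test_lock_cutoff_matches_percentile_translation(rng):
    expr = rng.normal(size=147)
    cut = lock_cutoff(expr, gene="BAALC", percentile=30, adverse_side="below")
    assert cut.threshold == pytest.approx(percentile_cutoff_value(expr, 30))
    assert cut.percentile == 30
    assert cut.method == "percentile-cv"


def test_lock_cutoff_serialization_roundtrip_classifies_identically(tmp_path, rng):
    expr = rng.normal(size=100)
    cut = lock_cutoff(expr, gene="MN1", percentile=30, adverse_side="above",
                      provenance={"cohort": "synthetic", "seed": 1})
    path = tmp_path / "cutoff.json"
    cut.to_json(path)
    loaded = LockedCutoff.from_json(path)
    cases = rng.normal(size=1000)
    assert np.array_equal(cut.classify(cases), loaded.classify(cases))
    assert loaded.provenance["seed"] == 1


def test_locked_cutoff_validates_fields():
    with pytest.raises(DataError):
        LockedCutoff("g", "percentile-cv", float("nan"), "above")
    with pytest.raises(SpecError):
        LockedCutoff("g", "percentile-cv", 0.0, "sideways")
    with pytest.raises(SpecError):
        LockedCutoff("g", "guesswork", 0.0, "above")


def test_percentile_cutoff_estimator(rng):
    expr = rng.normal(size=80)
    est = PercentileCutoff(percentile=30).fit(expr)
    assert est.threshold_ == pytest.approx(np.percentile(expr, 30))
    labels = est.predict(expr)
    assert (labels == "high").sum() == (expr > est.threshold_).sum()


def test_estimators_are_cloneable():
    from sklearn.base import clone

    for est in (
        CutoffSignificanceCV(n_reps=10),
        MaximallySelectedCutoff(min_high=4),
        PercentileCutoff(percentile=25),
    ):
        c = clone(est)
        assert c.get_params() == est.get_params()
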