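import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirsurv.survival import (
    DegenerateStratificationError,
    SurvivalInputError,
    _efron_terms,
    combo_stratify,
    cox_binary_fit,
    efron_loglik,
    km_curve,
    logrank_test,
    median_stratify,
)

# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def test_median_stratify_basic():
    values = pd.Series([5.0, 1.0, 3.0, 4.0], index=["s1", "s2", "s3", "s4"])
    strat = median_stratify(values, "m")
    assert set(strat.labels[strat.labels == "high"].index) == {"s1", "s4"}
    assert set(strat.labels[strat.labels == "low"].index) == {"s2", "s3"}
    assert strat.thresholds["m"] == 3.5


def test_median_stratify_ties_go_low():
    values = pd.Series([1.0, 2.0, 2.0, 9.0], index=["s1", "s2", "s3", "s4"])
    strat = median_stratify(values, "m")
    assert set(strat.labels[strat.labels == "high"].index) == {"s4"}
    assert strat.n_low == 3


def test_median_stratify_constant_vector_is_degenerate():
    with pytest.raises(DegenerateStratificationError):
        median_stratify(pd.Series([7.0, 7.0, 7.0, 7.0]), "m")


def test_combo_stratify_singleton_identity():
    values = pd.Series([5.0, 1.0, 3.0, 4.0], index=list("abcd"))
    single = median_stratify(values, "m1")
    combo = combo_stratify({"m1": single})
    pd.testing.assert_series_equal(combo.labels, single.labels)


def test_combo_stratify_mixed_label():
    idx = list("abcd")
    s1 = median_stratify(pd.Series([5, 1, 3, 4.0], index=idx), "m1")
    s2 = median_stratify(pd.Series([1, 5, 4, 3.0], index=idx), "m2")
    combo = combo_stratify({"m1": s1, "m2": s2})
    # 'a' is high for m1 but low for m2
    assert combo.labels["a"] == "mixed"
    assert combo.n_high + combo.n_low <= len(idx)


def test_combo_stratify_independent_splits_group_size():
    """Two independent 50/50 splits over 400 samples give E[n_all_high]=100.

    The overlap of two exact half-splits is hypergeometric with
    var = 200 * .5 * .5 * 200/399, sd ~ 5; stay within 3 sd over seeds.
    """
    sd = np.sqrt(200 * 0.25 * 200 / 399)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(400)]
        s1 = median_stratify(pd.Series(rng.normal(size=400), index=idx), "m1")
        s2 = median_stratify(pd.Series(rng.normal(size=400), index=idx), "m2")
        combo = combo_stratify({"m1": s1, "m2": s2})
        assert abs(combo.n_high - 100) < 3 * sd


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_all_censored_flat_at_one():
    curve = km_curve([10, 20, 30], [0, 0, 0])
    assert curve.times.size == 0  # no steps at all


def test_km_no_censoring_product_limit_by_hand():
    curve = km_curve([1, 2, 3], [1, 1, 1])
    np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])


def test_km_single_event():
    curve = km_curve([5], [1])
    assert curve.survival[-1] == 0.0


def test_km_matches_empirical_survival_without_censoring():
    rng = np.random.default_rng(3)
    t = rng.exponential(10, 60)
    curve = km_curve(t, np.ones(60, dtype=int))
    for time, s in zip(curve.times, curve.survival):
        assert s == pytest.approx((t > time).mean())


def test_km_non_increasing_and_bounded(survival_cohort):
    times, events, _ = survival_cohort
    curve = km_curve(times, events)
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all((curve.survival >= 0) & (curve.survival <= 1))


def test_km_agrees_with_lifelines(survival_cohort):
    lifelines = pytest.importorskip("lifelines")
    times, events, _ = survival_cohort
    kmf = lifelines.KaplanMeierFitter().fit(times, events)
    curve = km_curve(times, events)
    for time, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(
            float(kmf.survival_function_at_times(time).iloc[0]))


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    t = [1, 2, 3, 1, 2, 3]
    e = [1, 1, 0, 1, 1, 0]
    g = [True, True, True, False, False, False]
    chi2, p = logrank_test(t, e, g)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_worked_example():
    """Group A events at t=1,2; group B at t=3,4: O_A=2, E_A=5/6, V=17/36."""
    chi2, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1],
                           [True, True, False, False])
    assert chi2 == pytest.approx(2.8824, abs=1e-3)
    assert 0 < p < 1


def test_logrank_errors():
    with pytest.raises(SurvivalInputError, match="one group"):
        logrank_test([1, 2], [1, 1], [True, True])
    with pytest.raises(SurvivalInputError, match="no events"):
        logrank_test([1, 2], [0, 0], [True, False])


def test_logrank_label_swap_invariance(survival_cohort):
    times, events, groups = survival_cohort
    chi2_a, p_a = logrank_test(times, events, groups)
    chi2_b, p_b = logrank_test(times, events, ~groups)
    assert chi2_a == pytest.approx(chi2_b, rel=1e-12)
    assert p_a == pytest.approx(p_b, rel=1e-12)


def test_logrank_invariant_under_monotone_expression_transform(survival_cohort):
    times, events, _ = survival_cohort
    rng = np.random.default_rng(11)
    expr = pd.Series(rng.lognormal(2, 1, len(times)))
    for transform in (np.log, np.sqrt, lambda x: x ** 3):
        g_raw = median_stratify(expr, "m").high_indicator().to_numpy()
        g_tr = median_stratify(pd.Series(transform(expr.to_numpy())),
                               "m").high_indicator().to_numpy()
        np.testing.assert_array_equal(g_raw, g_tr)
        assert logrank_test(times, events, g_raw) == logrank_test(
            times, events, g_tr)


def test_logrank_p_agrees_with_permutation_oracle():
    """Chi-square(1) tail vs relabeling the 30 subjects 2000 times."""
    rng = np.random.default_rng(5)
    n = 30
    groups = np.arange(n) % 2 == 0
    t = rng.exponential(np.where(groups, 50, 100))
    e = (rng.random(n) < 0.8).astype(int)
    chi2_obs, p_asym = logrank_test(t, e, groups)
    perm_stats = []
    for _ in range(2000):
        perm = rng.permutation(groups)
        chi2, _ = logrank_test(t, e, perm)
        perm_stats.append(chi2)
    p_perm = np.mean(np.asarray(perm_stats) >= chi2_obs)
    mc_sd = np.sqrt(p_perm * (1 - p_perm) / 2000) + 1e-4
    assert abs(p_perm - p_asym) < 4 * mc_sd + 0.02


# ---------------------------------------------------------------------------
# Cox fit
# ---------------------------------------------------------------------------

def test_cox_symmetry_gives_zero_beta():
    t = [1, 2, 1, 2]
    e = [1, 1, 1, 1]
    g = [True, True, False, False]
    stats = cox_binary_fit(t, e, g)
    assert stats.beta == pytest.approx(0.0, abs=1e-8)
    assert stats.hr == pytest.approx(1.0, abs=1e-8)


def test_cox_hr_is_exp_beta(survival_cohort):
    times, events, groups = survival_cohort
    stats = cox_binary_fit(times, events, groups)
    assert stats.hr == pytest.approx(np.exp(stats.beta), rel=1e-12)


def test_cox_group_inversion(survival_cohort):
    times, events, groups = survival_cohort
    a = cox_binary_fit(times, events, groups)
    b = cox_binary_fit(times, events, ~groups)
    assert a.hr * b.hr == pytest.approx(1.0, abs=1e-10)


def test_cox_matches_grid_search_oracle():
    """Newton solution maximizes the Efron partial likelihood (dense grid)."""
    rng = np.random.default_rng(21)
    for _ in range(5):
        n = 30
        g = rng.random(n) > 0.5
        g[0], g[1] = True, False
        t = rng.integers(1, 10, n).astype(float)   # heavy ties
        e = (rng.random(n) < 0.7).astype(int)
        e[:2] = 1
        stats = cox_binary_fit(t, e, g)
        if stats.diverged:
            continue
        s_total, A, B = _efron_terms(t, e, g)
        grid = np.arange(-4.0, 4.0, 1e-4)
        beta_star = grid[np.argmax(efron_loglik(grid, s_total, A, B))]
        assert stats.beta == pytest.approx(beta_star, abs=1e-3)


def test_cox_efron_equals_breslow_without_ties():
    """With unique event times the Efron denominators reduce to Breslow's."""
    rng = np.random.default_rng(2)
    n = 25
    t = rng.exponential(10, n)          # continuous: ties a.s. absent
    e = (rng.random(n) < 0.8).astype(int)
    e[0] = 1
    g = rng.random(n) > 0.5
    g[0], g[1] = True, False
    s_total, A, B = _efron_terms(t, e, g)

    # Breslow: one term per event time with full risk-set counts
    event_times = np.unique(t[e == 1])
    A_b, B_b = [], []
    for et in event_times:
        at_risk = t >= et
        A_b.append((at_risk & g).sum())
        B_b.append((at_risk & ~g).sum())
    grid = np.linspace(-2, 2, 9)
    ll_efron = efron_loglik(grid, s_total, A, B)
    ll_breslow = efron_loglik(grid, s_total, np.array(A_b, float),
                              np.array(B_b, float))
    np.testing.assert_allclose(ll_efron, ll_breslow, rtol=1e-12)


def test_cox_monotone_likelihood_flagged_not_raised():
    # every event in the high group, all before any low-group subject exits
    t = [1, 2, 3, 10, 11, 12]
    e = [1, 1, 1, 0, 0, 0]
    g = [True, True, True, False, False, False]
    stats = cox_binary_fit(t, e, g)
    assert stats.diverged
    assert abs(stats.beta) <= 15.0


def test_cox_agrees_with_lifelines(survival_cohort):
    lifelines = pytest.importorskip("lifelines")
    times, events, groups = survival_cohort
    stats = cox_binary_fit(times, events, groups)
    df = pd.DataFrame({"t": times, "e": events, "x": groups.astype(float)})
    cph = lifelines.CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e",
            fit_options={"precision": 1e-12, "max_steps": 500})
    assert stats.beta == pytest.approx(float(cph.params_["x"]), abs=1e-6)


@given(st.integers(min_value=0, max_value=10_000))
def test_cox_beta_sign_matches_observed_minus_expected(seed):
    """The fitted log-HR points the same way as the log-rank O-E sum."""
    rng = np.random.default_rng(seed)
    n = 20
    g = np.arange(n) % 2 == 0
    t = rng.exponential(10, n)
    e = (rng.random(n) < 0.8).astype(int)
    if e.sum() < 2:
        return
    stats = cox_binary_fit(t, e, g)
    if stats.diverged or abs(stats.beta) < 1e-6:
        return
    # reconstruct the O-E sum
    o_minus_e = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        dying = (t == et) & (e == 1)
        o_minus_e += (dying & g).sum() - dying.sum() * (at_risk & g).sum() / at_risk.sum()
    assert np.sign(stats.beta) == np.sign(o_minus_e)
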