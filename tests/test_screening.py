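import numpy as np
import pandas as pd
import pytest

from mirsurv.screening import (
    ComboResult,
    ScreenConfig,
    additive_search,
    passing_oncomirs,
    screen_oncomirs,
    select_best,
    synergy_criterion,
    synergy_screen,
    synergy_union,
)
from mirsurv.simulate import SyntheticConfig, simulate_cohort
from mirsurv.survival import SurvivalStats


def _stats(hr, p, n_high=50, n_low=50):
    return SurvivalStats(beta=float(np.log(hr)), hr=hr, se_beta=0.1,
                         logrank_chi2=1.0, logrank_p=p,
                         n_high=n_high, n_low=n_low, n_events=40)


def test_screen_config_validation():
    with pytest.raises(ValueError):
        ScreenConfig(p_threshold=0.0)
    with pytest.raises(ValueError):
        ScreenConfig(synergy_fold=1.0)


def test_low_expression_fails_regardless_of_survival_signal():
    """A perfectly prognostic miRNA below the RPM floor is filtered out."""
    rng = np.random.default_rng(0)
    n = 100
    # expression values all < 1 RPM but perfectly ordered with survival
    expr = pd.DataFrame([np.linspace(0.01, 0.9, n)], index=["m_low"],
                        columns=[f"s{i}" for i in range(n)])
    time = np.linspace(1000, 10, n)  # high expression -> early death
    clin = pd.DataFrame({"time": time, "event": np.ones(n, dtype=int)},
                        index=expr.columns)
    rec = screen_oncomirs(expr, clin, ScreenConfig())[0]
    assert not rec.passes
    assert "low expression" in rec.reasons
    assert rec.stats is not None and rec.stats.logrank_p < 1e-6


def test_planted_oncomir_recovered_among_nulls():
    """One miRNA with true HR 2.5 among 50 nulls is found in >=90% of seeds."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = SyntheticConfig(n_patients=300, n_mirnas=51,
                              main_effects={"planted": float(np.log(2.5))},
                              low_expression_fraction=0.0, seed=seed)
        expr, clin, _ = simulate_cohort(cfg)
        records = screen_oncomirs(expr, clin, ScreenConfig())
        if "planted" in passing_oncomirs(records):
            hits += 1
    assert hits >= int(0.9 * n_seeds)


@pytest.mark.parametrize("pair_hr, hr_a, hr_b, p, expected", [
    # published synergy table rows: each pair HR clears 1.5x both singles
    (3.09, 1.75, 1.84, 4.33e-5, True),
    (2.82, 1.75, 1.82, 1.45e-4, True),
    (2.95, 1.92, 1.65, 6.58e-5, True),
    (2.64, 1.66, 1.75, 3.13e-4, True),
    # pair HR equal to the larger single fails the fold criterion
    (1.84, 1.75, 1.84, 1e-5, False),
    # significant fold change but non-significant p fails
    (3.5, 1.5, 1.5, 0.2, False),
])
def test_synergy_criterion(pair_hr, hr_a, hr_b, p, expected):
    assert synergy_criterion(pair_hr, hr_a, hr_b, p, ScreenConfig()) is expected


def test_synergy_screen_runs_all_pairs():
    cfg = SyntheticConfig(
        n_patients=200, n_mirnas=3, low_expression_fraction=0.0,
        main_effects={"m1": 0.5, "m2": 0.5, "m3": 0.0}, seed=1)
    expr, clin, _ = simulate_cohort(cfg)
    pairs = synergy_screen(["m1", "m2", "m3"], expr, clin, ScreenConfig())
    assert len(pairs) == 3
    assert {frozenset((p.mirna_a, p.mirna_b)) for p in pairs} == {
        frozenset(("m1", "m2")), frozenset(("m1", "m3")),
        frozenset(("m2", "m3"))}


def test_synergy_union_collects_passing_pairs_only():
    a = _stats(3.0, 1e-4)
    pairs = [
        type("P", (), {"passes": True, "mirna_a": "x", "mirna_b": "y"}),
        type("P", (), {"passes": False, "mirna_a": "y", "mirna_b": "z"}),
    ]
    assert synergy_union(pairs) == ["x", "y"]
    assert a.hr == 3.0  # fixture sanity


def test_additive_search_subset_counts():
    cfg = SyntheticConfig(n_patients=400, n_mirnas=6,
                          low_expression_fraction=0.0,
                          main_effects={f"m{i}": 0.3 for i in range(1, 7)},
                          seed=2)
    expr, clin, _ = simulate_cohort(cfg)
    ids = [f"m{i}" for i in range(1, 7)]
    combos = additive_search(ids, expr, clin, ScreenConfig())
    assert len(combos) == 63                      # 2^6 - 1 non-empty subsets
    assert sum(1 for c in combos if c.k == 3) == 20   # C(6,3)
    # k=1 combos agree with the single-miRNA screen
    records = {r.mirna_id: r for r in screen_oncomirs(expr, clin, ScreenConfig())}
    for combo in combos:
        if combo.k == 1 and combo.stats is not None:
            single = records[combo.mirna_set[0]].stats
            assert combo.stats.hr == pytest.approx(single.hr, rel=1e-12)
            assert combo.stats.logrank_p == pytest.approx(single.logrank_p,
                                                          rel=1e-12)
    # group-size monotonicity: supersets cannot enlarge the all-high group
    by_set = {c.mirna_set: c for c in combos}
    for combo in combos:
        if combo.k >= 2 and combo.stats is not None:
            sub = by_set[combo.mirna_set[:-1]]
            if sub.stats is not None:
                assert combo.stats.n_high <= sub.stats.n_high


def test_planted_triple_attains_max_hr_among_size3_combos():
    """Three miRNAs with pairwise interactions planted among six candidates:
    the planted triple has the largest size-3 all-high/all-low HR in >=80%
    of seeds."""
    beta, gamma = float(np.log(1.3)), float(np.log(2.0))
    trio = ["m1", "m2", "m3"]
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        cfg = SyntheticConfig(
            n_patients=300, n_mirnas=6, low_expression_fraction=0.0,
            main_effects={m: beta for m in trio},
            interaction_effects={("m1", "m2"): gamma, ("m1", "m3"): gamma,
                                 ("m2", "m3"): gamma},
            seed=seed)
        expr, clin, _ = simulate_cohort(cfg)
        combos = additive_search(list(expr.index), expr, clin,
                                 ScreenConfig(max_combo_size=3))
        k3 = [c for c in combos
              if c.k == 3 and not c.degenerate and c.stats is not None]
        best = max(k3, key=lambda c: c.stats.hr)
        hits += best.mirna_set == ("m1", "m2", "m3")
    assert hits >= int(0.8 * n_seeds)


def test_additive_search_combinatorial_guard():
    expr = pd.DataFrame(np.ones((26, 4)),
                        index=[f"m{i}" for i in range(26)],
                        columns=list("abcd"))
    clin = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1]},
                        index=list("abcd"))
    with pytest.raises(ValueError, match="max_combo_size"):
        additive_search([f"m{i}" for i in range(26)], expr, clin,
                        ScreenConfig())


def _combo(mirnas, hr, p, n=50, degenerate=False):
    return ComboResult(mirna_set=tuple(mirnas), k=len(mirnas),
                       stats=_stats(hr, p, n, n),
                       log2_hr=float(np.log2(hr)), degenerate=degenerate)


def test_select_best_max_hr():
    cfg = ScreenConfig()
    best, report = select_best([_combo("ab", 3.0, 0.01),
                                _combo("cd", 2.0, 0.001)], cfg)
    assert best.mirna_set == ("a", "b")
    assert report["n_qualifying"] == 2


def test_select_best_single_qualifier_identity():
    cfg = ScreenConfig()
    best, _ = select_best([_combo("ab", 3.0, 0.01),
                           _combo("cd", 2.0, 0.5)], cfg)
    assert best.mirna_set == ("a", "b")


def test_select_best_tie_breaks_toward_smaller_set():
    cfg = ScreenConfig()
    best, _ = select_best([_combo("abc", 3.0, 0.01),
                           _combo("de", 3.0, 0.01)], cfg)
    assert best.mirna_set == ("d", "e")


def test_select_best_respects_group_size_guard():
    cfg = ScreenConfig()
    best, report = select_best([_combo("ab", 5.0, 0.001, n=5),
                                _combo("cd", 2.0, 0.01, n=50)], cfg)
    assert best.mirna_set == ("c", "d")


def test_select_best_empty_result_with_report():
    cfg = ScreenConfig()
    best, report = select_best([_combo("ab", 0.9, 0.5)], cfg)
    assert best is None
    assert report["reason"] == "no significant combination"
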