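"""Survival stratification, Kaplan-Meier, log-rank, meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncemt.survival import (
    apply_horizon,
    fisher_combine,
    kaplan_meier,
    logrank_test,
    median_stratify,
    meta_analyze,
    quartile_contrast,
    survival_expression_correlation,
)


def _records(times, events, prefix="s"):
    return pd.DataFrame(
        {"time": times, "event": events},
        index=[f"{prefix}{i}" for i in range(len(times))],
    )


# ------------------------------------------------------------- stratification

def test_median_split_examples():
    assert list(median_stratify(pd.Series([1, 2, 3, 4]))) == ["low", "low", "high", "high"]
    labels = median_stratify(pd.Series([1, 2, 2, 3]))
    assert list(labels) == ["low", "low", "low", "high"]  # ties at median go low


def test_median_split_odd_n_balance(rng):
    for _ in range(20):
        v = pd.Series(rng.normal(size=11))
        labels = median_stratify(v)
        assert abs((labels == "high").sum() - (labels == "low").sum()) <= 1


def test_median_split_rejects_degenerate_input():
    with pytest.raises(ValueError, match="at least 2"):
        median_stratify(pd.Series([1.0]))
    with pytest.raises(ValueError, match="all values equal"):
        median_stratify(pd.Series([2.0, 2.0, 2.0]))


def test_horizon_censoring():
    sv = apply_horizon(_records([10, 70, 80], [1, 1, 0]), horizon=60)
    assert list(sv["time"]) == [10, 60, 60]
    assert list(sv["event"]) == [1, 0, 0]


# -------------------------------------------------------------- Kaplan-Meier

def test_km_no_events_stays_at_one():
    km = kaplan_meier(_records([5, 10, 15], [0, 0, 0]))
    assert (km["survival"] == 1.0).all()


def test_km_single_event():
    km = kaplan_meier(_records([5, 8], [1, 0])).set_index("time")
    assert km.loc[0.0, "survival"] == 1.0
    assert km.loc[5.0, "survival"] == pytest.approx(0.5)


def test_km_matches_hand_computed_product_limit():
    # events at 1, 2, 4, 6; censored at 3 and 5
    km = kaplan_meier(_records([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])).set_index("time")
    assert km.loc[1.0, "survival"] == pytest.approx(5 / 6)
    assert km.loc[2.0, "survival"] == pytest.approx(5 / 6 * 4 / 5)
    assert km.loc[4.0, "survival"] == pytest.approx(5 / 6 * 4 / 5 * 2 / 3)
    assert km.loc[6.0, "survival"] == pytest.approx(0.0)


def test_km_is_monotone_step_function(rng):
    sv = _records(rng.exponential(20, 50), rng.integers(0, 2, 50))
    km = kaplan_meier(sv)
    assert np.all(np.diff(km["survival"]) <= 1e-12)
    assert km["survival"].iloc[0] == 1.0
    with pytest.raises(ValueError, match="negative"):
        kaplan_meier(_records([-1], [1]))


# ------------------------------------------------------------------ log-rank

def _logrank_oracle(ta, ea, tb, eb):
    """Hand computation of sum(O-E) and variance over distinct event times."""
    times = sorted(set(list(ta[ea == 1]) + list(tb[eb == 1])))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        na = ((ta >= t)).sum()
        nb = ((tb >= t)).sum()
        da = ((ta == t) & (ea == 1)).sum()
        db = ((tb == t) & (eb == 1)).sum()
        n, d = na + nb, da + db
        e_a = d * na / n
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, stats.chi2.sf(chi2, 1)


def test_logrank_identical_groups():
    g = _records([2, 4, 6, 8], [1, 1, 0, 1])
    chi2, p = logrank_test(g, g.copy())
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_oracle():
    ga = _records([1, 3, 5, 7], [1, 1, 1, 0], "a")
    gb = _records([2, 4, 6, 8], [1, 0, 1, 1], "b")
    chi2, p = logrank_test(ga, gb)
    exp_chi2, exp_p = _logrank_oracle(
        ga["time"].to_numpy(), ga["event"].to_numpy(),
        gb["time"].to_numpy(), gb["event"].to_numpy(),
    )
    assert chi2 == pytest.approx(exp_chi2, rel=1e-6)
    assert p == pytest.approx(exp_p, rel=1e-6)


def test_logrank_label_swap_invariance(rng):
    ga = _records(rng.exponential(20, 30), rng.integers(0, 2, 30), "a")
    gb = _records(rng.exponential(10, 30), rng.integers(0, 2, 30), "b")
    assert logrank_test(ga, gb)[0] == pytest.approx(logrank_test(gb, ga)[0])


def test_logrank_power_under_threefold_hazard(rng):
    rejections = 0
    for _ in range(200):
        ta = rng.exponential(30, 100)
        tb = rng.exponential(10, 100)
        cens = 40.0
        ga = _records(np.minimum(ta, cens), (ta <= cens).astype(int), "a")
        gb = _records(np.minimum(tb, cens), (tb <= cens).astype(int), "b")
        if logrank_test(ga, gb)[1] < 0.05:
            rejections += 1
    assert rejections / 200 > 0.8


def test_logrank_warns_without_events():
    g = _records([5, 6], [0, 0])
    with pytest.warns(RuntimeWarning, match="no events"):
        chi2, p = logrank_test(g, g.copy())
    assert p == 1.0


# ------------------------------------------- expression-survival correlation

def test_expression_time_correlation_perfect_negative():
    sv = _records([1, 2, 3, 4], [1, 1, 1, 1])
    expr = pd.Series([-1, -2, -3, -4.0], index=sv.index)
    rho, _ = survival_expression_correlation(sv, expr)
    assert rho == pytest.approx(-1.0)


def test_expression_time_correlation_null_uniform(rng):
    sv = _records(rng.exponential(20, 40), np.ones(40, int))
    ps = []
    for _ in range(200):
        expr = pd.Series(rng.normal(size=40), index=sv.index)
        ps.append(survival_expression_correlation(sv, expr)[1])
    assert stats.kstest(ps, "uniform").pvalue > 0.001


def test_expression_time_correlation_input_checks():
    sv = _records([1, 2, 3, 4], [1, 1, 0, 0])
    const = pd.Series([1.0, 1.0, 1.0, 1.0], index=sv.index)
    with pytest.raises(ValueError, match="fewer than 3 events"):
        survival_expression_correlation(sv, const)
    sv_all = _records([1, 2, 3, 4], [1, 1, 1, 1])
    with pytest.raises(ValueError, match="constant"):
        survival_expression_correlation(sv_all, const)


# ---------------------------------------------------------- quartile contrast

def test_quartile_groups_of_two_from_eight_samples():
    strat = pd.Series(np.arange(1.0, 9.0), index=[f"s{i}" for i in range(8)])
    expr = pd.DataFrame(
        [np.arange(8.0)], index=["g"], columns=strat.index
    )
    res = quartile_contrast(expr, strat)
    # gene tracks the stratifier, so low-vs-high contrast is strongly negative
    assert res.loc["g", "log2_fold_change"] < 0


def test_quartile_contrast_recovers_planted_sign(rng):
    hits = 0
    for _ in range(50):
        strat = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        gene = 0.8 * strat + 0.3 * rng.normal(size=40)
        expr = pd.DataFrame([np.exp2(3 + gene)], index=["g"], columns=strat.index)
        res = quartile_contrast(expr, strat)
        hits += res.loc["g", "log2_fold_change"] < 0
    assert hits / 50 >= 0.95


def test_quartile_contrast_needs_two_per_group():
    strat = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    expr = pd.DataFrame([[1, 2, 3.0]], index=["g"], columns=strat.index)
    with pytest.raises(ValueError):
        quartile_contrast(expr, strat)


# ----------------------------------------------------------- Fisher's method

def test_fisher_combination_worked_cases():
    assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
    assert fisher_combine([0.3]) == pytest.approx(0.3, rel=1e-12)  # chi2_2 identity
    x = -2 * np.log(0.05) * 2
    assert x == pytest.approx(11.98, abs=0.01)
    assert fisher_combine([0.05, 0.05]) == pytest.approx(
        stats.chi2.sf(x, 4), rel=1e-12
    )
    assert fisher_combine([0.05, 0.05]) == pytest.approx(0.0175, abs=5e-4)


def test_fisher_floors_zero_with_warning():
    with pytest.warns(RuntimeWarning, match="floored"):
        p = fisher_combine([0.0, 0.5])
    assert 0 < p < 1e-100


def test_fisher_null_uniform(rng):
    combined = [fisher_combine(rng.uniform(size=5)) for _ in range(2000)]
    assert stats.kstest(combined, "uniform").pvalue > 0.01


def test_meta_analysis_direction_gating():
    a = pd.DataFrame(
        {"log2_fold_change": [1.2, 0.8], "p_value": [0.01, 0.04]}, index=["g1", "g2"]
    )
    b = pd.DataFrame(
        {"log2_fold_change": [0.9, -0.5], "p_value": [0.02, 0.03]}, index=["g1", "g2"]
    )
    res = meta_analyze({"d1": a, "d2": b})
    assert res.loc["g1", "direction_consistent"]
    assert res.loc["g1", "combined_p"] == pytest.approx(fisher_combine([0.01, 0.02]))
    assert not res.loc["g2", "direction_consistent"]
    assert np.isnan(res.loc["g2", "combined_p"])
    with pytest.raises(ValueError, match="at least 2"):
        meta_analyze({"d1": a})
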