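"""Differential expression: exact NB test, Welch t, BH adjustment, status calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lncemt.de import (
    DE,
    NON_DE,
    AMBIGUOUS,
    bh_adjust,
    classify_de,
    de_exact_test,
    de_ttest,
)
from lncemt.synthetic import SyntheticConfig, generate_cohort
from conftest import make_subtype


# ---------------------------------------------------------------- exact test

def test_identical_groups_give_p_one_and_zero_fc():
    counts = pd.DataFrame(
        {"e1": [5, 10], "e2": [8, 7], "m1": [5, 10], "m2": [8, 7]},
        index=["gA", "gB"],
    )
    res = de_exact_test(counts, make_subtype(2, 2, list(counts.columns)))
    assert np.allclose(res["log2_fold_change"], 0.0)
    assert np.allclose(res["p_value"], 1.0)


def _binomial_two_sided(total, observed, p=0.5):
    """Enumeration oracle: sum binomial probabilities <= that of the observed split."""
    pmf = [math.comb(total, k) * p**k * (1 - p) ** (total - k) for k in range(total + 1)]
    obs = pmf[observed]
    return sum(q for q in pmf if q <= obs * (1 + 1e-12))


@pytest.mark.parametrize("counts_ab", [(9, 1), (5, 5), (10, 0), (7, 3)])
def test_vanishing_dispersion_reduces_to_binomial_conditioning(counts_ab):
    """With dispersion -> 0 and equal library sizes the conditional test is binomial."""
    a, b = counts_ab
    # second gene balances the library sizes so normalization is the identity
    counts = pd.DataFrame({"s1": [a, 10 - a], "s2": [b, 10 - b]}, index=["g", "filler"])
    res = de_exact_test(counts, make_subtype(1, 1, ["s1", "s2"]), dispersion=1e-9)
    expected = _binomial_two_sided(a + b, a)
    assert res.loc["g", "p_value"] == pytest.approx(expected, rel=1e-3)


def test_planted_fold_change_recovered():
    """Planted regulator shift appears in target genes at the expected magnitude."""
    cfg = SyntheticConfig(
        n_epithelial=50, n_mesenchymal=50, beta_lnc=1.0, de_log2fc=2.0, seed=31
    )
    cohort, truth = generate_cohort(cfg)
    res = de_exact_test(cohort.mrna_counts, cohort.subtype)
    med = res.loc[sorted(truth.de_genes), "log2_fold_change"].abs().median()
    assert med == pytest.approx(2.0, abs=0.3)


def test_exact_test_null_p_values_near_uniform(rng):
    """Null NB counts give approximately uniform p (Kolmogorov D below 0.05)."""
    lam = rng.gamma(1 / 0.15, 25 * 0.15, (2000, 30))
    counts = pd.DataFrame(
        rng.poisson(lam), index=[f"g{i}" for i in range(2000)],
        columns=[f"s{i}" for i in range(30)],
    )
    res = de_exact_test(counts, make_subtype(15, 15, list(counts.columns)))
    d = stats.kstest(res["p_value"], "uniform").statistic
    assert d < 0.05


def test_exact_test_input_validation():
    counts = pd.DataFrame({"s1": [1.5], "s2": [2.0]}, index=["g"])
    with pytest.raises(ValueError, match="integer"):
        de_exact_test(counts, make_subtype(1, 1, ["s1", "s2"]))
    zero = pd.DataFrame({"s1": [0], "s2": [3]}, index=["g"])
    with pytest.raises(ValueError, match="zero total"):
        de_exact_test(zero, make_subtype(1, 1, ["s1", "s2"]))


# ------------------------------------------------------------------- t-test

def test_welch_matches_hand_computation():
    """p agrees with the Welch statistic and Welch-Satterthwaite df computed longhand."""
    a = np.array([3.1, 4.5, 2.2])  # mesenchymal
    b = np.array([1.0, 1.4, 0.9])  # epithelial
    expr = pd.DataFrame([np.r_[b, a]], index=["f"],
                        columns=["e1", "e2", "e3", "m1", "m2", "m3"])
    res = de_ttest(expr, make_subtype(3, 3, list(expr.columns)), log_transform=False)
    va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
    expected = 2 * stats.t.sf(abs(t), df)
    assert res.loc["f", "p_value"] == pytest.approx(expected, rel=1e-10)


def test_one_tailed_is_half_two_tailed_in_hypothesized_direction():
    expr = pd.DataFrame(
        [[1.0, 2.0, 1.5, 5.0, 6.0, 5.5]], index=["f"],
        columns=["e1", "e2", "e3", "m1", "m2", "m3"],
    )
    sub = make_subtype(3, 3, list(expr.columns))
    two = de_ttest(expr, sub).loc["f", "p_value"]
    one = de_ttest(expr, sub, alternative="greater").loc["f", "p_value"]
    assert one == pytest.approx(two / 2, rel=1e-12)


def test_degenerate_variance_warns_and_sets_p_one():
    expr = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["f"],
                        columns=["e1", "e2", "m1", "m2"])
    with pytest.warns(RuntimeWarning, match="zero variance"):
        res = de_ttest(expr, make_subtype(2, 2, list(expr.columns)))
    assert res.loc["f", "p_value"] == 1.0


# ------------------------------------------------------------------------ BH

def _bh_oracle(p):
    """Brute-force step-up: q_i = min_{j: p_j >= p_i} p_j * m / rank_j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = running
    return q


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.4], [0.4]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_worked_examples(p, expected):
    assert bh_adjust(p) == pytest.approx(expected)


@settings(max_examples=200, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40))
def test_bh_matches_bruteforce_and_is_monotone(p):
    q = bh_adjust(p)
    assert q == pytest.approx(_bh_oracle(np.asarray(p)))
    assert np.all(q >= np.asarray(p) - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bh_adjust([0.1, np.nan])


# ------------------------------------------------------------------ classify

@pytest.mark.parametrize(
    "lfc, adj, expected",
    [
        (1.0, 1e-4, DE),          # boundary fold change is inclusive
        (0.2, 0.5, NON_DE),
        (3.0, 0.1, AMBIGUOUS),    # between the significance cutoffs
        (0.5, 1e-5, AMBIGUOUS),   # significant but below fold change
    ],
)
def test_classification_rules(lfc, adj, expected):
    df = pd.DataFrame(
        {"log2_fold_change": [lfc], "p_value": [adj / 2], "adjusted_p": [adj]},
        index=["g"],
    )
    out = classify_de(df, de_alpha=1e-3)
    assert out.loc["g", "status"] == expected


def test_de_and_nonde_are_disjoint(rng):
    df = pd.DataFrame(
        {
            "log2_fold_change": rng.normal(0, 2, 500),
            "p_value": rng.uniform(size=500),
        }
    )
    df["adjusted_p"] = bh_adjust(df["p_value"])
    out = classify_de(df, de_alpha=0.05)
    assert not ((out["status"] == DE) & (out["status"] == NON_DE)).any()
    assert set(out["status"]) <= {DE, NON_DE, AMBIGUOUS}
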