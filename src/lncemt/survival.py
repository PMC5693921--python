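"""Survival stratification and cross-dataset meta-analysis of expression changes.

Samples are split at the median expression of a stratifying lncRNA (ties go
to the low group), survival is administratively censored at a five-year
horizon (60 months), curves are Kaplan-Meier product-limit estimates, and
groups are compared with the log-rank test.  Cross-dataset evidence for a
gene's deregulation is pooled with Fisher's combined probability test,
combining only datasets whose fold-change directions agree.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .de import bh_adjust

__all__ = [
    "median_stratify",
    "apply_horizon",
    "kaplan_meier",
    "logrank_test",
    "survival_expression_correlation",
    "quartile_contrast",
    "fisher_combine",
    "meta_analyze",
]

HIGH = "high"
LOW = "low"


def median_stratify(values) -> pd.Series:
    """Label samples 'high' (> median) or 'low' (< median; ties at median low)."""
    v = pd.Series(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 samples to stratify")
    med = v.median()
    if (v == v.iloc[0]).all():
        raise ValueError("all values equal: stratification undefined")
    return pd.Series(np.where(v > med, HIGH, LOW), index=v.index, name="stratum")


def apply_horizon(
    survival: pd.DataFrame, horizon: float = 60.0
) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon`` months."""
    out = survival.copy()
    over = out["time"] > horizon
    out.loc[over, "time"] = horizon
    out.loc[over, "event"] = 0
    return out


def kaplan_meier(survival: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve S(t).

    Returns a DataFrame with columns ``time`` and ``survival`` giving the
    right-continuous step function (S = 1 before the first event).
    """
    if len(survival) < 1:
        raise ValueError("need at least one record")
    if (survival["time"] < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(survival["time"], survival["event"])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p from chi2 with 1 df)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if group_a["event"].sum() == 0 and group_b["event"].sum() == 0:
        warnings.warn("no events in either group; p set to 1", RuntimeWarning, stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(
        group_a["time"], group_b["time"], group_a["event"], group_b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def survival_expression_correlation(
    survival: pd.DataFrame, expression: pd.Series, events_only: bool = True
) -> tuple[float, float]:
    """Spearman correlation between expression and survival time.

    By default only samples with an observed event are used, since censored
    times understate survival; the all-samples mode is available but biased
    by censoring.
    """
    df = survival.join(expression.rename("expr"), how="inner")
    if events_only:
        df = df[df["event"] == 1]
        if len(df) < 3:
            raise ValueError("fewer than 3 events for correlation")
    elif len(df) < 3:
        raise ValueError("fewer than 3 records")
    if df["expr"].nunique() == 1:
        raise ValueError("constant expression: correlation undefined")
    res = stats.spearmanr(df["expr"], df["time"])
    return float(res.statistic), float(res.pvalue)


def quartile_contrast(
    expr_matrix: pd.DataFrame, stratifier_values: pd.Series, genes=None
) -> pd.DataFrame:
    """Per-gene expression change, lowest vs highest stratifier quartile.

    Samples at or below Q1 of the stratifier form the low group, at or above
    Q3 the high group; each gene gets a Welch t-test on log2(x + 1) with
    log2FC oriented low-quartile minus high-quartile.
    """
    strat = stratifier_values.loc[expr_matrix.columns]
    if len(strat) < 4:
        raise ValueError("need at least 4 samples for quartile stratification")
    q1, q3 = strat.quantile(0.25), strat.quantile(0.75)
    low = strat.index[strat <= q1]
    high = strat.index[strat >= q3]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("a quartile group has fewer than 2 samples")
    sub = expr_matrix if genes is None else expr_matrix.loc[list(genes)]
    a = np.log2(sub[low].to_numpy(float) + 1.0)
    b = np.log2(sub[high].to_numpy(float) + 1.0)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(np.asarray(res.pvalue, float), nan=1.0)
    return pd.DataFrame(
        {"log2_fold_change": a.mean(axis=1) - b.mean(axis=1), "p_value": p},
        index=sub.index,
    )


def fisher_combine(p_values) -> float:
    """Fisher's combined probability: -2 sum(ln p) ~ chi2 with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("zero p-value floored at 1e-300", RuntimeWarning, stacklevel=2)
        p = np.maximum(p, 1e-300)
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def meta_analyze(per_dataset: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-dataset gene fold changes and p-values across cohorts.

    Each value of ``per_dataset`` is a DataFrame indexed by gene with columns
    ``log2_fold_change`` and ``p_value``.  Genes measured in at least two
    datasets get a Fisher-combined p when all fold-change directions agree;
    discordant genes are flagged and left uncombined.
    """
    if len(per_dataset) < 2:
        raise ValueError("meta-analysis requires at least 2 datasets")
    genes = sorted(set.intersection(*(set(df.index) for df in per_dataset.values())))
    rows = []
    for gene in genes:
        fcs = np.array([df.loc[gene, "log2_fold_change"] for df in per_dataset.values()])
        ps = np.array([df.loc[gene, "p_value"] for df in per_dataset.values()])
        consistent = bool(np.all(fcs > 0) or np.all(fcs < 0))
        rows.append(
            {
                "gene": gene,
                "mean_log2_fold_change": fcs.mean(),
                "direction_consistent": consistent,
                "combined_p": fisher_combine(ps) if consistent else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["direction_consistent"]
    if ok.any():
        out.loc[ok, "adjusted_combined_p"] = bh_adjust(
            out.loc[ok, "combined_p"].to_numpy()
        )
    return out
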