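"""Per-(gene, lncRNA) multivariate linear screen for lncRNA-associated genes.

For each candidate gene i and lncRNA k an ordinary-least-squares model

    y_i = b0 + b_dm * x_dm_i + b_cn * x_cn_i + b_lnc * x_lnc_k + eps

is fitted, where y is log2(RPKM + 1) gene expression, x_dm the centred
promoter methylation beta-value, x_cn the copy-number level, and x_lnc the
lncRNA's log2(RPKM + 1) expression.  The coefficient of interest is b_lnc.
By default response and predictors are z-scored per pair so that the
universal |b_lnc| >= 0.3 cutoff is on a common (correlation-like) scale
across genes; a raw-scale mode is available.  Each lncRNA enters its own
model (one lncRNA term per fit), iterated over the full candidate grid, and
p-values are BH-adjusted over all tested pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OmicsCohort, gene_level_methylation, offset_beta
from .de import bh_adjust

__all__ = ["RegressionAssociation", "fit_gene_lncrna_model", "screen_associations"]


@dataclass
class RegressionAssociation:
    """One fitted gene ~ methylation + copy number + lncRNA model."""

    gene: str
    lncrna: str
    beta0: float
    beta_dm: float
    beta_cn: float
    beta_lnc: float
    p_lnc: float
    dropped: tuple[str, ...] = ()


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def fit_gene_lncrna_model(
    y,
    x_dm,
    x_cn,
    x_lnc,
    standardize: bool = True,
    gene: str = "gene",
    lncrna: str = "lncrna",
) -> RegressionAssociation:
    """Fit one gene-lncRNA model and test the lncRNA coefficient.

    Constant (rank-deficient) predictors are dropped from the design and
    recorded in ``dropped``; the t-test for b_lnc uses n - 4 residual degrees
    of freedom for the full design (n - k when columns were dropped).
    """
    y = np.asarray(y, float)
    n = len(y)
    if n <= 4:
        raise ValueError("need more than 4 samples (no residual df)")
    preds = {
        "dm": np.asarray(x_dm, float),
        "cn": np.asarray(x_cn, float),
        "lnc": np.asarray(x_lnc, float),
    }
    for name, v in preds.items():
        if len(v) != n:
            raise ValueError(f"predictor {name} is not sample-aligned")
    if np.std(y) == 0:
        raise ValueError("constant response: model undefined")

    dropped = tuple(name for name, v in preds.items() if np.std(v) == 0)
    if standardize:
        y = _zscore(y)
        preds = {k: _zscore(v) for k, v in preds.items()}
    keep = [k for k in ("dm", "cn", "lnc") if k not in dropped]
    X = np.column_stack([np.ones(n)] + [preds[k] for k in keep])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    df = n - X.shape[1]
    resid = y - X @ coef
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.pinv(X.T @ X)

    betas = {"dm": 0.0, "cn": 0.0, "lnc": 0.0}
    for j, k in enumerate(keep, start=1):
        betas[k] = coef[j]
    if "lnc" in dropped:
        p_lnc = 1.0
    else:
        j = keep.index("lnc") + 1
        se = np.sqrt(sigma2 * xtx_inv[j, j])
        if se == 0:
            p_lnc = 0.0 if betas["lnc"] != 0 else 1.0
        else:
            p_lnc = 2 * stats.t.sf(abs(betas["lnc"] / se), df)
    return RegressionAssociation(
        gene=gene,
        lncrna=lncrna,
        beta0=float(coef[0]),
        beta_dm=float(betas["dm"]),
        beta_cn=float(betas["cn"]),
        beta_lnc=float(betas["lnc"]),
        p_lnc=float(p_lnc),
        dropped=dropped,
    )


def _batched_fit(
    Y: np.ndarray, DM: np.ndarray, CN: np.ndarray, lnc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve all per-gene OLS fits against one lncRNA in a single batch.

    Returns (coef, p_lnc) with coef of shape (G, 4) ordered as
    [intercept, dm, cn, lnc].
    """
    G, n = Y.shape
    ones = np.ones(n)
    # per-gene design: columns [1, dm_g, cn_g, lnc]; assemble X'X and X'y
    XtX = np.empty((G, 4, 4))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = DM @ ones
    XtX[:, 0, 2] = XtX[:, 2, 0] = CN @ ones
    XtX[:, 0, 3] = XtX[:, 3, 0] = lnc.sum()
    XtX[:, 1, 1] = np.einsum("ij,ij->i", DM, DM)
    XtX[:, 1, 2] = XtX[:, 2, 1] = np.einsum("ij,ij->i", DM, CN)
    XtX[:, 1, 3] = XtX[:, 3, 1] = DM @ lnc
    XtX[:, 2, 2] = np.einsum("ij,ij->i", CN, CN)
    XtX[:, 2, 3] = XtX[:, 3, 2] = CN @ lnc
    XtX[:, 3, 3] = lnc @ lnc
    Xty = np.empty((G, 4))
    Xty[:, 0] = Y @ ones
    Xty[:, 1] = np.einsum("ij,ij->i", Y, DM)
    Xty[:, 2] = np.einsum("ij,ij->i", Y, CN)
    Xty[:, 3] = Y @ lnc

    try:
        coef = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        # singular designs (constant predictors): fall back to pinv per gene
        inv = np.stack([np.linalg.pinv(m) for m in XtX])
        coef = np.einsum("gij,gj->gi", inv, Xty)

    df = n - 4
    rss = np.einsum("ij,ij->i", Y, Y) - np.einsum("gi,gi->g", coef, Xty)
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(np.maximum(sigma2 * inv[:, 3, 3], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef[:, 3] / se, np.inf * np.sign(coef[:, 3]))
    p = 2 * stats.t.sf(np.abs(tstat), df)
    p[~np.isfinite(tstat)] = np.where(coef[~np.isfinite(tstat), 3] != 0, 0.0, 1.0)
    return coef, p


def screen_associations(
    cohort: OmicsCohort,
    candidate_genes=None,
    candidate_lncrnas=None,
    coef_cutoff: float = 0.3,
    alpha: float = 1e-6,
    standardize: bool = True,
    bh_per_lncrna: bool = False,
) -> pd.DataFrame:
    """Fit the full gene x lncRNA grid and flag significant associations.

    Methylation is collapsed to one representative probe per gene and offset
    to the centred scale if the cohort has not been offset yet.  The returned
    table has one row per tested pair with the fitted coefficients, the
    lncRNA-coefficient p-value, its BH adjustment over the full grid (or per
    lncRNA when ``bh_per_lncrna``), and a ``flagged`` column implementing
    |beta_lnc| >= coef_cutoff and adjusted p < alpha.
    """
    genes = list(candidate_genes) if candidate_genes is not None else list(cohort.genes)
    lncs = (
        list(candidate_lncrnas)
        if candidate_lncrnas is not None
        else list(cohort.lncrnas)
    )
    if not genes or not lncs:
        raise ValueError("empty candidate gene or lncRNA list")
    n = len(cohort.samples)
    if n <= 4:
        raise ValueError("need more than 4 samples")

    meth = gene_level_methylation(cohort)
    if not cohort.methylation_offset:
        meth = offset_beta(meth)
    genes = [g for g in genes if g in meth.index]

    Y = np.log2(cohort.mrna_expr.loc[genes].to_numpy(float) + 1.0)
    DM = meth.loc[genes].to_numpy(float)
    CN = cohort.copy_number.loc[genes].to_numpy(float)
    L = np.log2(cohort.lncrna_expr.loc[lncs].to_numpy(float) + 1.0)

    if standardize:
        def rowz(M):
            sd = M.std(axis=1, ddof=1, keepdims=True)
            out = (M - M.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
            out[sd[:, 0] == 0] = 0.0
            return out

        Y, DM, CN, L = rowz(Y), rowz(DM), rowz(CN), rowz(L)

    frames = []
    for li, lnc in enumerate(lncs):
        coef, p = _batched_fit(Y, DM, CN, L[li])
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "lncrna": lnc,
                    "beta0": coef[:, 0],
                    "beta_dm": coef[:, 1],
                    "beta_cn": coef[:, 2],
                    "beta_lnc": coef[:, 3],
                    "p_lnc": p,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if bh_per_lncrna:
        table["adj_p_lnc"] = table.groupby("lncrna")["p_lnc"].transform(bh_adjust)
    else:
        table["adj_p_lnc"] = bh_adjust(table["p_lnc"].to_numpy())
    table["flagged"] = (table["beta_lnc"].abs() >= coef_cutoff) & (
        table["adj_p_lnc"] < alpha
    )
    return table
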