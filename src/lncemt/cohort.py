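"""Matched multi-omic cohort container, readers, and detection filters.

A cohort bundles feature-by-sample matrices (mRNA counts and RPKM, lncRNA
RPKM, gene copy number, promoter methylation beta-values) over one shared,
ordered sample set, together with subtype labels and optional survival
follow-up.  Loading takes the sample intersection across all layers and keeps
only genes present in every gene-level layer (expression, copy number, and
methylation through the probe map).

Detection filters follow common practice for tumour RNA-seq: a lncRNA is
"detected" when its median RPKM is positive and its 90th percentile exceeds
0.1; an mRNA is "expressed" when at least 75% of samples reach a normalized
value of 1.  Methylation beta-values in [0, 1] are shifted by -0.5 so that
the regression covariate is centred, and genes with several promoter probes
are represented by the probe most anti-correlated with the gene's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EPITHELIAL = "epithelial"
MESENCHYMAL = "mesenchymal"
SUBTYPES = (EPITHELIAL, MESENCHYMAL)


@dataclass
class OmicsCohort:
    """Aligned multi-omic matrices over one ordered sample set.

    All matrices are features x samples with identical, identically ordered
    columns.  ``methylation`` rows are probes; ``probe_map`` maps each probe
    to its gene (the identity map when probes are stored per gene).
    ``methylation_offset`` records whether beta-values have already been
    shifted to the [-0.5, 0.5] scale.
    """

    mrna_counts: pd.DataFrame
    mrna_expr: pd.DataFrame
    lncrna_expr: pd.DataFrame
    copy_number: pd.DataFrame
    methylation: pd.DataFrame
    probe_map: dict[str, str]
    subtype: pd.Series
    survival: pd.DataFrame | None = None
    methylation_offset: bool = False

    @property
    def samples(self) -> pd.Index:
        return self.mrna_expr.columns

    @property
    def genes(self) -> pd.Index:
        return self.mrna_expr.index

    @property
    def lncrnas(self) -> pd.Index:
        return self.lncrna_expr.index

    def validate(self) -> None:
        """Check cross-matrix alignment and declared value ranges."""
        cols = list(self.mrna_expr.columns)
        for name in ("mrna_counts", "lncrna_expr", "copy_number", "methylation"):
            other = getattr(self, name)
            if list(other.columns) != cols:
                raise ValueError(f"sample set of {name} differs from mrna_expr")
        if list(self.subtype.index) != cols:
            raise ValueError("subtype labels do not match the sample set")
        bad = set(self.subtype) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")
        m = self.methylation.to_numpy(float)
        lo, hi = (-0.5, 0.5) if self.methylation_offset else (0.0, 1.0)
        if np.nanmin(m) < lo - 1e-12 or np.nanmax(m) > hi + 1e-12:
            raise ValueError(
                f"methylation values outside declared [{lo}, {hi}] scale"
            )
        unknown = set(self.probe_map.values()) - set(self.genes)
        if unknown:
            raise ValueError(f"probes map to unknown genes: {sorted(unknown)[:5]}")
        if self.survival is not None:
            if (self.survival["time"] < 0).any():
                raise ValueError("negative survival time")
            if not self.survival["event"].isin([0, 1]).all():
                raise ValueError("survival event flags must be 0/1")


def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate feature ids in {path.name}: {dup}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path.name}: {exc}") from exc
    return df


def load_cohort(directory: str | Path) -> OmicsCohort:
    """Read a cohort directory of TSV matrices and align all layers.

    Required files: ``mrna_counts.tsv``, ``mrna_rpkm.tsv``, ``lncrna_rpkm.tsv``,
    ``copy_number.tsv``, ``methylation_beta.tsv``, ``samples.tsv``.  Optional:
    ``probe_map.tsv`` (two columns probe_id, gene_id; identity assumed when
    absent) and ``survival.tsv`` (sample_id, time, event).

    The sample set is the intersection of all matrices, ordered as in
    ``mrna_rpkm.tsv``; genes absent from any gene-level layer are dropped with
    a logged count.
    """
    directory = Path(directory)
    required = {
        "mrna_counts": "mrna_counts.tsv",
        "mrna_expr": "mrna_rpkm.tsv",
        "lncrna_expr": "lncrna_rpkm.tsv",
        "copy_number": "copy_number.tsv",
        "methylation": "methylation_beta.tsv",
    }
    mats: dict[str, pd.DataFrame] = {}
    for key, fname in required.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"missing required file: {path}")
        mats[key] = _read_matrix(path)

    samples_path = directory / "samples.tsv"
    if not samples_path.exists():
        raise FileNotFoundError(f"missing required file: {samples_path}")
    sample_table = pd.read_csv(samples_path, sep="\t", index_col=0)
    subtype = sample_table["subtype"].astype(str)

    shared = [
        s
        for s in mats["mrna_expr"].columns
        if all(s in m.columns for m in mats.values()) and s in subtype.index
    ]
    if not shared:
        raise ValueError("no samples shared across all matrices")
    n_dropped = len(mats["mrna_expr"].columns) - len(shared)
    if n_dropped:
        logger.info("dropped %d samples absent from some layer", n_dropped)
    mats = {k: m[shared] for k, m in mats.items()}
    subtype = subtype.loc[shared]

    probe_path = directory / "probe_map.tsv"
    if probe_path.exists():
        pm = pd.read_csv(probe_path, sep="\t", index_col=0)
        probe_map = pm.iloc[:, 0].astype(str).to_dict()
    else:
        probe_map = {p: p for p in mats["methylation"].index}

    meth_genes = {probe_map[p] for p in mats["methylation"].index if p in probe_map}
    genes = [
        g
        for g in mats["mrna_expr"].index
        if g in mats["mrna_counts"].index
        and g in mats["copy_number"].index
        and g in meth_genes
    ]
    n_gene_drop = len(mats["mrna_expr"].index) - len(genes)
    if n_gene_drop:
        logger.info("dropped %d genes absent from some gene-level layer", n_gene_drop)
    if not genes:
        raise ValueError("no genes shared across gene-level layers")
    for key in ("mrna_counts", "mrna_expr", "copy_number"):
        mats[key] = mats[key].loc[genes]
    keep_probes = [p for p in mats["methylation"].index if probe_map.get(p) in set(genes)]
    mats["methylation"] = mats["methylation"].loc[keep_probes]
    probe_map = {p: probe_map[p] for p in keep_probes}

    survival = None
    surv_path = directory / "survival.tsv"
    if surv_path.exists():
        sv = pd.read_csv(surv_path, sep="\t", index_col=0)
        survival = sv.loc[[s for s in shared if s in sv.index], ["time", "event"]]

    cohort = OmicsCohort(
        mrna_counts=mats["mrna_counts"],
        mrna_expr=mats["mrna_expr"],
        lncrna_expr=mats["lncrna_expr"],
        copy_number=mats["copy_number"],
        methylation=mats["methylation"],
        probe_map=probe_map,
        subtype=subtype,
        survival=survival,
    )
    cohort.validate()
    return cohort


def filter_lncrna_detected(lncrna_expr: pd.DataFrame) -> pd.Index:
    """Detected lncRNA: median RPKM > 0 and 90th percentile RPKM > 0.1.

    Percentiles use the linear-interpolation (type 7) quantile convention.
    """
    if lncrna_expr.shape[1] < 1:
        raise ValueError("empty matrix: no samples")
    x = lncrna_expr.to_numpy(float)
    med = np.quantile(x, 0.5, axis=1)
    p90 = np.quantile(x, 0.9, axis=1)
    keep = (med > 0) & (p90 > 0.1)
    return lncrna_expr.index[keep]


def filter_expressed(
    expr: pd.DataFrame, min_value: float = 1.0, min_fraction: float = 0.75
) -> pd.Index:
    """Expressed features: >= ``min_fraction`` of samples at or above ``min_value``."""
    if expr.shape[1] < 1:
        raise ValueError("empty matrix: no samples")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    frac = (expr.to_numpy(float) >= min_value).mean(axis=1)
    return expr.index[frac >= min_fraction]


def offset_beta(methylation: pd.DataFrame) -> pd.DataFrame:
    """Shift beta-values from [0, 1] to the centred [-0.5, 0.5] scale.

    Refuses input containing negative values (already-offset data) so the
    shift cannot be applied twice.
    """
    x = methylation.to_numpy(float)
    if np.nanmin(x) < 0:
        raise ValueError("negative values: input looks already offset")
    if np.nanmax(x) > 1 + 1e-12:
        raise ValueError("beta-values above 1 are out of range")
    return methylation - 0.5


def select_representative_probe(
    methylation: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    probe_map: Mapping[str, str],
    method: str = "spearman",
) -> dict[str, str]:
    """Pick one promoter probe per gene: the most expression-anti-correlated.

    For genes with a single probe that probe is returned directly.  For
    multi-probe genes the probe minimizing the correlation (Spearman by
    default, Pearson via ``method="pearson"``) between probe beta-values and
    the gene's expression is selected; no sign gate is applied, so a gene
    whose best correlation is positive still maps to the minimum.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method: {method}")
    by_gene: dict[str, list[str]] = {}
    for probe in methylation.index:
        gene = probe_map.get(probe)
        if gene is None:
            raise ValueError(f"probe {probe} missing from probe map")
        by_gene.setdefault(gene, []).append(probe)
    unknown = set(by_gene) - set(mrna_expr.index)
    if unknown:
        logger.info("skipping %d probe-mapped genes without expression", len(unknown))
    shared = [s for s in methylation.columns if s in mrna_expr.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for probe selection")

    representative: dict[str, str] = {}
    for gene, probes in by_gene.items():
        if gene not in mrna_expr.index:
            continue
        if len(probes) == 1:
            representative[gene] = probes[0]
            continue
        y = mrna_expr.loc[gene, shared].to_numpy(float)
        best_probe, best_r = None, np.inf
        for probe in probes:
            x = methylation.loc[probe, shared].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r = np.inf  # uninformative probe; only picked if all are
            elif method == "spearman":
                r = stats.spearmanr(x, y).statistic
            else:
                r = stats.pearsonr(x, y).statistic
            if r < best_r:
                best_probe, best_r = probe, r
        representative[gene] = best_probe if best_probe is not None else probes[0]
    return representative


def gene_level_methylation(
    cohort: OmicsCohort, representative: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse the probe-level methylation matrix to one row per gene."""
    if representative is None:
        representative = select_representative_probe(
            cohort.methylation, cohort.mrna_expr, cohort.probe_map
        )
    genes = [g for g in cohort.genes if g in representative]
    mat = cohort.methylation.loc[[representative[g] for g in genes]]
    mat.index = pd.Index(genes, name=cohort.methylation.index.name)
    return mat
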