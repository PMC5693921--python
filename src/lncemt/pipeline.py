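"""Discovery funnel and cross-cohort validation orchestration.

``run_discovery`` chains the stages: detection filters -> differential
expression (count exact test for genes, t-test for lncRNA) -> per-pair
regression screen -> hypergeometric enrichment of each lncRNA's associated
genes in the DE set -> fold-change filter (>= 2-fold up in mesenchymal) ->
conservation filter.  Enrichment is applied before the fold-change filter,
so an aberrantly expressed but unenriched lncRNA never reaches the final
set.  Every stage's table is kept (and optionally written as TSV) so each
reported number can be recomputed by calling the owning module directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from .cohort import (
    OmicsCohort,
    filter_expressed,
    filter_lncrna_detected,
    load_cohort,
)
from .de import DE, NON_DE, classify_de, de_exact_test, de_ttest
from .enrichment import lncrna_de_enrichment
from .conservation import max_window_conservation, read_conservation
from .partialcorr import spearman_rho
from .regression import screen_associations

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "PipelineConfig",
    "StageError",
    "DiscoveryReport",
    "run_discovery",
    "run_validation",
]


class StageError(RuntimeError):
    """A funnel stage eliminated every candidate."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass(frozen=True)
class Thresholds:
    """All funnel cutoffs; defaults are the study's printed values."""

    de_alpha: float = 1e-3
    nonde_alpha: float = 0.25
    fc_threshold: float = 2.0
    coef_cutoff: float = 0.3
    regression_alpha: float = 1e-6
    enrichment_alpha: float = 1e-3
    pathway_alpha: float = 0.05
    coexpr_cutoff: float = 0.3
    conservation_threshold: float = 0.9
    conservation_window: int = 200
    survival_horizon: float = 60.0

    def validate(self) -> None:
        for name in (
            "de_alpha",
            "nonde_alpha",
            "regression_alpha",
            "enrichment_alpha",
            "pathway_alpha",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 <= self.coexpr_cutoff <= 1:
            raise ValueError("coexpr_cutoff must lie in [0, 1]")
        if self.survival_horizon <= 0:
            raise ValueError("survival_horizon must be positive")


@dataclass
class PipelineConfig:
    """Paths plus thresholds, loadable from a single YAML file."""

    cohort_dir: str | None = None
    second_cohort_dir: str | None = None
    gmt_path: str | None = None
    conservation_path: str | None = None
    binding_path: str | None = None
    edges_path: str | None = None
    out_dir: str | None = None
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        thr.validate()
        return cls(thresholds=thr, **raw)


@dataclass
class DiscoveryReport:
    """Per-stage survivor tables and the final lncRNA set."""

    stage_tables: dict[str, pd.DataFrame]
    lncrna_table: pd.DataFrame
    final: list[str]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for stage, table in self.stage_tables.items():
            table.to_csv(out_dir / f"stage_{stage}.tsv", sep="\t")
        self.lncrna_table.to_csv(out_dir / "lncrna_funnel.tsv", sep="\t")
        (out_dir / "final_lncrnas.txt").write_text("\n".join(self.final) + "\n")


def run_discovery(
    cohort: OmicsCohort | str | Path,
    conservation_tracks: dict[str, np.ndarray] | str | Path | None = None,
    thresholds: Thresholds = Thresholds(),
    out_dir: str | Path | None = None,
) -> DiscoveryReport:
    """Run the full discovery funnel and rank EMT-linked lncRNA.

    ``cohort`` may be an in-memory :class:`OmicsCohort` or a directory
    readable by :func:`load_cohort`; ``conservation_tracks`` a mapping of
    per-base score arrays or a TSV path.  Raises :class:`StageError` when a
    stage leaves no survivors.
    """
    thresholds.validate()
    if not isinstance(cohort, OmicsCohort):
        cohort = load_cohort(cohort)
    if conservation_tracks is not None and not isinstance(conservation_tracks, dict):
        conservation_tracks = read_conservation(conservation_tracks)

    tables: dict[str, pd.DataFrame] = {}

    # stage 1: detection filters
    detected_lnc = list(filter_lncrna_detected(cohort.lncrna_expr))
    detected_genes = list(filter_expressed(cohort.mrna_expr))
    tables["detection"] = pd.DataFrame(
        {"feature": detected_genes + detected_lnc,
         "kind": ["gene"] * len(detected_genes) + ["lncrna"] * len(detected_lnc)}
    ).set_index("feature")
    if not detected_lnc:
        raise StageError("detection", "no lncRNA passed the detection filters")
    if not detected_genes:
        raise StageError("detection", "no genes passed the expression filter")

    # stage 2: differential expression of genes (count exact test)
    de_table = classify_de(
        de_exact_test(cohort.mrna_counts.loc[detected_genes], cohort.subtype),
        fc_threshold=thresholds.fc_threshold,
        de_alpha=thresholds.de_alpha,
        nonde_alpha=thresholds.nonde_alpha,
    )
    tables["differential_expression"] = de_table
    de_genes = set(de_table.index[de_table["status"] == DE])
    nonde_genes = set(de_table.index[de_table["status"] == NON_DE])
    if not de_genes:
        raise StageError("differential_expression", "no DE genes between subtypes")
    if not nonde_genes:
        raise StageError("differential_expression", "no non-DE background genes")

    # stage 3: regression screen over the full candidate grid
    assoc = screen_associations(
        cohort,
        candidate_genes=detected_genes,
        candidate_lncrnas=detected_lnc,
        coef_cutoff=thresholds.coef_cutoff,
        alpha=thresholds.regression_alpha,
    )
    tables["regression"] = assoc
    if not assoc["flagged"].any():
        raise StageError("regression", "no significant gene-lncRNA association")

    # stage 4: enrichment of associated genes in the DE set
    enrich = lncrna_de_enrichment(
        assoc, de_genes, nonde_genes, alpha=thresholds.enrichment_alpha
    )
    tables["enrichment"] = enrich
    enriched = list(enrich.loc[enrich["flagged"], "lncrna"]) if len(enrich) else []
    if not enriched:
        raise StageError("enrichment", "no lncRNA enriched in the DE set")

    # stage 5: aberrant expression (>= fc_threshold-fold up in mesenchymal)
    lnc_de = de_ttest(cohort.lncrna_expr.loc[detected_lnc], cohort.subtype)
    tables["lncrna_de"] = lnc_de
    min_lfc = np.log2(thresholds.fc_threshold)
    upregulated = [
        l for l in enriched if lnc_de.loc[l, "log2_fold_change"] >= min_lfc
    ]
    if not upregulated:
        raise StageError("fold_change", "no enriched lncRNA >= 2-fold up in mesenchymal")

    # stage 6: conservation
    if conservation_tracks is not None:
        scores = {
            l: max_window_conservation(
                conservation_tracks[l], thresholds.conservation_window
            )
            for l in upregulated
            if l in conservation_tracks
        }
        final = [l for l in upregulated if scores.get(l, 0.0) >= thresholds.conservation_threshold]
        if not final:
            raise StageError("conservation", "no surviving lncRNA is conserved")
    else:
        scores = {}
        final = upregulated
        logger.info("no conservation tracks supplied; conservation stage skipped")

    summary = pd.DataFrame(index=pd.Index(detected_lnc, name="lncrna"))
    summary["detected"] = True
    if len(enrich):
        e = enrich.set_index("lncrna")
        summary["enrichment_p"] = e["adjusted_p"]
        summary["enriched"] = summary.index.isin(e.index[e["flagged"]])
    else:
        summary["enrichment_p"] = np.nan
        summary["enriched"] = False
    summary["log2_fold_change"] = lnc_de["log2_fold_change"]
    summary["upregulated"] = summary["log2_fold_change"] >= min_lfc
    summary["conservation"] = pd.Series(scores, dtype=float)
    summary["final"] = summary.index.isin(final)
    summary = summary.sort_values(
        ["final", "enrichment_p"], ascending=[False, True]
    )

    report = DiscoveryReport(stage_tables=tables, lncrna_table=summary, final=sorted(final))
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_validation(
    cohort_a: OmicsCohort | str | Path,
    cohort_b: OmicsCohort | str | Path,
    thresholds: Thresholds = Thresholds(),
) -> dict:
    """Cross-cohort concordance of subtype fold changes and lncRNA co-expression.

    Computes per-gene log2 fold changes (Welch t path) in both cohorts over
    the shared gene namespace and their Spearman correlation, plus a
    per-lncRNA comparison of co-expression (fraction of DE vs non-DE genes
    with |rho| above the co-expression cutoff) in the second cohort.
    """
    thresholds.validate()
    if not isinstance(cohort_a, OmicsCohort):
        cohort_a = load_cohort(cohort_a)
    if not isinstance(cohort_b, OmicsCohort):
        cohort_b = load_cohort(cohort_b)
    shared_genes = [g for g in cohort_a.genes if g in set(cohort_b.genes)]
    if len(shared_genes) < 100:
        logger.warning("only %d shared genes between cohorts", len(shared_genes))
    if len(shared_genes) < 3:
        raise ValueError("too few shared genes for validation")

    fc_a = de_ttest(cohort_a.mrna_expr.loc[shared_genes], cohort_a.subtype)
    fc_b = de_ttest(cohort_b.mrna_expr.loc[shared_genes], cohort_b.subtype)
    rho = spearman_rho(
        fc_a["log2_fold_change"].to_numpy(), fc_b["log2_fold_change"].to_numpy()
    )

    # DE / non-DE universe from cohort A, co-expression measured in cohort B
    de_table = classify_de(
        fc_a,
        fc_threshold=thresholds.fc_threshold,
        de_alpha=0.05,
        nonde_alpha=thresholds.nonde_alpha,
    )
    de_genes = [g for g in de_table.index[de_table["status"] == DE]]
    nonde_genes = [g for g in de_table.index[de_table["status"] == NON_DE]]

    shared_lnc = [l for l in cohort_a.lncrnas if l in set(cohort_b.lncrnas)]
    rows = []
    logb = np.log2(cohort_b.mrna_expr.loc[shared_genes] + 1.0)
    for lnc in shared_lnc:
        lv = np.log2(cohort_b.lncrna_expr.loc[lnc].to_numpy(float) + 1.0)
        if np.std(lv) == 0:
            continue

        def frac_coexpr(gene_list):
            if not gene_list:
                return np.nan
            rhos = [
                abs(spearman_rho(logb.loc[g].to_numpy(), lv)) for g in gene_list
            ]
            return float(np.mean(np.asarray(rhos) >= thresholds.coexpr_cutoff))

        rows.append(
            {
                "lncrna": lnc,
                "frac_de_coexpressed": frac_coexpr(de_genes),
                "frac_nonde_coexpressed": frac_coexpr(nonde_genes),
            }
        )
    coexpr = pd.DataFrame(rows).set_index("lncrna") if rows else pd.DataFrame()

    return {
        "n_shared_genes": len(shared_genes),
        "fold_change_spearman": rho,
        "fold_changes": pd.DataFrame(
            {
                "log2fc_a": fc_a["log2_fold_change"],
                "log2fc_b": fc_b["log2_fold_change"],
            }
        ),
        "coexpression": coexpr,
    }
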