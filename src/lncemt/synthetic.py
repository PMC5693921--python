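"""Synthetic two-subtype multi-omic cohorts with planted lncRNA regulators.

The generator emulates the data model the discovery pipeline assumes: gene
log2 expression is an additive function of promoter methylation (centred
beta-value), gene copy number, and the log2 expression of a planted regulator
lncRNA, plus Gaussian noise.  Planted regulators are shifted upward in the
mesenchymal subtype, which propagates a differential-expression block to
their target genes; every gene additionally carries a small intrinsic subtype
shift so that two cohorts generated from the same ground truth show
concordant fold changes, as matched patient cohorts do.  Read counts are
drawn negative-binomially around library-size-scaled continuous means, so
both the count-based exact test and the continuous t-test path can be
exercised against the same truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import OmicsCohort, EPITHELIAL, MESENCHYMAL

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "load_truth",
    "generate_conservation",
    "simulate_survival",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure cohort generator.

    Effect sizes are on the log2-expression scale: ``beta_lnc`` multiplies the
    regulator's log2 expression, ``beta_cn`` a copy-number level in
    {-1, 0, 1, 2}, ``beta_dm`` a centred methylation beta-value, and
    ``de_log2fc`` is the mesenchymal shift applied to regulator lncRNAs.
    """

    n_epithelial: int = 100
    n_mesenchymal: int = 50
    n_genes: int = 200
    n_lncrnas: int = 15
    n_regulators: int = 3
    targets_per_regulator: int = 8
    beta_lnc: float = 0.8
    beta_cn: float = 0.25
    beta_dm: float = -1.0
    de_log2fc: float = 2.0
    noise_sd: float = 1.0
    libsize_range: tuple[float, float] = (0.8, 1.2)
    dispersion: float = 0.1
    seed: int = 0
    # realism defaults beyond the core contract
    lnc_mean: float = 5.0
    lnc_sd: float = 1.5
    gene_baseline_mean: float = 5.0
    gene_baseline_sd: float = 1.0
    gene_subtype_shift_sd: float = 0.3
    cn_levels: tuple[int, ...] = (-1, 0, 1, 2)
    cn_probs: tuple[float, ...] = (0.05, 0.90, 0.04, 0.01)
    probes_per_gene: int = 1
    # seed for gene-level structure (baselines, intrinsic subtype shifts,
    # methylation means); defaults to `seed`.  Fixing it while varying `seed`
    # regenerates an independent cohort from the same ground truth.
    structure_seed: int | None = None

    def validate(self) -> None:
        counts = {
            "n_epithelial": self.n_epithelial,
            "n_mesenchymal": self.n_mesenchymal,
            "n_genes": self.n_genes,
            "n_lncrnas": self.n_lncrnas,
            "targets_per_regulator": self.targets_per_regulator,
            "probes_per_gene": self.probes_per_gene,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_regulators < 0:
            raise ValueError("n_regulators must be >= 0")
        if self.n_regulators > self.n_lncrnas:
            raise ValueError("n_regulators exceeds n_lncrnas")
        if self.n_regulators * self.targets_per_regulator > self.n_genes:
            raise ValueError(
                "targets_per_regulator * n_regulators exceeds n_genes"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must be positive and ordered")
        if len(self.cn_levels) != len(self.cn_probs) or not np.isclose(
            sum(self.cn_probs), 1.0
        ):
            raise ValueError("cn_probs must match cn_levels and sum to 1")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    ``regulator_targets`` maps each planted regulator lncRNA to its target
    genes, ``planted_betas`` records the generative coefficient per
    (gene, lncRNA) pair, ``de_genes`` is the differential-expression block
    (the union of regulator targets), and ``gene_subtype_shift`` the small
    intrinsic mesenchymal shift of every gene.
    """

    regulator_targets: dict[str, set[str]]
    de_genes: set[str]
    planted_betas: dict[tuple[str, str], float]
    gene_subtype_shift: dict[str, float] = field(default_factory=dict)

    @property
    def regulators(self) -> list[str]:
        return sorted(self.regulator_targets)

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return set(self.planted_betas)


def generate_cohort(config: SyntheticConfig) -> tuple[OmicsCohort, GroundTruth]:
    """Draw one cohort with planted regulators; identical seeds are bit-identical."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    struct_seed = config.structure_seed if config.structure_seed is not None else config.seed
    rng_struct = np.random.default_rng(struct_seed)
    n_epi, n_mes = config.n_epithelial, config.n_mesenchymal
    n = n_epi + n_mes
    samples = [f"E{i:04d}" for i in range(n_epi)] + [
        f"M{i:04d}" for i in range(n_mes)
    ]
    mes = np.concatenate([np.zeros(n_epi), np.ones(n_mes)])
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    lncs = [f"L{i:03d}" for i in range(config.n_lncrnas)]

    # lncRNA log2 expression; regulators shifted upward in mesenchymal samples
    z = config.lnc_mean + config.lnc_sd * rng.standard_normal(
        (config.n_lncrnas, n)
    )
    z[: config.n_regulators] += config.de_log2fc * mes

    # methylation: per-gene Beta distribution; first probe is the causal one
    meth_means = rng_struct.uniform(0.2, 0.8, config.n_genes)
    conc = 20.0
    beta_vals = rng.beta(
        meth_means[:, None] * conc, (1 - meth_means[:, None]) * conc, (config.n_genes, n)
    )

    cn = rng.choice(
        np.asarray(config.cn_levels, dtype=float),
        p=config.cn_probs,
        size=(config.n_genes, n),
    )

    baseline = (
        config.gene_baseline_mean
        + config.gene_baseline_sd * rng_struct.standard_normal(config.n_genes)
    )
    delta = rng_struct.normal(0.0, config.gene_subtype_shift_sd, config.n_genes)
    noise = rng.normal(0.0, config.noise_sd, (config.n_genes, n))

    y = (
        baseline[:, None]
        + config.beta_dm * (beta_vals - 0.5)
        + config.beta_cn * cn
        + delta[:, None] * mes
        + noise
    )

    regulator_targets: dict[str, set[str]] = {}
    planted_betas: dict[tuple[str, str], float] = {}
    tpr = config.targets_per_regulator
    for r in range(config.n_regulators):
        reg = lncs[r]
        tgts = genes[r * tpr : (r + 1) * tpr]
        regulator_targets[reg] = set(tgts)
        for g_idx, gene in zip(range(r * tpr, (r + 1) * tpr), tgts):
            # centred regulator effect: targets keep the same baseline
            # magnitude as unregulated genes
            y[g_idx] += config.beta_lnc * (z[r] - config.lnc_mean)
            planted_betas[(gene, reg)] = config.beta_lnc

    # counts: NB around library-size-scaled continuous means (gamma-Poisson)
    lib = rng.uniform(*config.libsize_range, n)
    mu = np.exp2(y) * lib
    lam = rng.gamma(1.0 / config.dispersion, mu * config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    mrna_rpkm = np.clip(np.exp2(y) - 1.0, 0.0, None)
    lnc_rpkm = np.clip(np.exp2(z) - 1.0, 0.0, None)

    # methylation probes: identity map by default, k probes per gene otherwise
    if config.probes_per_gene == 1:
        probe_ids = list(genes)
        meth = beta_vals
        probe_map = {g: g for g in genes}
    else:
        probe_ids, rows, probe_map = [], [], {}
        for gi, gene in enumerate(genes):
            probe_ids.append(f"{gene}_p0")
            probe_map[f"{gene}_p0"] = gene
            rows.append(beta_vals[gi])
            for j in range(1, config.probes_per_gene):
                pid = f"{gene}_p{j}"
                probe_ids.append(pid)
                probe_map[pid] = gene
                m = rng.uniform(0.2, 0.8)
                rows.append(rng.beta(m * conc, (1 - m) * conc, n))
        meth = np.vstack(rows)

    cols = pd.Index(samples, name="sample_id")
    cohort = OmicsCohort(
        mrna_counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=cols),
        mrna_expr=pd.DataFrame(mrna_rpkm, index=pd.Index(genes, name="gene_id"), columns=cols),
        lncrna_expr=pd.DataFrame(lnc_rpkm, index=pd.Index(lncs, name="lncrna_id"), columns=cols),
        copy_number=pd.DataFrame(cn, index=pd.Index(genes, name="gene_id"), columns=cols),
        methylation=pd.DataFrame(meth, index=pd.Index(probe_ids, name="probe_id"), columns=cols),
        probe_map=probe_map,
        subtype=pd.Series(
            [EPITHELIAL] * n_epi + [MESENCHYMAL] * n_mes, index=cols, name="subtype"
        ),
    )
    truth = GroundTruth(
        regulator_targets=regulator_targets,
        de_genes=set().union(*regulator_targets.values()) if regulator_targets else set(),
        planted_betas=planted_betas,
        gene_subtype_shift=dict(zip(genes, delta)),
    )
    return cohort, truth


def write_cohort(
    cohort: OmicsCohort, truth: GroundTruth | None, directory: str | Path
) -> list[Path]:
    """Write a cohort (and its truth) as the TSV file set read by load_cohort."""
    if len(cohort.samples) == 0:
        raise ValueError("refusing to write a cohort with no samples")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    matrices = {
        "mrna_counts.tsv": cohort.mrna_counts,
        "mrna_rpkm.tsv": cohort.mrna_expr,
        "lncrna_rpkm.tsv": cohort.lncrna_expr,
        "copy_number.tsv": cohort.copy_number,
        "methylation_beta.tsv": cohort.methylation,
    }
    for fname, df in matrices.items():
        path = directory / fname
        df.to_csv(path, sep="\t")
        written.append(path)

    path = directory / "samples.tsv"
    cohort.subtype.to_frame().to_csv(path, sep="\t")
    written.append(path)

    identity = all(p == g for p, g in cohort.probe_map.items())
    if not identity:
        path = directory / "probe_map.tsv"
        pd.Series(cohort.probe_map, name="gene_id").rename_axis("probe_id").to_csv(
            path, sep="\t"
        )
        written.append(path)

    if cohort.survival is not None:
        path = directory / "survival.tsv"
        cohort.survival.to_csv(path, sep="\t")
        written.append(path)

    if truth is not None:
        path = directory / "truth.json"
        payload = {
            "regulator_targets": {
                k: sorted(v) for k, v in truth.regulator_targets.items()
            },
            "de_genes": sorted(truth.de_genes),
            "planted_betas": {
                f"{g}|{l}": b for (g, l), b in truth.planted_betas.items()
            },
            "gene_subtype_shift": truth.gene_subtype_shift,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(path)
    return written


def load_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        regulator_targets={
            k: set(v) for k, v in payload["regulator_targets"].items()
        },
        de_genes=set(payload["de_genes"]),
        planted_betas={
            tuple(k.split("|")): b for k, b in payload["planted_betas"].items()
        },
        gene_subtype_shift=payload.get("gene_subtype_shift", {}),
    )


def generate_conservation(
    lnc_ids,
    conserved_ids,
    seed: int = 0,
    length: int = 400,
    window: int = 200,
    conserved_range: tuple[float, float] = (0.93, 0.99),
    background_range: tuple[float, float] = (0.05, 0.30),
) -> dict[str, np.ndarray]:
    """Per-base phastCons-like tracks: conserved ids carry one high block.

    Conserved transcripts receive a contiguous ``window``-length block of
    scores drawn from ``conserved_range`` on a low background, so their
    maximal 200-nt window mean falls in the highly conserved band; all other
    transcripts are background throughout.
    """
    rng = np.random.default_rng(seed)
    conserved = set(conserved_ids)
    tracks: dict[str, np.ndarray] = {}
    for lnc in lnc_ids:
        track = rng.uniform(*background_range, length)
        if lnc in conserved:
            start = rng.integers(0, length - window + 1)
            track[start : start + window] = rng.uniform(*conserved_range, window)
        tracks[lnc] = track
    return tracks


def simulate_survival(
    values: pd.Series,
    log_hr: float = 0.7,
    baseline_median: float = 40.0,
    censor_range: tuple[float, float] = (12.0, 120.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with hazard tied to a (z-scored) expression value.

    Times are in months; follow-up ends at a uniform censoring time, giving a
    realistic mix of observed deaths and censored records.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(values, float)
    sd = x.std()
    zs = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    rate = np.log(2) / baseline_median * np.exp(log_hr * zs)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(*censor_range, len(x))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=values.index)
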