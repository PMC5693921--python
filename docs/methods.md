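# Methods

This note documents the statistical procedures implemented in `lncemt`, the
generative model behind the synthetic cohorts, the numerical conventions, and
the design choices made where the problem was genuinely open.

## Data model

A cohort is a set of feature-by-sample matrices over one shared, ordered
sample list: mRNA read counts and RPKM, lncRNA RPKM, gene copy-number levels,
and promoter methylation β-values, plus subtype labels (epithelial /
mesenchymal) and optional survival follow-up (months, event flag).  Loading
takes the sample intersection of all layers and keeps only genes present in
expression, copy number, and methylation (through the probe map); both drops
are logged.  Expression enters all linear models as log2(x + 1): RPKM-like
values are heavy-tailed, and an untransformed fit would be dominated by
outliers.

Methylation β-values in [0, 1] are offset by −0.5 so the covariate is
centred; the offset function refuses input containing negative values, which
guards against applying it twice.  When several probes map to one gene, the
representative probe is the one with the most negative probe–expression
correlation (Spearman by default, because rank correlation is the package's
association measure throughout and is robust to expression skew; Pearson via
a flag).  No sign gate is applied: a gene whose best correlation is positive
still maps to its minimum-correlation probe.

Percentiles in the detection filters use the linear-interpolation ("type 7")
quantile convention of mainstream numeric stacks.  "Median RPKM = 0
eliminates" is implemented as median ≤ 0 since RPKM is non-negative.  Both
detection thresholds are inclusive on the fraction (≥ 75%) and strict on the
percentile value (> 0, > 0.1).

## Differential expression

**Count path.**  The two-group comparison on read counts is an exact
negative-binomial test: per-sample *effective library sizes* are estimated by
the median-of-ratios method (the median, over genes with a positive
geometric mean, of the sample's count ratio to the gene-wise reference) and
counts are scaled to the geometric mean of those sizes, rounded to integers.
Raw column totals are deliberately not used: in a simulated transcriptome of
a few hundred genes, a planted block of strongly shifted genes carries a
large share of the total and total-count scaling transfers their shift onto
every null gene (composition bias); the median ratio is driven by the null
majority and is unbiased.  A per-gene common dispersion φ solves
var = μ + φμ² within each subtype group (method of moments, sample-size
weighted across groups, floored at 10⁻⁶).  Group sums of iid NB(μ, φ)
variables are NB with size n_g/φ, so conditional on the observed total the
two-sided p-value sums the probabilities of all splits at most as probable
as the observed one.  As φ → 0 this reduces to a binomial split of the
total, which provides an enumeration oracle in the tests.  This is a
faithful-in-spirit exact test for digital expression data, not a clone of
any released package: there is no quantile-adjusted conditional likelihood
and no TMM; the pipeline contract is the DE / non-DE partition.

**Continuous path.**  Welch's unequal-variance *t* on log2(x + 1), two- or
one-tailed.  Features with zero variance in both groups get p = 1 with a
warning.  Fold changes are mesenchymal minus epithelial on the log2 scale;
count-based fold changes use normalized group means with pseudocount 0.5 so
they are finite and bit-reproducible.

**Calls.**  BH adjustment is the standard step-up (via statsmodels), applied
over whatever family the caller supplies.  A gene is DE when
|log2FC| ≥ log2(2) (inclusive boundary) and adjusted p < α (strict;
α = 10⁻³ for the count path by default, 0.05 for validation-style continuous
data), non-DE when adjusted p > 0.25, otherwise ambiguous and excluded from
the enrichment universe.

## Regression screen

Each (gene, lncRNA) pair gets its own ordinary-least-squares fit of gene
expression on [intercept, centred methylation, copy number, lncRNA log2
expression]; one lncRNA per model, iterated over the candidate grid, never a
joint multi-lncRNA fit.  By default the response and every predictor are
z-scored per pair.  This is the decision that makes a universal coefficient
cutoff coherent: |β^lnc| ≥ 0.3 is only meaningful across genes on a common
scale, and on standardized data the single-predictor limit of β^lnc is the
Pearson correlation.  A raw-scale mode is available (used, e.g., to verify
unbiased recovery of generative coefficients).  The t-test for β^lnc uses
n − 4 residual degrees of freedom; constant predictors are dropped from the
design and recorded.  The grid fit is batched (per-lncRNA stacked 4×4 normal
equations) and verified in the tests against the per-pair fit and against an
explicit (XᵀX)⁻¹Xᵀy oracle.  Multiple testing is BH over the full tested
grid (all pairs pooled), with a per-lncRNA family behind a flag.

## Enrichment

The over-representation test is the hypergeometric upper tail including the
observed count, P(X ≥ k) — the standard convention; k = 0 returns 1.  For
lncRNA–DE enrichment the universe is DE ∪ non-DE, each lncRNA's associated
genes are intersected with it, and lncRNA with no associated gene in the
universe are excluded (the test is undefined) with a log entry; BH runs
across lncRNA and flags at adjusted p < 10⁻³.  Pathway enrichment against a
GMT collection intersects sets with the universe, skips sets reduced below 3
genes, and flags at adjusted p < 0.05.  Percent and fold-enrichment numbers
(binding sites, amplification, network coverage) are rounded to one decimal
only at the reporting boundary; internal values keep full precision.
Interaction coverage counts genes with at least one within-set edge, with
self-loops ignored and unordered pairs deduplicated.

## Conservation

A transcript's score is the maximum, over all contiguous 200-base windows at
step 1, of the window mean of per-base phastCons-like scores, computed with
a rolling cumulative sum (O(n)) and checked against the naive O(n·w) scan.
Step 1 maximizes sensitivity at linear cost.  Transcripts shorter than the
window fall back to the whole-track mean (logged) so behaviour is defined
everywhere.  The retention threshold defaults to 0.9; it is a configuration
default chosen to sit below the 0.94–0.98 band that highly conserved
transcripts occupy, not an estimated quantity.

## Partial correlation

First-order partial correlation is applied to Spearman correlations, the
package's association measure; the algebra is the textbook formula with the
result clamped to [−1, 1] against floating-point overshoot and an error when
a conditioning correlation has magnitude 1.  The reduction test requires
each gene pair to be mutually co-expressed with the lncRNA (|ρ| ≥ 0.3 by
default) and compares |r_xy| with |r_xy.l| by a one-sided Wilcoxon rank-sum
test (exact when the combined sample is ≤ 20 and tie-free, otherwise the
normal approximation with tie correction).  Magnitudes are compared because
"reduction of co-expression" concerns strength, not sign; a signed mode
exists.  Rank-sum (not signed-rank) is used although the pairs are matched,
following the named test; the calibration consequence is documented below.

## Survival and meta-analysis

Five-year analysis administratively censors follow-up at 60 months (times
truncated, events beyond the horizon set to censored).  Stratification is at
the median of the lncRNA's expression with ties assigned to the low group —
deterministic and documented; the Kaplan–Meier curves come from lifelines,
as does the log-rank χ² (p from χ²₁).  Expression–survival correlation is
Spearman ρ over samples with observed events by default, since censored
times understate survival; the all-samples mode is provided but flagged as
biased.  Quartile contrasts compare samples at or below Q1 of the
stratifier against those at or above Q3, Welch *t* per gene on the log
scale, oriented low minus high.  Fisher's combined probability is
−2Σln p ~ χ²₂ₖ with zero p-values floored at 10⁻³⁰⁰ (warned); the
meta-analysis combines per-dataset p-values only for genes whose fold-change
directions agree and flags discordant genes instead of combining them.

## Synthetic cohorts

The generator emulates a two-subtype tumour cohort with known structure.
Gene log2 expression is

    y_g = b_g + β_DM (m − 0.5) + β_CN c + δ_g I(mes) + Σ β_pair (z_k − μ_z) + ε

with per-gene baselines b_g ~ N(5, 1), methylation m ~ Beta per gene
(means uniform on [0.2, 0.8], concentration 20), copy number drawn from
{−1, 0, 1, 2} with amplification (≥ 1) frequency 5% by default, residual
ε ~ N(0, noise_sd), and a small intrinsic subtype shift δ_g ~ N(0, 0.3)
that emulates the pervasive mild transcriptome differences real subtypes
show (and is what makes cross-cohort fold-change concordance non-trivial).
Planted regulator lncRNA are shifted by `de_log2fc` (default 2) in the
mesenchymal subtype; their effect on targets is centred (z − μ_z) so target
genes keep the same baseline magnitude as unregulated genes.  The DE block
is therefore *induced through the regulators* (target log2FC =
β_pair · de_log2fc plus δ_g): a separate additive DE term on targets would
make the planted coefficient unidentifiable, because regulator expression
and the subtype indicator are collinear.  lncRNA log2 expression has mean 5
and SD 1.5, a realism default reflecting the high between-tumour
variability of lncRNA.  Counts are gamma-Poisson (NB) around
library-factor-scaled 2^y means with dispersion 0.1 and library factors
uniform on [0.8, 1.2]; RPKM matrices are 2^y − 1 (clipped at 0), so
log2(RPKM + 1) recovers the generative scale exactly.  Structural
randomness (baselines, δ_g, methylation means) is driven by a separate
`structure_seed`, so varying the sampling seed at fixed structure seed
regenerates an independent cohort from the same ground truth.  Identical
seeds give bit-identical cohorts and files.

What the generator does **not** emulate: batch effects, library-preparation
artifacts, subtype misclassification, miRNA layers, linked copy-number
segments, or correlated methylation blocks.  Passing tests therefore show
that the procedures recover the planted generative structure under the
stated noise — not that TCGA-scale effect sizes would be recovered; the
study's headline counts on real cohorts are data-dependent and out of reach
of a desk-scale simulation.

## Benchmark conditions

The benchmark experiments (in `lncemt.benchmarks`, shared by the test suite
and `scripts/acceptance.py`) use these conditions, chosen at design time:

- **Screen recovery**: 100 cohorts of 100 + 50 samples, planted coefficient
  0.5, residual SD 1.0, 200 genes × 15 lncRNA (3 regulators × 8 targets),
  flagging at |β| ≥ 0.3 and BH p < 10⁻⁶.  The regulator subtype shift is off
  (`de_log2fc = 0`) because this experiment measures the screen's operating
  characteristics on planted linear signal; with shifted regulators, targets
  of one regulator correlate with *every* shifted regulator through the
  shared subtype indicator, which measures that confound rather than the
  screen.
- **Funnel recovery** runs in the near-noiseless limit: residual SD 0.01 and
  intrinsic subtype shifts off, leaving planted regulation as the only
  subtype-linked variation, so the funnel must return exactly the planted,
  conserved, upregulated regulators.
- **Null calibration**: the regression grid of a cohort with no regulators
  (3000 pairs) is tested for uniform raw p-values.  For the discrete
  hypergeometric test, uniformity is asserted on the randomized
  (continuity-corrected) p-value P(X > k) + U·P(X = k), which is exactly
  U(0, 1) iff the tail function is correct — the standard device for
  discrete tests, whose raw p-values are conservative, not uniform.  The
  rank-sum reduction test is calibrated with disjoint pair sets (marginals
  from one half, partials from the other, conditioning lncRNA independent):
  with a shared pair set the two samples are matched and nearly identical,
  and the rank-sum null of independent samples does not hold — a limitation
  of using the rank-sum test on paired data that is inherited by design.
- **Mediation**: 50 gene pairs at n = 2000 driven solely by one lncRNA
  (loadings 0.7); the marginal Spearman ρ stays near 0.47 while the median
  |partial| falls below 0.05.
- **Cross-cohort validation**: two cohorts of 900 samples regenerated from
  one structure seed; fold-change Spearman ρ ≈ 0.95.

The NB exact test's null uniformity is asserted at Kolmogorov D < 0.05 on
2000 null genes: its p-values are discrete and mildly conservative, and the
dispersion is estimated per gene, so exact uniformity is not expected.

## Known limitations

- The exact test is not bit-compatible with released count-DE packages (by
  design); only the DE / non-DE partition is contractual.
- Applying partial-correlation algebra to Spearman ρ is an approximation:
  rank correlations do not satisfy the Gaussian partial-correlation
  identity exactly, which is why the mediation benchmark checks a
  threshold (median |r_partial| < 0.05) rather than zero.
- The survival module assumes right-censoring only, and the
  events-only expression–time correlation discards censored information.
- The funnel's stage order (enrichment before the fold-change filter) is
  part of the contract: an aberrantly expressed but unenriched lncRNA is
  excluded, and the reverse order would change the final set.
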