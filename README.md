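# lncemt

Discovery of EMT-linked long non-coding RNA (lncRNA) regulators from matched
multi-omic tumour cohorts.

Epithelial-to-mesenchymal transition (EMT) marks aggressive, metastasis-prone
tumours, and in cancers such as high-grade serous ovarian carcinoma patients
fall into epithelial and mesenchymal expression subtypes.  `lncemt` is for
computational biologists who want to ask: *which lncRNA plausibly drive the
mesenchymal expression program?*  It implements an integrated discovery
funnel over matched mRNA expression, lncRNA expression, gene copy number and
promoter methylation for two-subtype cohorts, together with a
synthetic-cohort generator with planted regulators so every stage can be
validated against a known ground truth.

## The model

The core screen fits, for every candidate gene *i* and lncRNA *k*, the
multivariate linear model over samples *t*

```
Y_it = β0 + β_i^DM · x_it^DM + β_i^CN · x_it^CN + β_ik^lnc · x_kt^lnc + ε
```

where `Y` is gene log2 expression, `x^DM` the promoter methylation β-value
centred to [−0.5, 0.5], `x^CN` the copy-number level, and `x^lnc` the
lncRNA's log2 expression.  Copy number and methylation act as nuisance
covariates so that the coefficient of interest `β_ik^lnc` reflects
association with the lncRNA beyond the gene's own genomic and epigenomic
state.  Response and predictors are z-scored per pair (configurable), which
makes the universal flagging rule — |β^lnc| ≥ 0.3 and Benjamini–Hochberg
adjusted *p* < 10⁻⁶ — a common-scale criterion across genes.

Around the screen, the funnel chains:

1. **Detection filters** — lncRNA kept when median RPKM > 0 and the 90th
   percentile > 0.1; mRNA kept when ≥ 75% of samples reach a normalized
   value of 1.
2. **Differential expression** — an exact negative-binomial test on counts
   (two-sided, conditional on the per-gene total, method-of-moments common
   dispersion, robust median-of-ratios library equalization) for genes, and
   Welch *t* on log2(x+1) for lncRNA; genes are called DE (≥ 2-fold, BH
   *p* < 10⁻³) or non-DE (BH *p* > 0.25).
3. **Enrichment** — per lncRNA, a hypergeometric upper-tail test of its
   associated genes against the DE set with the DE ∪ non-DE universe.
4. **Aberrant expression** — enriched lncRNA must be ≥ 2-fold up in the
   mesenchymal subtype.
5. **Conservation** — the maximally conserved 200-nt sliding window of
   per-base phastCons scores must reach 0.9.

Downstream evidence modules: first-order partial correlation
`r_xy.l = (r_xy − r_xl·r_yl) / √((1−r_xl²)(1−r_yl²))` on Spearman
correlations, with a one-sided Wilcoxon rank-sum test for co-expression
reduction; Kaplan–Meier five-year survival stratified at the median lncRNA
expression with the log-rank test; lowest- vs highest-quartile expression
contrasts pooled across cohorts with Fisher's combined probability test
(−2Σln *p* ~ χ²₂ₖ).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
cohorts (a discovery cohort of 100 epithelial + 50 mesenchymal samples, 200
genes, 15 lncRNA with 3 planted regulators of 8 targets each, and an
independent validation cohort regenerated from the same ground truth):

```
python analysis/01_simulate_cohorts.py
python analysis/02_detection_and_de.py
python analysis/03_regression_screen.py
python analysis/08_discovery_funnel.py
```

prints, among other things:

```
gene DE status: {'non-DE': 108, 'ambiguous': 73, 'DE': 19}
3000 pairs fitted; 24 flagged
recall of planted pairs: 100.00%; false flags: 0
final EMT-linked lncRNA: L000, L001
planted regulators:     L000, L001, L002
cross-cohort fold-change Spearman rho = 0.882 over 200 genes
```

All 24 planted (gene, lncRNA) pairs are flagged with no false positives.  At
this realistic noise level (residual SD 1.0 on the log2 scale) one borderline
regulator, L002, drops at the enrichment stage because several of its targets
are classified ambiguous rather than DE — the kind of attrition such funnels
show on real cohorts; in the near-noiseless limit the funnel returns exactly
the planted set (see the acceptance checks).  The same pipeline is scriptable
via the `lncemt` CLI (`lncemt simulate`, `lncemt discover`, `lncemt
validate`, ...), configured from a single YAML file.

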