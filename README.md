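# markersurv

Prognostic-marker analysis for cohorts stratified by a bimodally expressed
gene. The package:

- **stratifies** samples into marker-high / marker-low groups using either
  the valley of a kernel density estimate (pooled across cohorts by a
  sample-size-weighted mean) or the crossing point of a two-component
  Gaussian mixture at a chosen density ratio (equal-density or the 10% rule);
- **compares disease-free survival** between the strata with a
  from-first-principles Kaplan–Meier estimator and Mantel–Haenszel log-rank
  test (asymptotic chi-square p by default, exact/permutation p for very
  small cohorts), including risk tables and a per-gene survival screen;
- **characterizes the marker's co-expression neighborhood** via tie-corrected
  Spearman correlation, Benjamini–Hochberg FDR, signed-p
  (`sign(r)·(1 − p)`) matrices, and cross-cohort **max-rank aggregation**
  of top co-expressed genes or interaction partners;
- **tests clinicopathological associations** (Wilcoxon rank-sum,
  Kruskal–Wallis, Pearson, with exact permutation enumeration for tiny
  samples);
- ships a **synthetic-data generator** producing multi-cohort data with a
  bimodal [0, 1] marker activity score, genes rank-correlated to the marker
  through a Gaussian copula, and stratum-dependent right-censored survival —
  so the whole pipeline is testable offline.

## Quick start

```bash
# simulate three cohorts
markersurv simulate --out sim --seed 3 --n-cohorts 3

# pooled density-valley threshold + strata
markersurv stratify --expression sim/cohort1/expression.tsv \
    --expression sim/cohort2/expression.tsv \
    --marker MARKER --method pooled --out strat

# Kaplan-Meier / log-rank for one cohort
markersurv survive --strata strat/strata_cohort1.tsv \
    --clinical sim/cohort1/clinical.tsv --out surv

# co-expression tables and max-rank aggregation
markersurv coexpress --expression sim/cohort1/expression.tsv \
    --expression sim/cohort2/expression.tsv --marker MARKER --k 20 --out coex

# covariate association panel
markersurv associate --expression sim/cohort1/expression.tsv --marker MARKER \
    --clinical sim/cohort1/clinical.tsv --out assoc.tsv

# everything at once from a config
markersurv run --config config.yaml --out report
```

`run` expects a YAML config:

```yaml
cohorts:
  - expression_path: sim/cohort1/expression.tsv
    clinical_path: sim/cohort1/clinical.tsv
    alias: c1
    value_kind: log2_intensity   # or "activity" for [0,1] scores
marker: MARKER
partners_path: partners.gmt      # optional gene set (GMT or one-per-line)
threshold_method: pooled         # valley | pooled | mixture
k: 20
alpha: 0.05
min_cohorts: 2
seed: 7
```

The report bundle contains the stratification summary (counts and
one-decimal percentages per cohort and total), per-cohort KM curves and
log-rank results, the top-k co-expression table with per-cohort r_s and FDR,
a per-gene survival screen flagging genes significant in ≥ `min_cohorts`
cohorts, signed-p matrices, the association panel, and a plain-text manifest
recording the threshold provenance and every fallback decision.

## File formats

Everything is plain text: expression matrices are TSV (header row of sample
ids, first column feature id), clinical tables are TSV with `sample_id`,
`dfs_time`, `dfs_event` plus arbitrary covariate columns, gene sets are GMT
or one symbol per line.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (arithmetic checks
against published summary tables, threshold-recovery and type-I-error
simulations, and brute-force oracles for KM, log-rank, BH-FDR, max-rank
aggregation and signed-p matrices).

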