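"""Orchestrate the full analysis over one or more cohorts from a single config.

Produces, per cohort: strata, Kaplan-Meier curves, log-rank comparison and a
risk table; pooled across cohorts: a stratification summary (counts and
one-decimal percentages), a top-k co-expression table with BH FDRs, a
per-gene survival screen, signed-p matrices and an association panel — plus
a run manifest recording seeds, thresholds and every fallback decision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from markersurv.association import association_panel
from markersurv.coexpression import aggregate_max_rank, marker_correlation_table, signed_p_matrix, top_partners
from markersurv.io import (
    ClinicalTable,
    ExpressionMatrix,
    align_cohort,
    read_clinical,
    read_expression,
    read_geneset,
    write_report_tables,
)
from markersurv.stratification import (
    SampleStrata,
    ThresholdEstimate,
    classify,
    estimate_density,
    find_valley,
    fit_mixture_1d,
    mixture_ratio_threshold,
    pool_thresholds,
)
from markersurv.survival import kaplan_meier, logrank, per_gene_survival_screen, risk_table

logger = logging.getLogger(__name__)


@dataclass
class CohortSpec:
    expression_path: str
    clinical_path: str
    alias: str
    value_kind: str = "log2_intensity"


@dataclass
class PipelineConfig:
    cohorts: list[CohortSpec]
    marker: str
    primary_probe: str | None = None
    partners_path: str | None = None
    threshold_method: str = "pooled"  # valley | pooled | mixture
    mixture_ratio: float = 1.0
    threshold_override: float | None = None
    k: int = 20
    alpha: float = 0.05
    min_cohorts: int = 2
    seed: int = 0
    reference_aliases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("config must list at least one cohort")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("significance level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cohorts = [CohortSpec(**c) for c in raw.pop("cohorts")]
        return cls(cohorts=cohorts, **raw)


def survival_eligible(cohort_totals, n_excluded: int) -> int:
    """Samples eligible for survival analysis: combined cohort sizes minus the
    count excluded for non-tumoral origin or missing follow-up."""
    totals = [int(n) for n in cohort_totals]
    if not totals or any(n <= 0 for n in totals):
        raise ValueError("cohort totals must be positive and non-empty")
    if not 0 <= int(n_excluded) <= sum(totals):
        raise ValueError("exclusion count must lie in [0, sum(totals)]")
    return sum(totals) - int(n_excluded)


def summarize_stratification(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-cohort and total high/low counts with one-decimal percentages.

    ``counts`` maps cohort alias -> (n_high, n_low); values may also be
    :class:`SampleStrata`. Percentage is 100 * high / total rounded to one
    decimal (0.0 when the cohort is empty).
    """
    rows = []
    tot_high = tot_low = 0
    for alias, val in counts.items():
        if isinstance(val, SampleStrata):
            high, low = val.n_high, val.n_low
        else:
            high, low = int(val[0]), int(val[1])
        if high < 0 or low < 0:
            raise ValueError("counts must be non-negative")
        total = high + low
        pct = round(100.0 * high / total, 1) if total else 0.0
        rows.append({"cohort": alias, "n_high": high, "n_low": low,
                     "n_total": total, "pct_high": pct})
        tot_high += high
        tot_low += low
    total = tot_high + tot_low
    rows.append({
        "cohort": "Total",
        "n_high": tot_high,
        "n_low": tot_low,
        "n_total": total,
        "pct_high": round(100.0 * tot_high / total, 1) if total else 0.0,
    })
    return pd.DataFrame(rows)


def _marker_scores(expr: ExpressionMatrix, config: PipelineConfig) -> pd.Series:
    probe = config.primary_probe if config.primary_probe in (expr.feature_ids or []) else None
    feature = probe or (config.marker if config.marker in expr.feature_ids else None)
    if feature is None:
        raise KeyError(f"marker {config.marker!r} not found in cohort matrix")
    return expr.row(feature)


def derive_threshold(
    score_vectors: dict[str, np.ndarray],
    method: str,
    mixture_ratio: float = 1.0,
    override: float | None = None,
    value_range: tuple[float, float] | None = None,
) -> tuple[ThresholdEstimate, list[str]]:
    """Derive the stratification cut from per-cohort marker scores.

    Returns the threshold and a list of human-readable provenance notes for
    the manifest.
    """
    notes: list[str] = []
    if override is not None:
        return ThresholdEstimate(value=float(override), method="fixed"), ["fixed override"]
    if method in ("valley", "pooled"):
        minima, sizes = [], []
        for alias, x in score_vectors.items():
            curve = estimate_density(x, value_range=value_range)
            v = find_valley(curve)
            minima.append(v)
            sizes.append(x.size)
            notes.append(f"{alias}: valley at {v:.6g} (n={x.size}, h={curve.bandwidth:.4g})")
        if method == "valley" and len(minima) > 1:
            notes.append("valley method with several cohorts: pooling by sample size")
        return pool_thresholds(minima, sizes), notes
    if method == "mixture":
        pooled = np.concatenate(list(score_vectors.values()))
        fit = fit_mixture_1d(pooled)
        thr = mixture_ratio_threshold(fit, ratio=mixture_ratio)
        notes.append(
            f"mixture fit on {pooled.size} pooled scores: mu=({fit.mu1:.4g},{fit.mu2:.4g}), "
            f"ratio={mixture_ratio} -> cut {thr.value:.6g}"
        )
        return thr, notes
    raise ValueError(f"unknown threshold method {method!r}")


def run(config: PipelineConfig, out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Execute every stage and write the report bundle under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from markersurv import __version__ as pkg_version

    manifest: list[str] = [f"markersurv {pkg_version}", f"seed {config.seed}"]

    cohorts: dict[str, tuple[ExpressionMatrix, ClinicalTable]] = {}
    full_expression: dict[str, ExpressionMatrix] = {}
    for spec in config.cohorts:
        stage = f"io:{spec.alias}"
        try:
            expr = read_expression(spec.expression_path, value_kind=spec.value_kind)
            clin = read_clinical(spec.clinical_path)
            full_expression[spec.alias] = expr
            expr_s, clin_s = align_cohort(expr, clin)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        dropped = expr.n_samples - expr_s.n_samples
        if dropped:
            manifest.append(f"{spec.alias}: excluded {dropped} samples without survival data")
        cohorts[spec.alias] = (expr_s, clin_s)

    # threshold on survival-eligible samples' marker scores
    score_vectors = {
        alias: _marker_scores(expr, config).to_numpy()
        for alias, (expr, _) in cohorts.items()
    }
    vr = (0.0, 1.0) if config.cohorts[0].value_kind == "activity" else None
    threshold, notes = derive_threshold(
        score_vectors, config.threshold_method, config.mixture_ratio,
        config.threshold_override, value_range=vr,
    )
    manifest += [f"threshold: {threshold.value:.6g} ({threshold.method})", *notes]

    results: dict[str, pd.DataFrame] = {}
    strata_counts: dict[str, SampleStrata] = {}
    km_rows, logrank_rows = [], []
    for alias, (expr, clin) in cohorts.items():
        stage = f"survival:{alias}"
        try:
            strata = classify(_marker_scores(expr, config), threshold)
            strata_counts[alias] = strata
            labels = np.array([strata.labels[s] for s in clin.sample_ids])
            t = clin.table["dfs_time"].to_numpy()
            e = clin.table["dfs_event"].to_numpy()
            for grp in ("high", "low"):
                sel = labels == grp
                if sel.sum() == 0:
                    manifest.append(f"{alias}: stratum {grp} empty; no curve")
                    continue
                curve = kaplan_meier(t[sel], e[sel])
                tp = np.linspace(0, float(t.max()), 6)
                at_risk = risk_table(curve, tp)
                for et, sv in zip(curve.event_times, curve.survival):
                    km_rows.append({"cohort": alias, "stratum": grp, "time": et, "survival": sv})
                manifest.append(
                    f"{alias}/{grp}: n={int(sel.sum())}, at-risk@{tp.round(2).tolist()}="
                    f"{at_risk.tolist()}"
                )
            lr = logrank(t, e, labels)
            logrank_rows.append({
                "cohort": alias, "chi_square": lr.chi_square, "p_value": lr.p_value,
                "n_high": int((labels == "high").sum()), "n_low": int((labels == "low").sum()),
            })
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    results["stratification_summary"] = summarize_stratification(strata_counts)
    results["km_curves"] = pd.DataFrame(km_rows)
    results["logrank"] = pd.DataFrame(logrank_rows)

    # co-expression on all samples (not just survival-eligible)
    stage = "coexpression"
    try:
        corr_tables = {}
        for spec in config.cohorts:
            expr = full_expression[spec.alias]
            marker_feat = _marker_scores(expr, config).name
            corr_tables[spec.alias] = marker_correlation_table(expr, marker_feat)
        study_aliases = [a for a in corr_tables if a not in config.reference_aliases] or list(corr_tables)
        agg = aggregate_max_rank([corr_tables[a] for a in study_aliases],
                                 k=min(config.k, min(len(t) for t in corr_tables.values())))
        rows = []
        for gene in agg.selection:
            rec = {"gene": gene, "max_rank": agg.max_rank[gene]}
            for alias in corr_tables:
                by_gene = {r.gene: r for r in corr_tables[alias]}
                if gene in by_gene:
                    rec[f"r_s_{alias}"] = by_gene[gene].r_s
                    rec[f"fdr_{alias}"] = by_gene[gene].fdr
            rows.append(rec)
        results["top_coexpressed"] = pd.DataFrame(rows)
        if config.partners_path:
            partners = read_geneset(config.partners_path)
            ref_aliases = config.reference_aliases or list(corr_tables)
            pagg = top_partners([corr_tables[a] for a in ref_aliases], partners, k=config.k)
            results["top_partners"] = pd.DataFrame(
                {"gene": pagg.selection,
                 "max_rank": [pagg.max_rank[g] for g in pagg.selection]}
            )
            for alias in corr_tables:
                expr = full_expression[alias]
                marker_feat = _marker_scores(expr, config).name
                genes = [marker_feat] + [g for g in pagg.selection if g in expr.feature_ids]
                sp = signed_p_matrix(expr, genes)
                sp.insert(0, "gene", sp.index)
                results[f"signed_p_{alias}"] = sp.reset_index(drop=True)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # per-gene survival screen over the aggregated selection plus the marker
    stage = "screen"
    try:
        screen_genes = []
        for g in [_marker_scores(cohorts[next(iter(cohorts))][0], config).name, *agg.selection]:
            if g not in screen_genes and all(
                g in expr.feature_ids for expr, _ in cohorts.values()
            ):
                screen_genes.append(g)
        results["survival_screen"] = per_gene_survival_screen(
            [expr for expr, _ in cohorts.values()],
            [clin for _, clin in cohorts.values()],
            screen_genes,
            alpha=config.alpha,
            min_cohorts=config.min_cohorts,
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # association panel per cohort
    stage = "association"
    try:
        assoc_rows = []
        for alias, (expr, clin) in cohorts.items():
            if not clin.covariate_names:
                continue
            scores = _marker_scores(expr, config).loc[clin.sample_ids].to_numpy()
            for res in association_panel(scores, clin):
                assoc_rows.append({
                    "cohort": alias, "covariate": res.covariate, "test": res.test,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "adjusted_p": res.adjusted_p,
                })
        results["association_panel"] = pd.DataFrame(assoc_rows)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    write_report_tables(results, out_dir)
    (out_dir / "manifest.txt").write_text("\n".join(manifest) + "\n", encoding="utf-8")
    (out_dir / "threshold.json").write_text(
        json.dumps(
            {
                "value": threshold.value,
                "method": threshold.method,
                "per_cohort_minima": threshold.per_cohort_minima,
                "weights": threshold.weights,
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    return results
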