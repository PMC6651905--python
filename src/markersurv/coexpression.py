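"""Marker-centric Spearman co-expression, BH-FDR, signed-p matrices and
cross-cohort max-rank aggregation."""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from markersurv.io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

#: Below this sample size the Spearman p-value is exact (full permutation
#: enumeration); above it the t-approximation with n-2 df is used.
EXACT_PERMUTATION_MAX_N = 10


@dataclass
class CorrelationResult:
    """Spearman correlation of one gene with the marker, with BH-adjusted p."""

    gene: str
    r_s: float
    p_value: float
    fdr: float | None
    n_pairs: int


@dataclass
class RankAggregation:
    """Per-cohort descending-correlation ranks and the max-rank statistic.

    ``per_cohort_ranks`` maps gene -> list of ranks (1 = highest r_s in that
    cohort); ``selection`` is the top-k list ordered ascending by max rank.
    """

    per_cohort_ranks: dict[str, list[int]]
    max_rank: dict[str, int]
    selection: list[str]


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int64)


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman correlation with a two-sided p-value.

    r_s is Pearson on average ranks. The p-value uses the t-approximation
    with n-2 df for n > 10 and exact enumeration of all rank permutations
    for n <= 10 (ties permuted as observed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 paired finite values, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance (a constant input)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = _all_permutations(n)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        null_r = (ryc[perms] @ rxc) / denom
        obs = abs(float(rxc @ ryc) / denom)
        p = float((np.abs(null_r) >= obs - 1e-12).mean())
    elif abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def marker_correlation_table(
    expression: ExpressionMatrix, marker: str, genes=None
) -> list[CorrelationResult]:
    """Spearman correlation of each gene with the marker, BH-adjusted within
    the table. Genes with zero rank variance are dropped with a warning."""
    if genes is None:
        genes = [g for g in expression.feature_ids if g != marker]
    mk = expression.row(marker).to_numpy()
    results: list[CorrelationResult] = []
    for gene in genes:
        vals = expression.row(gene).to_numpy()
        ok = np.isfinite(mk) & np.isfinite(vals)
        try:
            r, p = spearman(mk[ok], vals[ok])
        except ValueError as exc:
            warnings.warn(f"skipping {gene}: {exc}", stacklevel=2)
            continue
        results.append(CorrelationResult(gene=gene, r_s=r, p_value=p, fdr=None, n_pairs=int(ok.sum())))
    adj = bh_fdr([r.p_value for r in results])
    for res, q in zip(results, adj):
        res.fdr = float(q)
    return results


def signed_p_matrix(expression: ExpressionMatrix, genes) -> pd.DataFrame:
    """Pairwise sign(r_s) * (1 - p) matrix; symmetric, +1 on the diagonal.

    Constant gene rows yield 0 entries with a warning.
    """
    missing = [g for g in genes if g not in expression.feature_ids]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    g = list(genes)
    k = len(g)
    vals = {gene: expression.row(gene).to_numpy() for gene in g}
    s = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                r, p = spearman(vals[g[i]], vals[g[j]])
                s[i, j] = s[j, i] = math.copysign(1.0, r) * (1.0 - p) if r != 0 else 0.0
            except ValueError:
                warnings.warn(
                    f"constant input for pair ({g[i]}, {g[j]}); entry set to 0", stacklevel=2
                )
                s[i, j] = s[j, i] = 0.0
    return pd.DataFrame(s, index=g, columns=g)


def _competition_ranks(table: list[CorrelationResult], genes: list[str]) -> dict[str, int]:
    """Descending r_s ranks 1..G; ties broken lexicographically by gene id so
    the ranks form a permutation."""
    sub = {t.gene: t.r_s for t in table if t.gene in genes}
    ordered = sorted(sub, key=lambda gn: (-sub[gn], gn))
    return {gn: i + 1 for i, gn in enumerate(ordered)}


def aggregate_max_rank(per_cohort_tables, k: int) -> RankAggregation:
    """Cross-cohort max-rank aggregation.

    Each gene is ranked within each cohort in descending order of r_s; the
    maximum (worst) rank over cohorts is its representative statistic; the
    selection is the first ``k`` genes after sorting ascending by that
    statistic (gene id breaks ties).
    """
    if not per_cohort_tables:
        raise ValueError("need at least one cohort table")
    gene_sets = [set(t.gene for t in tab) for tab in per_cohort_tables]
    common = sorted(set.intersection(*gene_sets))
    if not common:
        raise ValueError("empty gene intersection across cohorts")
    if k > len(common):
        raise ValueError(f"k={k} exceeds the {len(common)}-gene intersection")
    per_cohort = [_competition_ranks(tab, common) for tab in per_cohort_tables]
    ranks = {gn: [pc[gn] for pc in per_cohort] for gn in common}
    max_rank = {gn: max(rs) for gn, rs in ranks.items()}
    ordered = sorted(common, key=lambda gn: (max_rank[gn], gn))
    return RankAggregation(per_cohort_ranks=ranks, max_rank=max_rank, selection=ordered[:k])


def top_partners(per_cohort_tables, partner_set: GeneSet, k: int = 20) -> RankAggregation:
    """Max-rank aggregation restricted to an externally determined partner set."""
    members = set(partner_set.members)
    restricted = []
    for tab in per_cohort_tables:
        sub = [t for t in tab if t.gene in members]
        if not sub:
            raise ValueError(
                f"partner set {partner_set.name!r} does not intersect a cohort table"
            )
        restricted.append(sub)
    n_common = len(set.intersection(*[set(t.gene for t in tab) for tab in restricted]))
    if n_common < len(members):
        logger.info(
            "partner set %s: %d of %d members measured in all cohorts",
            partner_set.name, n_common, len(members),
        )
    return aggregate_max_rank(restricted, k=min(k, n_common))
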