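"""Association tests between marker expression and clinicopathological covariates.

Dispatch follows covariate arity: two categories -> Wilcoxon rank-sum
(statistic reported as the rank sum W of the first category), more than
two -> Kruskal-Wallis, continuous -> Pearson correlation. The rank tests
use tie-corrected average ranks with normal / chi-square approximations,
switching to exact permutation enumeration for pooled n <= 12 where the
approximations are too coarse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from markersurv.coexpression import bh_fdr
from markersurv.io import ClinicalTable

logger = logging.getLogger(__name__)

#: Numeric covariates with more distinct values than this are treated as continuous.
CONTINUOUS_UNIQUE_MIN = 7

#: At or below this pooled sample size the rank tests enumerate the exact
#: permutation null; the normal / chi-square approximations are too coarse there.
EXACT_MAX_N = 12


@dataclass
class AssociationResult:
    covariate: str
    test: str  # wilcoxon | kruskal_wallis | pearson
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    n_dropped: int = 0
    adjusted_p: float | None = None


def _rank_sum_test(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum with average ranks.

    Returns (W, p) where W is the rank sum of the first sample; under H0
    E[W] = n1*(n1+n2+1)/2. The p-value is the exact two-sided permutation
    probability for pooled n <= EXACT_MAX_N and the tie-corrected normal
    approximation above that.
    """
    from itertools import combinations

    n1, n2 = x1.size, x2.size
    pooled = np.concatenate([x1, x2])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        raise ValueError("zero variance in rank-sum test (all values tied)")
    if n <= EXACT_MAX_N:
        dev = abs(w - mean_w)
        null_w = np.array([sum(c) for c in combinations(ranks, n1)])
        p = float((np.abs(null_w - mean_w) >= dev - 1e-12).mean())
    else:
        z = (w - mean_w) / np.sqrt(var_w)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w, min(p, 1.0)


def _kruskal_exact_p(pooled: np.ndarray, sizes: list[int], h_obs: float) -> float:
    """Exact Kruskal-Wallis p by enumerating all group assignments."""
    from itertools import combinations

    ranks = stats.rankdata(pooled)
    n = ranks.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    base = 12.0 / (n * (n + 1))

    h_values: list[float] = []

    def h_from_sums(rank_sums: list[float]) -> float:
        s = sum(rs * rs / k for rs, k in zip(rank_sums, sizes))
        return (base * s - 3.0 * (n + 1)) / tie_corr

    def recurse(remaining: tuple[int, ...], gi: int, rank_sums: list[float]) -> None:
        if gi == len(sizes) - 1:
            h_values.append(h_from_sums(rank_sums + [ranks[list(remaining)].sum()]))
            return
        for combo in combinations(remaining, sizes[gi]):
            rest = tuple(i for i in remaining if i not in set(combo))
            recurse(rest, gi + 1, rank_sums + [ranks[list(combo)].sum()])

    recurse(tuple(range(n)), 0, [])
    null = np.asarray(h_values)
    return float((null >= h_obs - 1e-12).mean())


def _is_continuous(values: pd.Series) -> bool:
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.isna().any():
        return False
    return numeric.nunique() >= CONTINUOUS_UNIQUE_MIN


def associate(scores, covariate: pd.Series, kind: str | None = None) -> AssociationResult:
    """Test the association of marker scores with one covariate column.

    ``kind`` may force ``"continuous"`` or ``"categorical"``; by default
    numeric columns with many distinct values are treated as continuous.
    Missing covariate values are dropped with a logged count; categories with
    fewer than 2 observations are dropped with a warning.
    """
    s = pd.Series(np.asarray(scores, dtype=float)).reset_index(drop=True)
    cov = pd.Series(covariate).reset_index(drop=True)
    if len(s) != len(cov):
        raise ValueError("scores and covariate must have the same length")
    name = str(covariate.name) if getattr(covariate, "name", None) else "covariate"
    keep = s.notna() & cov.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("associate(%s): dropped %d samples with missing values", name, n_dropped)
    s, cov = s[keep], cov[keep]
    if len(cov) == 0:
        raise ValueError(f"covariate {name!r} has no non-missing values")

    continuous = kind == "continuous" or (kind is None and _is_continuous(cov))
    if continuous:
        x = pd.to_numeric(cov).to_numpy(dtype=float)
        r, p = stats.pearsonr(s.to_numpy(), x)
        return AssociationResult(
            covariate=name, test="pearson", statistic=float(r), p_value=float(p),
            group_sizes={"n": int(len(s))}, n_dropped=n_dropped,
        )

    sizes = cov.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("associate(%s): dropping categories with < 2 observations: %s", name, small)
        keep2 = ~cov.isin(small)
        s, cov = s[keep2], cov[keep2]
        n_dropped += int((~keep2).sum())
        sizes = cov.value_counts()
    if sizes.size < 2:
        raise ValueError(f"covariate {name!r} has fewer than 2 usable categories")
    groups = [s[cov == c].to_numpy() for c in sizes.index]
    group_sizes = {str(c): int(n) for c, n in sizes.items()}
    if sizes.size == 2:
        w, p = _rank_sum_test(groups[0], groups[1])
        return AssociationResult(
            covariate=name, test="wilcoxon", statistic=w, p_value=p,
            group_sizes=group_sizes, n_dropped=n_dropped,
        )
    h, p = stats.kruskal(*groups)
    if len(s) <= EXACT_MAX_N:
        p = _kruskal_exact_p(
            np.concatenate(groups), [g.size for g in groups], float(h)
        )
    return AssociationResult(
        covariate=name, test="kruskal_wallis", statistic=float(h), p_value=float(p),
        group_sizes=group_sizes, n_dropped=n_dropped,
    )


def association_panel(scores, clinical: ClinicalTable, covariates=None) -> list[AssociationResult]:
    """One association test per covariate plus BH adjustment across the panel.

    Raw p-values are what the dispatch produces; ``adjusted_p`` adds the
    panel-level BH value on top.
    """
    names = covariates if covariates is not None else clinical.covariate_names
    results = []
    for name in names:
        if name not in clinical.table.columns:
            raise KeyError(f"covariate {name!r} not in clinical table")
        try:
            results.append(associate(scores, clinical.table[name]))
        except ValueError as exc:
            logger.warning("skipping covariate %s: %s", name, exc)
    if results:
        adj = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    return results
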