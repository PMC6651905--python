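"""Product-limit survival estimation and two-group log-rank comparison.

Implemented from first principles (no survival-library dependency) so the
estimators stay oracle-testable: the Kaplan-Meier curve is the running
product of (1 - d/n) over distinct event times, and the log-rank test uses
the Mantel-Haenszel statistic with the hypergeometric variance and no
continuity correction. Ties between events and censorings at the same time
are resolved events-first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from markersurv.io import ClinicalTable, ExpressionMatrix
from markersurv.stratification import (
    ThresholdEstimate,
    UnimodalDensityError,
    classify,
    estimate_density,
    find_valley,
    fit_mixture_1d,
    mixture_ratio_threshold,
)

logger = logging.getLogger(__name__)


@dataclass
class KaplanMeierCurve:
    """Product-limit estimate S(t) at each distinct event time.

    ``observed_times`` keeps every follow-up time (events and censorings) so
    n-at-risk can be recomputed at arbitrary timepoints.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    observed_times: np.ndarray = field(repr=False, default=None)

    def survival_at(self, t: float) -> float:
        """S(t): the estimate at the last event time <= t (1.0 before the first)."""
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: np.ndarray  # events per group
    expected: np.ndarray  # expected events per group under H0


def _clean_times(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and >= 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0 (censored) or 1 (event)")
    return t, e.astype(int)


def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator."""
    t, e = _clean_times(times, events)
    uniq = np.unique(t[e == 1])
    # at risk just before tj: observed time >= tj (tied censorings count,
    # since events precede censorings at tied times)
    n_at_risk = np.array([(t >= tj).sum() for tj in uniq], dtype=int)
    d = np.array([((t == tj) & (e == 1)).sum() for tj in uniq], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - d / n_at_risk
    surv = np.cumprod(factors)
    return KaplanMeierCurve(
        event_times=uniq,
        survival=surv,
        at_risk=n_at_risk,
        events=d,
        observed_times=np.sort(t),
    )


def logrank(
    times,
    events,
    groups,
    method: str = "asymptotic",
    n_permutations: int = 20000,
    seed: int = 0,
) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test (1 df chi-square).

    ``method="asymptotic"`` (default) takes p from the chi-square reference
    distribution; ``method="permutation"`` estimates it from ``n_permutations``
    random relabelings of the group vector, which is preferable for very
    small cohorts where the chi-square approximation is poor.
    """
    t, e = _clean_times(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must match times in length")
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {labels.size}")
    in1 = g == labels[0]
    if e.sum() == 0:
        raise ValueError("no events; log-rank undefined")
    uniq = np.unique(t[e == 1])
    # pooled risk sets per event time
    nj = (t[None, :] >= uniq[:, None]).sum(axis=1).astype(float)
    n1j = (t[None, in1] >= uniq[:, None]).sum(axis=1).astype(float)
    dj = ((t[None, :] == uniq[:, None]) & (e[None, :] == 1)).sum(axis=1).astype(float)
    d1j = ((t[None, in1] == uniq[:, None]) & (e[None, in1] == 1)).sum(axis=1).astype(float)
    n2j = nj - n1j
    exp1 = n1j * dj / nj
    with np.errstate(divide="ignore", invalid="ignore"):
        vj = n1j * n2j * dj * (nj - dj) / (nj * nj * (nj - 1.0))
    vj = np.where(nj > 1, vj, 0.0)
    U = float((d1j - exp1).sum())
    V = float(vj.sum())
    if V <= 0:
        raise ValueError("zero variance; groups have no comparable events")
    chi2 = U * U / V
    if method == "asymptotic":
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "permutation":
        p = _permutation_pvalue(t, e, in1, chi2, n_permutations, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    observed = np.array([d1j.sum(), dj.sum() - d1j.sum()])
    expected = np.array([exp1.sum(), dj.sum() - exp1.sum()])
    return LogRankResult(chi_square=chi2, p_value=p, observed=observed, expected=expected)


def _permutation_pvalue(
    t: np.ndarray, e: np.ndarray, in1: np.ndarray, chi2_obs: float,
    n_permutations: int, seed: int,
) -> float:
    """Permutation p for the log-rank statistic, vectorized across relabelings.

    When the number of distinct group labelings C(n, n1) is at most
    ``n_permutations`` the null is enumerated exactly; otherwise it is
    sampled by random relabelings.
    """
    from itertools import combinations
    from math import comb

    uniq = np.unique(t[e == 1])
    at_risk = (t[None, :] >= uniq[:, None]).astype(float)  # J x n
    event_here = ((t[None, :] == uniq[:, None]) & (e[None, :] == 1)).astype(float)
    nj = at_risk.sum(axis=1)
    dj = event_here.sum(axis=1)
    n1 = int(in1.sum())
    n = t.size
    exact = comb(n, n1) <= n_permutations
    if exact:
        member = np.zeros((comb(n, n1), n))
        for b, idx in enumerate(combinations(range(n), n1)):
            member[b, list(idx)] = 1.0
    else:
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_permutations, n)), axis=1)
        member = np.zeros((n_permutations, n))
        np.put_along_axis(member, order[:, :n1], 1.0, axis=1)
    n1j = member @ at_risk.T  # B x J
    d1j = member @ event_here.T
    with np.errstate(divide="ignore", invalid="ignore"):
        vj = n1j * (nj - n1j) * dj * (nj - dj) / (nj * nj * (nj - 1.0))
    vj = np.where(nj > 1, vj, 0.0)
    U = (d1j - n1j * dj / nj).sum(axis=1)
    V = vj.sum(axis=1)
    ok = V > 0
    chi2_perm = U[ok] ** 2 / V[ok]
    n_ge = int((chi2_perm >= chi2_obs - 1e-12).sum())
    if exact:
        return float(n_ge / ok.sum())
    return float((n_ge + 1) / (ok.sum() + 1))


def risk_table(curve: KaplanMeierCurve, timepoints) -> np.ndarray:
    """Number of samples still at risk (observed time >= t) at each timepoint."""
    tp = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(tp) < 0):
        raise ValueError("timepoints must be ascending")
    obs = curve.observed_times
    return (obs.size - np.searchsorted(obs, tp, side="left")).astype(int)


def dichotomize_scores(scores, value_range=None) -> tuple[ThresholdEstimate, str]:
    """Valley -> mixture(ratio=1) -> median-split fallback chain for a gene track.

    Returns the threshold and the name of the method that succeeded. The
    chain is this pipeline's convention; each fallback is logged so the
    provenance survives into reports.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    try:
        curve = estimate_density(x, value_range=value_range)
        return ThresholdEstimate(value=find_valley(curve), method="valley"), "valley"
    except (UnimodalDensityError, ValueError) as exc:
        logger.info("valley dichotomization failed (%s); trying mixture", exc)
    try:
        fit = fit_mixture_1d(x)
        thr = mixture_ratio_threshold(fit, ratio=1.0)
        return thr, "mixture_equal"
    except (ValueError, RuntimeError) as exc:
        logger.info("mixture dichotomization failed (%s); falling back to median", exc)
    return ThresholdEstimate(value=float(np.median(x)), method="fixed"), "median"


def per_gene_survival_screen(
    expressions,
    clinicals,
    genes,
    alpha: float = 0.05,
    min_cohorts: int = 2,
):
    """Dichotomize each gene per cohort and log-rank test the two strata.

    ``expressions``/``clinicals`` may be single cohort objects or equal-length
    lists of them. Returns a DataFrame with one row per gene: per-cohort
    p-values (NaN when the gene is not assessable, e.g. one empty stratum),
    the dichotomization method used, the count of cohorts with p < ``alpha``
    and a flag for significance in at least ``min_cohorts`` cohorts.
    """
    import pandas as pd

    if isinstance(expressions, ExpressionMatrix):
        expressions = [expressions]
    if isinstance(clinicals, ClinicalTable):
        clinicals = [clinicals]
    if len(expressions) != len(clinicals):
        raise ValueError("expressions and clinicals must pair up cohort-wise")
    for expr in expressions:
        missing = [gn for gn in genes if gn not in expr.feature_ids]
        if missing:
            raise KeyError(f"genes absent from a cohort matrix: {missing[:5]}")

    rows = []
    for gene in genes:
        rec: dict[str, object] = {"gene": gene}
        n_sig = 0
        for ci, (expr, clin) in enumerate(zip(expressions, clinicals)):
            tag = f"cohort{ci + 1}"
            scores = expr.row(gene)
            vr = (0.0, 1.0) if expr.value_kind == "activity" else None
            try:
                thr, method = dichotomize_scores(scores.to_numpy(), value_range=vr)
            except ValueError:
                rec[f"p_{tag}"], rec[f"method_{tag}"] = np.nan, "not_assessable"
                continue
            strata = classify(scores, thr)
            clin_idx = clin.table.set_index("sample_id")
            ids = [s for s in strata.labels if s in clin_idx.index]
            labels = np.array([strata.labels[s] for s in ids])
            if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
                rec[f"p_{tag}"], rec[f"method_{tag}"] = np.nan, "not_assessable"
                continue
            sub = clin_idx.loc[ids]
            try:
                res = logrank(sub["dfs_time"].to_numpy(), sub["dfs_event"].to_numpy(), labels)
                p = res.p_value
            except ValueError:
                p = np.nan
            rec[f"p_{tag}"] = p
            rec[f"method_{tag}"] = method
            if np.isfinite(p) and p < alpha:
                n_sig += 1
        rec["n_significant"] = n_sig
        rec["significant_in_min_cohorts"] = n_sig >= min_cohorts
        rows.append(rec)
    return pd.DataFrame(rows)
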