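"""Multi-cohort synthetic data with the statistical structure the analysis assumes.

Each cohort carries (i) a bimodal [0, 1] activity score for a marker gene,
drawn from a two-component truncated-Gaussian mixture, (ii) a block of
"module" genes rank-correlated with the marker through a shared latent
Gaussian (copula construction), (iii) independent background genes, and
(iv) right-censored survival times whose hazard depends on the true marker
stratum. Everything is reproducible from the config seed via a hierarchical
random stream split, so adding cohorts never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from markersurv.io import ClinicalTable, ExpressionMatrix, write_clinical, write_expression

MARKER_ID = "MARKER"


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort."""

    n_samples: int = 200
    n_genes: int = 50
    marker_mix_weight: float = 0.267  # fraction of samples in the high component
    marker_high_mean: float = 0.8
    marker_low_mean: float = 0.2
    marker_sd: float = 0.1
    module_genes: int = 10
    module_rho: float = 0.45
    hazard_low: float = 0.15  # events per unit time for the low stratum
    hazard_high: float = 0.05
    censor_rate: float = 0.05
    max_followup: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("dimensions must be positive")
        if not 0.0 < self.marker_mix_weight < 1.0:
            raise ValueError("marker_mix_weight must lie in (0, 1)")
        if not self.marker_low_mean < self.marker_high_mean:
            raise ValueError("marker_low_mean must be below marker_high_mean")
        if not (0.0 <= self.marker_low_mean <= 1.0 and 0.0 <= self.marker_high_mean <= 1.0):
            raise ValueError("marker component means must lie in [0, 1]")
        if not -1.0 < self.module_rho < 1.0:
            raise ValueError("module_rho must lie in (-1, 1)")
        if min(self.marker_sd, self.hazard_low, self.hazard_high,
               self.censor_rate, self.max_followup) <= 0:
            raise ValueError("all rates and spreads must be positive")
        if self.module_genes < 0 or self.module_genes > self.n_genes:
            raise ValueError("module_genes must lie in [0, n_genes]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth behind it."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise ValueError("expression and clinical sample ids disagree")
        labels = self.truth.get("stratum")
        if labels is not None and len(labels) != self.expression.n_samples:
            raise ValueError("truth labels must cover every sample")


def _component(mean: float, sd: float) -> stats.rv_continuous:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _mixture_cdf(x: np.ndarray, config: CohortConfig) -> np.ndarray:
    lo = _component(config.marker_low_mean, config.marker_sd)
    hi = _component(config.marker_high_mean, config.marker_sd)
    w = config.marker_mix_weight
    return (1.0 - w) * lo.cdf(x) + w * hi.cdf(x)


def true_valley(config: CohortConfig) -> float:
    """Location of the mixture-density minimum between the component means."""
    lo = _component(config.marker_low_mean, config.marker_sd)
    hi = _component(config.marker_high_mean, config.marker_sd)
    w = config.marker_mix_weight
    pdf = lambda x: (1.0 - w) * lo.pdf(x) + w * hi.pdf(x)
    res = optimize.minimize_scalar(
        pdf, bounds=(config.marker_low_mean, config.marker_high_mean), method="bounded"
    )
    return float(res.x)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort from the generative model described in the module docstring."""
    seq = np.random.SeedSequence(config.seed)
    rng_marker, rng_expr, rng_surv = (np.random.default_rng(s) for s in seq.spawn(3))
    n = config.n_samples

    is_high = rng_marker.random(n) < config.marker_mix_weight
    lo = _component(config.marker_low_mean, config.marker_sd)
    hi = _component(config.marker_high_mean, config.marker_sd)
    marker = np.where(
        is_high,
        hi.rvs(size=n, random_state=rng_marker),
        lo.rvs(size=n, random_state=rng_marker),
    )

    # Copula link: the marker's mixture-CDF value is a uniform comonotone with
    # the marker, so correlating genes with its normal score yields the target
    # Spearman after the bivariate-normal conversion rho_pearson = 2 sin(pi*rho/6).
    u = np.clip(_mixture_cdf(marker, config), 1e-12, 1 - 1e-12)
    z_marker = stats.norm.ppf(u)
    a = 2.0 * math.sin(math.pi * config.module_rho / 6.0)

    n_module = config.module_genes
    n_noise = config.n_genes - n_module
    module = a * z_marker[None, :] + math.sqrt(1.0 - a * a) * rng_expr.standard_normal(
        (n_module, n)
    )
    noise = rng_expr.standard_normal((n_noise, n))

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    feature_ids = (
        [MARKER_ID]
        + [f"MOD{i + 1:03d}" for i in range(n_module)]
        + [f"BG{i + 1:04d}" for i in range(n_noise)]
    )
    values = np.vstack([marker[None, :], module, noise])
    expression = ExpressionMatrix(
        feature_ids=feature_ids, sample_ids=sample_ids, values=values,
        value_kind="log2_intensity",
    )

    hazard = np.where(is_high, config.hazard_high, config.hazard_low)
    event_time = rng_surv.exponential(1.0 / hazard)
    censor_time = np.minimum(
        rng_surv.exponential(1.0 / config.censor_rate, size=n), config.max_followup
    )
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame(
            {"sample_id": sample_ids, "dfs_time": observed, "dfs_event": event}
        )
    )

    truth = {
        "stratum": ["high" if h else "low" for h in is_high],
        "true_valley": true_valley(config),
        "true_hazard_ratio": config.hazard_high / config.hazard_low,
        "config": config,
    }
    return SyntheticCohort(expression=expression, clinical=clinical, truth=truth)


def generate_multi_cohort(
    configs: list[CohortConfig], shared_truth: bool = False
) -> list[SyntheticCohort]:
    """Independent cohorts; with ``shared_truth`` every cohort reuses the first
    config's marker-mixture parameters so one pooled threshold is correct."""
    if not configs:
        raise ValueError("need at least one cohort config")
    if shared_truth:
        ref = configs[0]
        configs = [
            replace(
                c,
                marker_mix_weight=ref.marker_mix_weight,
                marker_low_mean=ref.marker_low_mean,
                marker_high_mean=ref.marker_high_mean,
                marker_sd=ref.marker_sd,
            )
            for c in configs
        ]
    return [generate_cohort(c) for c in configs]


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort in the formats the io module reads, truth as a TSV sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "clinical": out_dir / "clinical.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    truth_df = pd.DataFrame(
        {
            "sample_id": cohort.expression.sample_ids,
            "true_stratum": cohort.truth["stratum"],
            "true_valley": cohort.truth["true_valley"],
            "true_hazard_ratio": cohort.truth["true_hazard_ratio"],
        }
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
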