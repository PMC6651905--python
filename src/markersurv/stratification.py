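"""Dichotomize samples on a marker score.

Two threshold families are provided: (a) the valley of a kernel density
estimate between the two tallest peaks, pooled across cohorts by a
sample-size-weighted mean, and (b) the crossing point where the ratio of two
fitted Gaussian components equals a requested value (1 for the equal-density
crossing, 0.10 for the "10% rule").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

GRID_POINTS = 512

THRESHOLD_METHODS = ("valley", "pooled_valley", "mixture_equal", "mixture_ratio", "fixed")


class UnimodalDensityError(ValueError):
    """The density has no valley between two peaks; callers may fall back to
    the mixture method."""


class DegenerateMixtureError(RuntimeError):
    """EM collapsed onto a zero-variance component even after restarts."""


@dataclass
class DensityCurve:
    """Kernel density estimate on an ascending grid; integrates to ~1."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise ValueError("grid and density must be equal-length vectors")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class ThresholdEstimate:
    """A cut-point on the score scale together with its provenance."""

    value: float
    method: str
    per_cohort_minima: list[float] | None = None
    weights: list[int] | None = None

    def __post_init__(self) -> None:
        if self.method not in THRESHOLD_METHODS:
            raise ValueError(f"unknown threshold method {self.method!r}")
        if not math.isfinite(self.value):
            raise ValueError("threshold value must be finite")


@dataclass
class MixtureFit:
    """Parameters of a two-component univariate Gaussian mixture (mu1 < mu2)."""

    w1: float
    w2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    log_likelihood: float
    n_iter: int
    converged: bool
    log_likelihood_path: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if not (self.mu1 < self.mu2):
            raise ValueError("components must be ordered mu1 < mu2")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component sds must be positive")


@dataclass
class SampleStrata:
    """Per-sample high/low labels under a threshold (high iff score >= cut)."""

    labels: dict[str, str]
    threshold: ThresholdEstimate
    missing: list[str] = field(default_factory=list)

    @property
    def n_high(self) -> int:
        return sum(1 for v in self.labels.values() if v == "high")

    @property
    def n_low(self) -> int:
        return sum(1 for v in self.labels.values() if v == "low")


def silverman_bandwidth(scores: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5); falls back to sd if IQR is zero."""
    n = scores.size
    sd = float(np.std(scores, ddof=1))
    iqr = float(np.subtract(*np.percentile(scores, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def estimate_density(
    scores,
    bandwidth: float | None = None,
    value_range: tuple[float, float] | None = None,
) -> DensityCurve:
    """Gaussian-kernel density on a fixed 512-point grid.

    The grid spans [min - 3h, max + 3h], clipped to ``value_range`` (pass
    ``(0, 1)`` for activity scores).
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >= 10 finite scores, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("scores have zero variance; no density to estimate")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    lo, hi = x.min() - 3 * bandwidth, x.max() + 3 * bandwidth
    if value_range is not None:
        lo, hi = max(lo, value_range[0]), min(hi, value_range[1])
    grid = np.linspace(lo, hi, GRID_POINTS)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bandwidth * math.sqrt(2 * math.pi))
    # renormalize on the grid: clipping to the legal range (and the 3h window)
    # discards kernel tail mass, and the curve must still integrate to ~1
    dens = dens / np.trapezoid(dens, grid)
    return DensityCurve(grid=grid, density=dens, bandwidth=bandwidth)


def _strict_local_maxima(d: np.ndarray) -> list[int]:
    return [i for i in range(1, d.size - 1) if d[i] > d[i - 1] and d[i] > d[i + 1]]


def find_valley(density: DensityCurve) -> float:
    """Grid point of minimum density strictly between the two tallest peaks.

    Raises :class:`UnimodalDensityError` when fewer than two strict local
    maxima exist. If more than two maxima tie for the top heights, the two
    most separated among the tied set are used.
    """
    d = density.density
    maxima = _strict_local_maxima(d)
    if len(maxima) < 2:
        raise UnimodalDensityError(
            f"density has {len(maxima)} strict local maxima; no valley to find"
        )
    order = sorted(maxima, key=lambda i: (-d[i], i))
    top_height = d[order[1]]
    tied = [i for i in maxima if d[i] >= top_height]
    if len(tied) > 2:
        left, right = min(tied), max(tied)
    else:
        left, right = sorted(order[:2])
    segment = d[left : right + 1]
    j = left + int(np.argmin(segment))
    return float(density.grid[j])


def pool_thresholds(minima, sizes) -> ThresholdEstimate:
    """Sample-size-weighted mean of per-cohort valley locations."""
    m = np.asarray(minima, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if m.size == 0 or m.size != n.size:
        raise ValueError("minima and sizes must be equal-length non-empty lists")
    if np.any(n <= 0):
        raise ValueError("cohort sizes must be positive")
    value = float(np.sum(m * n) / np.sum(n))
    return ThresholdEstimate(
        value=value,
        method="pooled_valley" if m.size > 1 else "valley",
        per_cohort_minima=[float(v) for v in m],
        weights=[int(v) for v in n],
    )


def classify(scores, threshold: ThresholdEstimate) -> SampleStrata:
    """Label each sample high (score >= cut, boundary inclusive) or low.

    ``scores`` maps sample id -> score (dict or pandas Series). Samples with
    missing scores are excluded and logged.
    """
    items = scores.items() if hasattr(scores, "items") else enumerate(scores)
    labels: dict[str, str] = {}
    missing: list[str] = []
    for sid, v in items:
        sid = str(sid)
        v = float(v)
        if not math.isfinite(v):
            missing.append(sid)
            continue
        labels[sid] = "high" if v >= threshold.value else "low"
    if missing:
        logger.info("classify: excluded %d samples with missing scores", len(missing))
    return SampleStrata(labels=labels, threshold=threshold, missing=missing)


def _em_once(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray, w: np.ndarray,
             tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    n = x.size
    ll_path: list[float] = []
    prev_ll = -np.inf
    converged = False
    min_sigma = 1e-8 * max(np.ptp(x), 1.0)
    for _ in range(max_iter):
        # E step: responsibilities via log densities for stability
        log_comp = (
            np.log(w)[:, None]
            - np.log(sigma)[:, None]
            - 0.5 * math.log(2 * math.pi)
            - 0.5 * ((x[None, :] - mu[:, None]) / sigma[:, None]) ** 2
        )
        m = log_comp.max(axis=0)
        log_mix = m + np.log(np.exp(log_comp - m).sum(axis=0))
        ll = float(log_mix.sum())
        ll_path.append(ll)
        resp = np.exp(log_comp - log_mix)
        # M step
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-12):
            raise DegenerateMixtureError("component lost all responsibility")
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp @ (x * x)) / nk - mu * mu
        sigma = np.sqrt(np.maximum(var, 0.0))
        if np.any(sigma < min_sigma):
            raise DegenerateMixtureError("component sd collapsed toward zero")
        if prev_ll > -np.inf and (ll - prev_ll) < tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
    return mu, sigma, w, ll_path, converged


def fit_mixture_1d(
    values,
    init: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    max_restarts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of a two-component univariate Gaussian mixture.

    Components are initialised at the 25th/75th percentiles (or ``init``)
    with the pooled sd; the log-likelihood is non-decreasing across
    iterations, and convergence is declared when its relative change drops
    below ``tol``. Degenerate fits (a component sd collapsing to zero) are
    retried with jittered initial means up to ``max_restarts`` times.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError(f"need >= 20 finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("values have zero variance")
    if init is None:
        q25, q75 = np.percentile(x, [25, 75])
        init = (float(q25), float(q75))
    pooled_sd = float(np.std(x, ddof=1))
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        mu = np.array(init, dtype=float)
        if attempt > 0:
            mu = mu + rng.normal(0.0, 0.25 * pooled_sd, size=2)
        if mu[0] == mu[1]:
            mu[1] += 0.5 * pooled_sd
        sigma = np.array([pooled_sd, pooled_sd])
        w = np.array([0.5, 0.5])
        try:
            mu, sigma, w, ll_path, converged = _em_once(x, mu, sigma, w, tol, max_iter)
        except DegenerateMixtureError as exc:
            last_err = exc
            continue
        order = np.argsort(mu)
        mu, sigma, w = mu[order], sigma[order], w[order]
        if mu[0] == mu[1]:  # relabeling requires strict order
            last_err = DegenerateMixtureError("components coincide")
            continue
        return MixtureFit(
            w1=float(w[0]),
            w2=float(w[1]),
            mu1=float(mu[0]),
            mu2=float(mu[1]),
            sigma1=float(sigma[0]),
            sigma2=float(sigma[1]),
            log_likelihood=float(ll_path[-1]),
            n_iter=len(ll_path),
            converged=converged,
            log_likelihood_path=ll_path,
        )
    raise DegenerateMixtureError(f"EM failed after {max_restarts} restarts: {last_err}")


def _log_density_ratio(fit: MixtureFit, x: np.ndarray) -> np.ndarray:
    """log of w1*phi1(x) / (w2*phi2(x))."""
    l1 = (
        math.log(fit.w1)
        - math.log(fit.sigma1)
        - 0.5 * ((x - fit.mu1) / fit.sigma1) ** 2
    )
    l2 = (
        math.log(fit.w2)
        - math.log(fit.sigma2)
        - 0.5 * ((x - fit.mu2) / fit.sigma2) ** 2
    )
    return l1 - l2


def mixture_ratio_threshold(fit: MixtureFit, ratio: float = 1.0) -> ThresholdEstimate:
    """Smallest x in [mu1, mu2] where w1*phi1(x)/(w2*phi2(x)) equals ``ratio``.

    ``ratio=1`` gives the equal-density crossing; ``ratio=0.10`` the 10%
    rule. Solved by bisection to 1e-8 after bracketing on a fine grid.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if not fit.converged:
        raise ValueError("mixture fit did not converge; refusing to derive a threshold")
    grid = np.linspace(fit.mu1, fit.mu2, 2048)
    g = _log_density_ratio(fit, grid) - math.log(ratio)
    sign_change = np.nonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]
    exact = np.nonzero(g == 0.0)[0]
    if exact.size and (not sign_change.size or exact[0] <= sign_change[0]):
        x0 = float(grid[exact[0]])
    elif sign_change.size:
        i = int(sign_change[0])
        f = lambda x: float(_log_density_ratio(fit, np.asarray([x]))[0] - math.log(ratio))
        x0 = float(optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-8))
    else:
        raise ValueError(
            f"no density-ratio crossing at ratio={ratio} in [{fit.mu1:.4g}, {fit.mu2:.4g}]; "
            f"ratio range on the interval is [{np.exp(g.min() + math.log(ratio)):.3g}, "
            f"{np.exp(g.max() + math.log(ratio)):.3g}]"
        )
    method = "mixture_equal" if ratio == 1.0 else "mixture_ratio"
    return ThresholdEstimate(value=x0, method=method)
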