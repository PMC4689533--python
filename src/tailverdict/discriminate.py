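"""The discrimination algorithm: aggregate, estimate, bootstrap, classify.

A normalized sum of i.i.d. variables converges (if at all) to a stable law
with some index alpha <= 2.  Summing a series in non-overlapping blocks of
length K = 1, 2, ..., K_max therefore pushes the aggregated data toward its
limiting law: stable data keep their index under aggregation, while any
finite-variance law drifts toward the Gaussian index alpha = 2.  Tracking the
regression estimate of alpha as a function of K makes the domain of attraction
visible:

* estimates flat at (or clipped to) 2       -> light-tailed, Gaussian domain;
* estimates flat at some alpha < 2          -> heavy-tailed, stable domain;
* estimates rising toward 2                 -> light-tailed but slow convergence.

Box plots of bootstrap replicates (resampling the whole series with
replacement) show whether the per-K differences exceed estimator noise; the
boxes widen with K because aggregation shortens the sample.

Block sums are deliberately not renormalized: the regression estimate of alpha
is scale- and location-invariant, so the centering/scaling constants of the
limit theorem would cancel anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cf_estimation import EstimationError, estimate_stable

__all__ = [
    "AlphaCurve",
    "BootstrapResult",
    "BoxplotStats",
    "Verdict",
    "aggregate",
    "alpha_curve",
    "bootstrap_curves",
    "boxplot_stats",
    "classify",
    "verdicts_differ",
]

DEFAULT_K_MAX = 10
DEFAULT_BOOTSTRAP = 100
DEFAULT_DELTA = 0.02


@dataclass(frozen=True)
class AlphaCurve:
    """Estimated stability index per aggregation level K = 1..K_max."""

    K_levels: np.ndarray
    alpha_hats: np.ndarray
    n: int


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number box-plot summary with the 1.5-IQR outlier rule.

    Quartiles use linear interpolation between order statistics (the common
    plotting-package convention; outlier membership depends on it).  Outliers
    are exactly the points above Q3 + 1.5 (Q3 - Q1) or below Q1 - 1.5 (Q3 - Q1);
    whiskers extend to the most extreme values that are not outliers.
    """

    Q1: float
    median: float
    Q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


@dataclass(frozen=True)
class BootstrapResult:
    """B bootstrap alpha-curves from one sample, plus per-K box summaries."""

    B: int
    estimates: np.ndarray  # shape (B, K_max)
    per_K_boxstats: tuple
    seed: object


@dataclass(frozen=True)
class Verdict:
    """Light/heavy call with the inferred limiting index and a rule trace."""

    domain_label: str  # "light" | "heavy" | "inconclusive"
    limiting_alpha: float
    evidence: dict = field(compare=False)


def aggregate(sample, K: int) -> np.ndarray:
    """Sum consecutive non-overlapping blocks of length K (trailing remainder dropped).

    Returns floor(N/K) block sums; K = 1 returns the sample unchanged.
    """
    x = np.asarray(sample, dtype=float)
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > x.size:
        raise ValueError(f"K={K} exceeds the sample length {x.size}")
    m = x.size // K
    return x[: m * K].reshape(m, K).sum(axis=1)


def alpha_curve(sample, K_max: int = DEFAULT_K_MAX) -> AlphaCurve:
    """Estimate the stability index of the block-aggregated series at K = 1..K_max."""
    x = np.asarray(sample, dtype=float)
    levels = np.arange(1, K_max + 1)
    alphas = np.empty(K_max)
    for i, K in enumerate(levels):
        try:
            alphas[i] = estimate_stable(aggregate(x, int(K))).alpha
        except EstimationError as exc:
            raise EstimationError(f"estimation failed at aggregation level K={K}: {exc}") from exc
    return AlphaCurve(K_levels=levels, alpha_hats=alphas, n=int(x.size))


def bootstrap_curves(sample, B: int = DEFAULT_BOOTSTRAP, K_max: int = DEFAULT_K_MAX, seed=None) -> BootstrapResult:
    """Alpha-curves for B bootstrap resamples (whole-series resampling with replacement).

    Each replicate draws N values with replacement from the original series,
    then runs :func:`alpha_curve`; per-K box statistics are computed down the
    columns of the resulting B x K_max matrix.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    x = np.asarray(sample, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    est = np.empty((B, K_max))
    for b in range(B):
        resample = x[rng.integers(0, x.size, size=x.size)]
        est[b] = alpha_curve(resample, K_max).alpha_hats
    stats = tuple(boxplot_stats(est[:, j]) for j in range(K_max))
    return BootstrapResult(B=B, estimates=est, per_K_boxstats=stats, seed=seed)


def boxplot_stats(values) -> BoxplotStats:
    """Box-plot summary of a batch of values (see :class:`BoxplotStats`)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty batch")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    is_out = (v < lo_fence) | (v > hi_fence)
    inliers = v[~is_out]
    return BoxplotStats(
        Q1=float(q1),
        median=float(med),
        Q3=float(q3),
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
        outliers=np.sort(v[is_out]),
    )


def _curve_of(obj) -> np.ndarray:
    if isinstance(obj, AlphaCurve):
        return np.asarray(obj.alpha_hats, dtype=float)
    if isinstance(obj, BootstrapResult):
        return np.median(obj.estimates, axis=0)
    raise TypeError(f"expected AlphaCurve or BootstrapResult, got {type(obj).__name__}")


def classify(curve_or_bootstrap, delta: float = DEFAULT_DELTA) -> Verdict:
    """Turn an alpha curve into a light/heavy/inconclusive verdict.

    The underlying test is visual (does the curve settle on 2, or below 2?);
    this numeric rule is a documented heuristic, not a calibrated hypothesis
    test.  With the per-K curve (bootstrap per-K medians, if given a
    :class:`BootstrapResult`):

    * **light** if the median alpha over the top 3 levels is >= 2 - delta, or
      if the curve is still rising (signed drift last - first >= delta) and its
      final level has already reached 2 - delta (converging to the Gaussian
      index from below);
    * **heavy** if the top-3 median is <= 2 - delta *and* the curve is not
      still rising (drift < delta, or the top-3 range <= 2 delta, i.e. a
      plateau); the limiting index is the top-3 median;
    * **inconclusive** otherwise.
    """
    curve = _curve_of(curve_or_bootstrap)
    if curve.size < 3:
        raise ValueError("need at least 3 aggregation levels to classify")
    top3 = curve[-3:]
    top3_median = float(np.median(top3))
    drift = float(curve[-1] - curve[0])
    plateau = float(top3.max() - top3.min()) <= 2.0 * delta
    evidence = {
        "curve": curve.tolist(),
        "top3_median": top3_median,
        "drift": drift,
        "plateau": plateau,
        "delta": delta,
    }
    if top3_median >= 2.0 - delta:
        label = "light"
        rule = "light: top3_median >= 2 - delta"
    elif drift >= delta and curve[-1] >= 2.0 - delta:
        label = "light"
        rule = "light: rising and final level >= 2 - delta"
    elif drift < delta or plateau:
        label = "heavy"
        rule = "heavy: top3_median <= 2 - delta and (drift < delta or plateau)"
    else:
        label = "inconclusive"
        rule = "inconclusive: below 2 - delta but still rising"
    evidence["rule"] = rule
    return Verdict(domain_label=label, limiting_alpha=top3_median, evidence=evidence)


def verdicts_differ(v1: Verdict, v2: Verdict, delta: float = DEFAULT_DELTA) -> bool:
    """Do two verdicts point at different underlying laws?

    True when the domain labels differ, or when both are heavy but the inferred
    limiting indices are more than ``delta`` apart (two stable laws with
    different alpha).
    """
    if v1.domain_label != v2.domain_label:
        return True
    if v1.domain_label == "heavy":
        return abs(v1.limiting_alpha - v2.limiting_alpha) > delta
    return False
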