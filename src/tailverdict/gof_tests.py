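"""Classical goodness-of-fit battery run alongside the discrimination algorithm.

One- and two-sample Kolmogorov-Smirnov statistics

    D  = sup_x |F_n(x) - F(x)|,        D2 = sup_x |F_{1,n}(x) - F_{2,n}(x)|,

with p-value = P(D >= t) from the asymptotic Kolmogorov distribution; the
Jarque-Bera moment test for Gaussianity; and an Anderson-Darling test for the
stable law whose p-value comes from a parametric bootstrap (simulate from the
fitted stable law, re-fit, recompute the statistic, count exceedances).

These are the tests the discrimination algorithm is compared against: the
two-sample KS statistic looks at the body of the distribution and is nearly
blind to tail differences that block aggregation exposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import kolmogorov
from scipy.stats import chi2

from ._cfinvert import cdf_on_grid
from .cf_estimation import EstimationError, estimate_stable
from .stable_laws import StableParams, stable_cf, stable_rvs

__all__ = [
    "TestResult",
    "edf",
    "ks_one_sample",
    "ks_two_sample",
    "normalize",
    "jarque_bera",
    "ad_stable",
]


@dataclass(frozen=True)
class TestResult:
    """Statistic and p-value of a goodness-of-fit / two-sample test."""

    statistic: float
    p_value: float
    method: str
    details: dict = field(default_factory=dict, compare=False)


def edf(sample):
    """Empirical distribution function of the sample.

    Returns a vectorized right-continuous step function F_n with jumps 1/n at
    the sorted sample points (ties stack).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size == 0:
        raise ValueError("sample is empty")
    n = x.size

    def F(t):
        out = np.searchsorted(x, np.asarray(t, dtype=float), side="right") / n
        return float(out) if np.isscalar(t) else out

    return F


def ks_one_sample(sample, cdf) -> TestResult:
    """One-sample Kolmogorov-Smirnov test of the sample against a continuous CDF.

    The supremum D = sup_x |F_n(x) - F(x)| is attained at a sample point, so it
    is computed exactly from both one-sided gaps there; the p-value uses the
    asymptotic Kolmogorov distribution of sqrt(n) D.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("sample is empty")
    u = np.asarray(cdf(x), dtype=float)
    if np.any((u < 0.0) | (u > 1.0)) or not np.all(np.isfinite(u)):
        raise ValueError("cdf returned values outside [0, 1]")
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    D = float(max(d_plus, d_minus))
    p = float(kolmogorov(np.sqrt(n) * D))
    return TestResult(D, min(max(p, 0.0), 1.0), "ks-one-sample", {"n": n})


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test D2 = sup |F_{1,n} - F_{2,n}|.

    The supremum is evaluated over the jump points of either EDF (where it is
    attained); the asymptotic p-value uses the effective size n1 n2 / (n1 + n2).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    F1 = edf(a)
    F2 = edf(b)
    D2 = float(np.max(np.abs(F1(grid) - F2(grid))))
    ne = a.size * b.size / (a.size + b.size)
    p = float(kolmogorov(np.sqrt(ne) * D2))
    return TestResult(D2, min(max(p, 0.0), 1.0), "ks-two-sample", {"n1": a.size, "n2": b.size})


def normalize(sample) -> np.ndarray:
    """Center by the sample mean and scale by the sample standard deviation (ddof=1)."""
    x = np.asarray(sample, dtype=float)
    sd = np.std(x, ddof=1) if x.size > 1 else 0.0
    if not sd > 0.0:
        raise ValueError("cannot normalize a sample with zero variance")
    return (x - np.mean(x)) / sd


def jarque_bera(sample, n_mc: int | None = None, seed=None) -> TestResult:
    """Jarque-Bera test of Gaussianity: JB = n/6 (S^2 + (Kurt - 3)^2 / 4).

    S and Kurt are the (biased) sample skewness and kurtosis; JB is invariant
    to affine transformations of the data.  The p-value comes from the
    asymptotic chi-square(2) law, or from ``n_mc`` Monte-Carlo Gaussian
    replications when small-sample accuracy matters.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 observations, got {n}")

    def _stat(arr):
        c = arr - arr.mean(axis=-1, keepdims=True)
        m2 = np.mean(c**2, axis=-1)
        if np.any(m2 <= 0.0):
            raise ValueError("zero variance sample")
        S = np.mean(c**3, axis=-1) / m2**1.5
        kurt = np.mean(c**4, axis=-1) / m2**2
        return arr.shape[-1] / 6.0 * (S**2 + (kurt - 3.0) ** 2 / 4.0)

    jb = float(_stat(x))
    if n_mc is None:
        p = float(chi2.sf(jb, df=2))
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null = _stat(rng.standard_normal((int(n_mc), n)))
        p = float((1 + np.sum(null >= jb)) / (n_mc + 1))
    return TestResult(jb, p, "jarque-bera", {"n": n, "n_mc": n_mc})


@lru_cache(maxsize=64)
def _standard_stable_cdf_table(alpha: float, beta: float):
    """(x, pdf, cdf) grids for the standardized stable law (sigma=1, mu=0), by
    FFT inversion of the characteristic function."""
    params = StableParams(alpha=alpha, sigma=1.0, beta=beta, mu=0.0)
    return cdf_on_grid(lambda k: stable_cf(k, params), k_max=128.0, n_points=2**16)


def stable_cdf(x, params: StableParams):
    """CDF of the stable law, via a cached FFT inversion of its characteristic
    function.

    Between grid nodes the CDF is evaluated by a trapezoid-consistent
    correction using the inverted density (error well below 1e-6 in the body);
    beyond the grid it saturates at the edge values.
    """
    xs, pdf, cdf = _standard_stable_cdf_table(
        round(float(params.alpha), 6), round(float(params.beta), 6)
    )
    z = (np.asarray(x, dtype=float) - params.mu) / params.sigma
    dx = xs[1] - xs[0]
    i = np.clip(np.searchsorted(xs, z) - 1, 0, xs.size - 2)
    t = np.clip(z - xs[i], 0.0, dx)
    pdz = pdf[i] + (pdf[i + 1] - pdf[i]) * (t / dx)
    out = np.clip(cdf[i] + t * (pdf[i] + pdz) / 2.0, 0.0, 1.0)
    out = np.where(z <= xs[0], cdf[0], np.where(z >= xs[-1], cdf[-1], out))
    return float(out) if np.isscalar(x) else out


def _ad_statistic(sample, params: StableParams) -> float:
    """Anderson-Darling quadratic EDF statistic against the stable CDF."""
    z = np.clip(stable_cdf(np.sort(np.asarray(sample, dtype=float)), params), 1e-12, 1 - 1e-12)
    n = z.size
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(z) + np.log(1.0 - z[::-1]))))


def ad_stable(sample, n_boot: int = 1000, seed=None) -> TestResult:
    """Anderson-Darling test that the sample follows a stable law.

    The stable parameters are first fitted by the CF regression method; the AD
    statistic is computed against the fitted CDF; the p-value is the parametric
    bootstrap exceedance proportion (``n_boot`` simulations from the fitted
    law, each re-fitted before its statistic is computed), so it lives on the
    grid {0, 1/n_boot, ..., 1}.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 100:
        raise ValueError(f"need at least 100 observations, got {x.size}")
    if n_boot < 100:
        raise ValueError(f"need at least 100 bootstrap replications, got {n_boot}")
    fit = estimate_stable(x)
    observed = _ad_statistic(x, fit.params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        sim = stable_rvs(fit.params, x.size, rng)
        try:
            refit = estimate_stable(sim)
        except EstimationError:
            exceed += 1  # count failures against the null, conservatively
            continue
        if _ad_statistic(sim, refit.params) >= observed:
            exceed += 1
    p = exceed / n_boot
    return TestResult(
        observed,
        p,
        "anderson-darling-stable",
        {
            "n": int(x.size),
            "n_boot": n_boot,
            "fitted": {
                "alpha": fit.alpha,
                "sigma": fit.sigma,
                "beta": fit.beta,
                "mu": fit.mu,
            },
        },
    )
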