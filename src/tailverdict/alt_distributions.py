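"""Comparison laws that are *not* stable yet mimic stable data at moderate n.

Three finite-variance families, all attracted to the Gaussian law, that are
notoriously hard to tell from a nearby stable law on samples of a few thousand
points:

* **Symmetric tempered (truncated Levy) stable** ``T``: a stable Levy measure
  exponentially tilted by e^{-lambda |x|}.  In Levy-triplet language
  (kappa^2, nu, gamma_drift) the general family has

      kappa = 0,
      nu(dx) = (C+ e^{-lambda_+ x} 1_{x>0} + C- e^{-lambda_- |x|} 1_{x<0})
               dx / |x|^{alpha+1},
      gamma_drift = m - \\int_{|x|>1} x nu(dx),

  with C+-, lambda+- > 0, alpha in (0,2), m real.  Only the symmetric case
  m = 0, lambda_+ = lambda_- = lambda, C+- = 1 is simulated here; its Fourier
  transform is

      phi_T(k) = exp{ (lambda + ik)^alpha + (lambda - ik)^alpha - 2 lambda^alpha }.

  All moments are finite, so block sums of T drift toward the Gaussian limit
  even though the central body of T looks stable with the same alpha.

* **Square Gaussian** ``W = sqrt(1 - 2 gamma^2) X + gamma (X^2 - 1)`` with X
  standard normal and gamma^2 <= 1/2: zero mean, unit variance, mildly skewed,
  light-tailed.  (This mixing coefficient gamma is unrelated to the triplet
  drift gamma_drift above; the code keeps the names apart.)

* **Student's t** with nu degrees of freedom, built as Z = U / sqrt(V / nu)
  with U ~ N(0,1) independent of V ~ chi^2_nu.  Power tails ~ |x|^{-1-nu}, but
  for nu > 2 the variance is finite, so t data are Gaussian-attracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from ._cfinvert import InversionError, cdf_on_grid
from .stable_laws import ParameterError

__all__ = [
    "TemperedStableParams",
    "SquareGaussianParams",
    "StudentParams",
    "InversionError",
    "tempered_cf",
    "tempered_rvs",
    "square_gaussian_rvs",
    "student_rvs",
    "student_pdf",
]


@dataclass(frozen=True)
class TemperedStableParams:
    """Symmetric tempered stable law: stability index ``alpha`` in (0, 2) and
    exponential tilting rate ``tempering`` (lambda > 0, inverse sample units)."""

    alpha: float
    tempering: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 2.0):
            raise ParameterError(f"alpha must be in (0, 2), got {self.alpha}")
        if not self.tempering > 0.0:
            raise ParameterError(f"tempering rate must be positive, got {self.tempering}")


@dataclass(frozen=True)
class SquareGaussianParams:
    """Square Gaussian mixing coefficient gamma, with gamma^2 <= 1/2."""

    gamma_mix: float

    def __post_init__(self) -> None:
        if not self.gamma_mix**2 <= 0.5:
            raise ParameterError(f"gamma_mix^2 must be <= 1/2, got gamma={self.gamma_mix}")


@dataclass(frozen=True)
class StudentParams:
    """Student's t degrees of freedom (positive integer)."""

    dof: int

    def __post_init__(self) -> None:
        if not (isinstance(self.dof, (int, np.integer)) and self.dof >= 1):
            raise ParameterError(f"dof must be a positive integer, got {self.dof}")


def tempered_cf(k, params: TemperedStableParams):
    """Fourier transform phi_T(k) of the symmetric tempered stable law.

    Real and positive for every real k (the law is symmetric); phi_T(0) = 1.
    Complex powers are taken on the principal branch.
    """
    a, lam = params.alpha, params.tempering
    karr = np.asarray(k, dtype=complex)
    exponent = (lam + 1j * karr) ** a + (lam - 1j * karr) ** a - 2.0 * lam**a
    out = np.exp(exponent)
    if np.isscalar(k):
        return complex(out)
    return out


@lru_cache(maxsize=32)
def _tempered_inverse_table(alpha: float, lam: float):
    """Cached (cdf, x) grids for inversion sampling of the tempered stable law."""
    params = TemperedStableParams(alpha, lam)

    def log_mod(kk: float) -> float:
        return float(
            ((lam + 1j * kk) ** alpha + (lam - 1j * kk) ** alpha - 2.0 * lam**alpha).real
        )

    k_max = 1.0
    while log_mod(k_max) > -30.0 and k_max < 1e8:
        k_max *= 2.0
    # widen beyond the decay scale: a large k_max means fine x-resolution
    k_max = max(k_max, 40.0)
    x, _pdf, cdf = cdf_on_grid(lambda kk: tempered_cf(kk, params), k_max, 2**14)
    return cdf, x


def tempered_rvs(params: TemperedStableParams, n: int, seed=None) -> np.ndarray:
    """Sample the symmetric tempered stable law by inverse-CDF lookup.

    The density is recovered by FFT inversion of phi_T on a grid wide enough
    that |phi_T| < 1e-12 at the edge (grid failures raise
    :class:`InversionError`, never pass silently), the CDF is interpolated
    monotonically and inverted at uniform draws.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cdf, x = _tempered_inverse_table(float(params.alpha), float(params.tempering))
    u = rng.uniform(cdf[0], cdf[-1], size=n)
    return np.interp(u, cdf, x)


def square_gaussian_rvs(params: SquareGaussianParams, n: int, seed=None) -> np.ndarray:
    """Draw W = sqrt(1 - 2 gamma^2) X + gamma (X^2 - 1), X standard normal.

    Zero mean and unit variance hold exactly in law for every admissible gamma;
    gamma = 0 degenerates to the standard normal itself.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = params.gamma_mix
    X = rng.standard_normal(n)
    return math.sqrt(1.0 - 2.0 * g * g) * X + g * (X * X - 1.0)


def student_rvs(params: StudentParams, n: int, seed=None) -> np.ndarray:
    """Draw Z = U / sqrt(V / nu) with U ~ N(0,1) independent of V ~ chi^2_nu.

    Stream order is fixed and documented: the normal draws U are taken from the
    seeded generator first, the chi-square draws V second, so a given seed
    always reproduces the same sample.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nu = params.dof
    U = rng.standard_normal(n)
    V = rng.chisquare(nu, size=n)
    return U / np.sqrt(V / nu)


def student_pdf(x, params: StudentParams):
    """Student's t density  f(x) = Gamma((nu+1)/2) / (sqrt(pi nu) Gamma(nu/2))
    * (1 + x^2/nu)^{-(nu+1)/2};  symmetric and strictly positive."""
    nu = params.dof
    xarr = np.asarray(x, dtype=float)
    lognorm = gammaln((nu + 1) / 2.0) - 0.5 * math.log(math.pi * nu) - gammaln(nu / 2.0)
    out = np.exp(lognorm - ((nu + 1) / 2.0) * np.log1p(xarr * xarr / nu))
    if np.isscalar(x):
        return float(out)
    return out
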