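# Methods

## The discrimination procedure

`tailverdict` decides whether a univariate i.i.d. series belongs to the domain
of attraction of the Gaussian law (light tails, finite variance) or of a
non-Gaussian α-stable law (heavy tails, infinite variance). The generalized
central limit theorem says a normalized sum of i.i.d. variables converges, if
at all, to a stable law with index α ≤ 2; finite-variance laws go to α = 2,
laws with tails ~|x|^(−1−α), α < 2, keep their index. The procedure makes this
visible:

1. **Aggregate.** Split the series into consecutive non-overlapping blocks of
   length K = 1, …, K_max (default 10) and sum within blocks, keeping
   ⌊N/K⌋ sums and dropping the remainder. Block sums are *not* renormalized:
   the stability-index estimator is location-invariant and scale-equivariant,
   so the limit theorem's centering and scaling constants cancel.
2. **Estimate.** For each K, estimate the stability index α of the aggregated
   series by the characteristic-function regression method (below).
3. **Bootstrap.** Resample the whole series with replacement B times (default
   100), repeat steps 1–2 per replicate, and summarize each aggregation level
   by a box plot (quartiles by linear interpolation between order statistics;
   outliers beyond Q1 − 1.5·IQR / Q3 + 1.5·IQR; whiskers at the most extreme
   non-outliers). Boxes widen with K because aggregation shortens the sample.
4. **Read the curve.** Flat at (or clipped to) 2 → Gaussian domain; flat at
   some α < 2 → stable domain; rising toward 2 → finite variance with slow
   convergence.

The procedure is by construction a *visual diagnostic*, not a calibrated
hypothesis test. `classify` encodes the reading as a documented heuristic with
tolerance δ (default 0.02): **light** if the median estimate over the top
three levels reaches 2 − δ, or if the curve is still rising (last − first ≥ δ)
and its final level has reached 2 − δ; **heavy** if the top-3 median sits
below 2 − δ and the curve has stopped rising (drift < δ, or top-3 range
≤ 2δ); **inconclusive** otherwise. The rising-and-arrived clause is needed so
that a curve climbing from 1.85 to 1.99 — a finite-variance law still
converging — is read as light, matching how one reads the plots. δ = 0.02 is
chosen so that length-2000 Gaussian samples classify light in nearly all
seeds; there is no type-I error guarantee.

## Stable laws and their simulation

Stable laws use one parameterization everywhere (the classical S1 form of the
characteristic function, with index α, scale σ, skewness β, location μ; at
α = 2 the law is Gaussian with variance 2σ²). The α = 1 branch of the CF
carries its skew/log term with a minus sign, the mirror image of the
Samorodnitsky–Taqqu convention; the Chambers–Mallows–Stuck sampler flips β in
its α = 1 branch so sampler and CF agree for every parameter set (verified by
ECF-vs-CF property tests, including α = 1, β = 0.5). Evaluation switches to
the α = 1 branch when |α − 1| < 1e−8; every experiment in this package runs
at α ≥ 1.85, far from the seam. Stable densities are never needed — only the
CF, sampling, and (for the Anderson–Darling test) the CDF via numerical CF
inversion.

## The regression estimator of (α, σ, β, μ)

For the S1 form, log(−log |Φ(k)|²) = log(2σ^α) + α log k, and the phase of
Φ is μk + βσ^α tan(πα/2)·sgn(k)|k|^α. The estimator (Koutrouvelis-type):

* standardize by the sample median and IQR/1.349;
* stage 1: OLS of log(−log |ECF|²) on log k over k_l = πl/25, l = 1..L, with
  L interpolated from the classical lookup tables in (current α̂, n) — about
  9–10 points for α near 2 (initial α̂ from a fixed 10-point grid); grid
  points where |ECF| ≥ 1 − 1e−10 are dropped (counted in diagnostics) since
  the double log requires |ECF| < 1;
* stage 2: regress the cumulatively unwrapped ECF phase on (u, u^α) over
  u_l = πl/50 to get μ and β (unwrapping fixes the arctan branch, which would
  otherwise shift μ̂; β is clipped to [−1, 1] and set to 0 when
  |tan(πα/2)| < 1e−6, i.e. at the Gaussian boundary where it is
  unidentifiable and irrelevant);
* iterate with re-standardization by the current (σ̂, μ̂) until α̂ moves less
  than 1e−3 (max 10 iterations; on non-convergence the last iterate is
  returned with a flag).

Raw stage-1 slopes above 2 are reported as exactly 2 with a `clipped` flag,
so finite-variance data sit on the α = 2 line of the plots. The estimator is
exactly shift-invariant and scale-equivariant because every regression runs
on the standardized sample. Documented minimum sample length: 50.

Measured calibration (exact stable samples, 150–200 seeds): bias below 0.005
and sd(α̂) ≈ 0.033–0.037 at n = 2000 for α ∈ {1.85, 1.9, 1.95}; sd ≈ 0.09 at
n = 200. For Gaussian data the raw slope is centered almost exactly on 2, so
individual estimates clip to 2 in roughly half the seeds and bootstrap per-K
medians sit within 0.003 of 2 essentially always. These sampling widths are
the yardstick for what the aggregation diagnostic can and cannot resolve:
indices closer than ~0.03 at n = 2000 are inside one estimator sd.

## Comparison laws

* **Symmetric tempered stable** (index α, tilting rate λ): all moments
  finite (cumulants κ_m = 2·α(α−1)…(α−m+1)·λ^(α−m) for even m), so it is
  Gaussian-attracted although its central body mimics a stable law of the
  same α. Sampling is by inverse-CDF lookup on an FFT inversion of the CF:
  2^14 grid points, wavenumber half-width chosen so |φ| < 1e−12 at the edge
  (and at least 40, which keeps the x-resolution below 0.08). The cumulative
  integral uses trapezoid accumulation plus an Euler–Maclaurin endpoint
  correction (node error O(dx⁴)); a plain left-Riemann sum would shift every
  draw by −dx/2, a bias the cumulant validation test actually caught during
  development. The inversion refuses to proceed (explicit error) if the CF
  has not decayed at the grid edge — aliasing preserves total mass, so a mass
  check alone cannot detect that failure — or if the recovered mass deviates
  from 1 by more than 1e−3.
* **Square Gaussian** W = √(1−2γ²)X + γ(X²−1), X standard normal, γ² ≤ 1/2:
  zero mean and unit variance exactly, slightly skewed (E W³ = 6(1−2γ²)γ +
  8γ³), light-tailed.
* **Student's t** with ν degrees of freedom, sampled as U/√(V/ν) with one
  seeded generator and a documented stream order (normals first, chi-squares
  second). Power tails ~|x|^(−1−ν); finite variance ν/(ν−2) for ν > 2, hence
  Gaussian-attracted but with the slowest convergence among the fixtures.

## Goodness-of-fit battery

One-sample KS computes D = sup|F_n − F| exactly at the sample points, p-value
from the asymptotic Kolmogorov law of √n·D; the two-sample statistic is
evaluated over the jump points of both EDFs with effective size
n₁n₂/(n₁+n₂) (exact small-sample enumeration is out of scope; rejection
rates match `scipy.stats.ks_2samp` exactly). Jarque–Bera uses the standard
n/6·(S² + (Kurt−3)²/4) statistic with a χ²(2) p-value and an optional
Monte-Carlo small-sample mode. The Anderson–Darling test for the stable law
fits by the regression estimator, evaluates the quadratic EDF statistic
against a cached FFT-inverted stable CDF (k-grid half-width 128, 2^16 points;
between nodes a density-consistent trapezoid correction keeps the CDF error
below 1e−6 in the body), and obtains its p-value by parametric bootstrap
(default 1000 replications, each re-fitted), so p-values live on the grid
{0, 1/B, …, 1}. Measured levels on Gaussian nulls (n = 2000, 500 seeds): JB
4.0%, KS 5.2%, both within the 3–7% band; AD keeps p > 0.05 on ≥ 9/10 exact
stable samples.

## Benchmark scenarios: what they emulate and what they do not

The five built-in pairs (each n = 2000 by default) reproduce the simulation
study conditions exactly: Gaussian(0, √2) vs stable(1.95, 1) — the Gaussian
scale is √2 so its variance matches the α=2, σ=1 stable law, resolving an
ambiguous rendering of the source parameters; tempered stable(1.9, 0.1) vs
stable(1.9, 1) — the stable comparator follows the body text (α = 1.9), not
a figure caption that says 1.95; square Gaussian(γ=0.07) vs
stable(1.97, σ=0.7, β=1, μ=0.1); Student t(4) vs
stable(1.85, 0.77, 0.15, 0.01); stable(1.85, 1) vs stable(1.9, 1). Scenario
seeds split into two independent child streams, one per member.

These are i.i.d. samples. Real series (plasma potential fluctuations,
returns, movement data) carry serial dependence, which block aggregation
partially whitens but the bootstrap (i.i.d. resampling) ignores; passing
tests on these fixtures therefore says nothing about dependent data.

## Measured behavior, repetition counts, and known limitations

The acceptance-style tests regenerate the study under a fixed seed bank
(20 seeds for the per-case quantities; 100 repetitions for the five-pair
contrast) and check the printed outcomes. Two findings deserve honesty:

* **Student's t drift falls just short of its band.** The K ∈ {8,9,10}
  bootstrap-mean estimate averages ≈ 1.94 (not ≥ 1.95): t(4) aggregates
  converge slowly, and whole-series bootstrap resampling duplicates extreme
  observations, depressing aggregated-sample estimates by ~0.02. The rising
  shape — the qualitative signature — is robust.
* **The KS-blindness contrast is weaker than a single realization suggests.**
  Normalizing by the sample standard deviation of infinite-variance data
  de-calibrates the two-sample KS test: even two samples of the *same*
  stable(1.9) law fail-to-reject at 5% in only ~62% of repetitions. Across
  100 repetitions the fail-to-reject rates are 82/67/77/59/50% for the five
  pairs, and the aggregation verdicts differ in 68/84/57/86/92%. The square
  Gaussian pair's stable member (α = 1.97) sits within one estimator sd of
  the light/heavy boundary at δ = 0.02, which caps its separation rate.
  The qualitative claim — aggregation separates pairs KS mostly cannot —
  holds; the margins depend on the pair.

Other numerical choices: bootstrap replicates resample exactly N values
("whole dataset" resampling); the block partition starts at the first
observation with no overlap; for large datasets a flag replaces box plots by
the bootstrap-mean curve; tail plots show the right tail of the series as
given, with an `--abs` flag for |x|. All randomness flows from explicit seeds
recorded in every report, so any report reproduces byte-for-byte from its own
configuration.
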