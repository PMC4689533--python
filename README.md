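# tailverdict

Does a random dataset come from a light-tailed law (finite variance, Gaussian
domain of attraction) or a heavy-tailed one (infinite variance, attracted to
a non-Gaussian α-stable law)? The question arises wherever bursty fluctuation
data must be modeled — edge-plasma turbulence around the L–H transition,
asset returns, animal search trajectories, machine-condition signals — and
standard distribution tests are notoriously weak at it: a Student's t, a
tempered (truncated) Lévy, or a slightly sub-Gaussian stable sample can look
identical to its counterpart in the body of the distribution, where the
Kolmogorov–Smirnov statistic lives.

`tailverdict` implements a diagnostic built on the generalized central limit
theorem instead. A normalized sum of i.i.d. variables converges, if at all,
to a stable law with index α ≤ 2: summing a heavy-tailed series in blocks
leaves its stability index where it is, while any finite-variance series is
dragged toward the Gaussian index α = 2. The procedure:

1. sum the series in non-overlapping blocks of length K = 1, …, 10;
2. estimate the stability index α̂(K) of each aggregated series by the
   characteristic-function regression method (log–log regression of the
   empirical CF modulus, phase regression for skewness/location, iterated
   with re-standardization);
3. bootstrap the whole series (default 100 resamples) and draw a box plot of
   α̂ per K;
4. read the curve: flat at 2 → light tails; flat at α < 2 → heavy tails;
   rising toward 2 → light tails with slow convergence. `classify` encodes
   this reading as a heuristic verdict with tolerance δ (default 0.02).

The package also ships the simulators needed to exercise the method on hard
cases — exact stable sampling (Chambers–Mallows–Stuck), symmetric tempered
stable via characteristic-function inversion, square Gaussian, Student's t —
and the classical comparison battery: one/two-sample Kolmogorov–Smirnov,
Jarque–Bera, and an Anderson–Darling test for the stable law with parametric
bootstrap p-values. See `docs/methods.md` for the model details, parameter
defaults, and measured calibration.

## Worked example

Simulate the hardest-looking pair — a Gaussian with variance 2 next to a
symmetric stable law with α = 1.95 — and compare the two routes:

```sh
$ tailverdict simulate --scenario gaussian_vs_stable --seed 9 --out data
wrote gaussian_vs_stable_a.txt and gaussian_vs_stable_b.txt to data

$ tailverdict compare --a data/gaussian_vs_stable_a.txt \
                      --b data/gaussian_vs_stable_b.txt --seed 9 --out report
series a: light (limiting alpha 2.000)
series b: heavy (limiting alpha 1.963)
two-sample KS (normalized): D2 = 0.0260, p = 0.5085
```

The two-sample KS test sees nothing (p = 0.51 — the samples are
indistinguishable to it), but the aggregation diagnostic calls the Gaussian
series light — its bootstrap medians sit on the α = 2 line at every block
length — and the stable series heavy, with the estimated limiting index
1.96 near the true 1.95. `report/` contains the per-K box-plot figures, the
box statistics as TSV, a log–log tail plot, and a `report.json` that records
every seed, so the run reproduces byte-for-byte.

The same analysis for a single series:

```sh
tailverdict discriminate --input my_series.txt --kmax 10 --bootstrap 100 \
                         --delta 0.02 --seed 1 --out out/
```

or from Python:

```python
from tailverdict import bootstrap_curves, classify

verdict = classify(bootstrap_curves(x, B=100, K_max=10, seed=1), delta=0.02)
print(verdict.domain_label, verdict.limiting_alpha)
```

Five benchmark scenarios are built in (`tailverdict simulate --help`):
Gaussian vs stable(1.95), tempered stable(1.9, 0.1) vs stable(1.9),
square Gaussian(0.07) vs stable(1.97, 0.7, 1, 0.1), Student t(4) vs
stable(1.85, 0.77, 0.15, 0.01), and stable(1.85) vs stable(1.9).

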