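# Methods

## Model

Statistical mirroring turns a univariate dispersion question into a
similarity question. A sample `X` is preprocessed into `A = t(X)` and
compared, as a mirror reflection about a centre `δ`, with its
*statistical mirror* `B = [p] * n`, where `p` is a location estimate of
the transformed data (the *principal value*). The concatenated
`2n + 1`-slot sequence (head-to-head: `a_1..a_n, δ, b_n..b_1`;
tail-to-tail reverses both halves) is re-mapped onto the optiscale
`r_i = i·k`, `i = 1..2n+1`, and summarised by the Kabirian coefficient

    Kc = r_{n+1} (ΣA + δ + ΣB) / Σ_i r_i v_i ,

where `v_i` is the value in slot `i`. `Kc = 1` iff the pair is
identical in aggregate; `Kc = 0` when the structures cancel. The
translation models map `Kc` to the probability of similarity
(proximity): for `0 ≤ Kc ≤ 1`

    Psim = ((n+1)r1 − Kc(2n+1)r1) / (r1·Kc − (n+1)r1),

otherwise the inverse-branch form
`Psim = ((n+1)r1 − r1·Kc) / ((2n+1)r1·Kc − (n+1)r1)`. The deviation is
`Pdev = 1 − Psim` (`Psim ≥ 0`) or `−1 − Psim`. The backward maps return
the two bi-coefficients

    Kcalt1 = (n+1)r1(Psim+1) / (r1·Psim + (2n+1)r1),
    Kcalt2 = (n+1)r1(1+Psim) / (r1 + Psim(2n+1)r1),

one per branch; forward and backward translations close on each other
(the Y-rule), which the tests assert to 1e−12.

Because every formula is homogeneous of degree one in the optiscale,
the estimates are invariant to the interval `k` and to the optiscale
sign; `k = 1`, positive, is the default and the only exercised choice.

## Assumptions and invariances

- Ordering is compulsory, so the given order of observations is not
  preserved: all estimates are permutation-invariant and the method is
  unsuitable when serial patterns matter.
- *Raw* presets (no centring) are scale-invariant for `a > 0`; negating
  the data can flip the coefficient branch, so invariance under `a < 0`
  is not claimed for raw presets.
- *Absolute* presets (centred, absolute distances) are
  scaloc-invariant: `Pprox(aX + b) = Pprox(X)` for any `a ≠ 0`, `b`.
- Meanic presets are additionally invariant to the pairing style (the
  head-to-head and tail-to-tail coefficients are exactly the two
  bi-coefficients of the same `Psim`) and to whole-set duplication of
  the sample (`Pprox`/`Pdev` only — `Kc` itself changes with `n`).
  Non-meanic presets enjoy neither.
- `Pprox`, `Pdev` are bounded in `[−1, 1]` for all presets.

## Degenerate inputs and numerical choices

- All arithmetic is double precision; comparisons against 4-decimal
  printed values use tolerance 5e−5 (one place, a percent-scale CV, is
  asserted at 1e−4 because the reference print rounds its last digit
  down).
- `n = 1` is legal (`Kc = Pprox = 1`); empty data is an error.
- An all-zero construction (0/0) is defined as `Kc = 1`, the
  identical-structures limit, with a runtime warning.
- A zero denominator with nonzero numerator raises a degenerate-
  construction error.
- *Integral meanic* mirroring (signed mean-centring with a mean mirror)
  forces both structure sums to zero and hence `Kc = 0` analytically;
  it is permitted but warns, and is not part of the evaluated battery.
- Mode is the most frequent exact value, ties broken toward the
  smallest; all-distinct data raises a modal-undefined error rather
  than silently picking a value.
- `pdev_to_psim` is the branchwise inverse of `psim_to_pdev`; the two
  branches collide at `pdev = 0`, where the non-negative branch wins,
  so `psim = −1` is the one point that does not round-trip.
- Sorting is stable; duplicates are legitimate data (the duplication
  study depends on them).

## Simulation design (the study conditions)

The published parameter grids are not recoverable from the source
figures, so the generator fixes its own defaults once and treats any
other grid as configuration:

- **Normal design**: sample sizes {10, 20, 50, 100, 200} × means
  {0, 2, 5, 10, 20} × sigmas {0.5, 1, 2, 5, 10} — 125 combinations,
  S = 1000 iterations per cell by default.
- **Mixture design**: 11 contamination levels 0, 0.05, …, 0.50 × 5
  parameter pairs × 5 shape pairs at N = 100 — 275 combinations.
  Location-shift scenario: contaminant mean `μ + 10`, same sigma.
  Scaling scenario: same mean, contaminant sigma `5σ`. These magnitudes
  make the contaminant a clear outlier component at realistic base
  scales.
- Contamination is Bernoulli per observation. Each (combination,
  iteration) cell draws from a child seed `SeedSequence(master, combo,
  iteration)`; the clean partner is the base-component draw itself, so
  a contaminated dataset and its clean pair differ only in the masked
  slots and the `p = 0` pair is bit-identical — sensitivity at level 0
  is exactly zero by construction.

The generator emulates the contamination structure of real outlier-
bearing data but not heavy-tailed, skewed, or serially dependent data;
passing tests therefore demonstrate robustness under Gaussian-mixture
contamination only.

## Evaluation metrics

Estimates `β` are averaged per cell over the S iterations (absolute
values first for sign-carrying estimators, i.e. the CV). Efficiency is
the population variance (divisor S) of the min-max-normalized estimate
vector, computed within each (estimator, cell) — normalization is not
pooled across cells, so location/scale influences cancel before
variances are compared. Relative efficiency is `Eff_ref / Eff_prop`
(< 1 favours the proposed estimator). Percentage sensitivity is
`100·|β̄̂ − β̄|/β̄` per cell; the sensitivity curve is its mean across
parameter combinations per contamination level, and the resistance
threshold is the largest level keeping the curve at or below 5 %,
linearly interpolated between simulated levels (a curve never exceeding
the threshold reports the grid maximum, flagged as saturated).
Efficiency groups are compared with the two-tailed unpaired Student
(equal-variance) t-test.

The in-repo contamination study runs the default mixture grids at
S = 200 (both scenarios finish in well under a minute); at that scale
the absolute-meanic `Pdev` threshold exceeds the standard deviation's
under both location-shift and scaling contamination (measured ≈ 1.5 %
vs 0.2 % and ≈ 1.8 % vs 0.5 % at seed 20240416). Threshold magnitudes
are grid-dependent; only the ordering is asserted.

## Temperature demonstration

Each temperature scale is an affine map of Celsius; the packaged
12-month series run through the battery exposes each estimator's
invariance class. The Delisle conversion follows the source exactly,
where its printed formula coincides with the Fahrenheit one; the
historical negative-slope Delisle transform is deliberately not
substituted, and the demonstration's reference checks therefore exclude
that column (its published values are not consistent with the printed
formula, nor are the Romer/Newton standard deviations, which appear
decimal-shifted).

## Known limitations

- Univariate only; no multivariate extension.
- Only meanic mirroring is evaluated by the benchmark harness; the
  medianic/modalic/extremal/reference variants are implemented and
  tested for their mechanics but not benchmarked.
- Statistical mirroring is not location-shift-invariant in the raw
  form, and not a substitute for the standard deviation where a
  location-shift-invariant estimator is specifically required.
- Optinalytic normalization (nonzero centre modulation) is out of
  scope: `δ` is accepted but always 0 in the pipeline.
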