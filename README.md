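# nqdist

Non-quadratic statistical distances for model assessment: total variation,
the mixture index of fit (π\*), and the Kullback–Leibler family, for finite
discrete distributions and univariate continuous samples, plus a
contamination-model Monte Carlo study that evaluates them as measures of
model misspecification.

## Why these distances

When a parametric model `m` is fit to data generated by an unknown truth
`τ`, a statistical distance `ρ(τ, m)` prices the cost of the
misspecification. Quadratic distances (Pearson χ², Hellinger) are the
usual yardsticks; this package implements the non-quadratic ones, whose
values carry direct population interpretations:

- **Total variation** `V(τ, m) = ½ Σ_t |τ(t) − m(t)|` (or ½∫|τ − m| for
  densities) is the largest error in probability one can make by using `m`
  in place of `τ` for any event: `V = sup_A |P_τ(A) − P_m(A)|`. It is a
  metric on `[0, 1]`, convex in both arguments, invariant under one-to-one
  transformations, and locally equivalent to the Fisher information
  number.
- **Mixture index of fit**
  `π*(τ, m) = inf{π : τ = (1 − π) m + π e, e arbitrary}` is the smallest
  fraction of the population that must be declared "outliers" for the
  model to describe the rest perfectly. Closed form:
  `π* = sup_t [1 − τ(t)/m(t)]`. The family-minimized version
  `π*(τ, M) = inf_θ π*(τ, m_θ)` scores a whole model family. The related
  W index `W = V/(1 + V) ∈ [0, ½]` is the common contamination level at
  which `τ` and `m` admit a shared two-component representation.
- **Kullback–Leibler / likelihood distances**
  `K²(τ, m) = Σ m log(m/τ)` and `λ²(τ, m) = Σ τ log(τ/m)` (note the
  argument order of `K²`: the model sits in front), their symmetric sum
  (J divergence), and the chi-squared benchmarks `P²`, `S²` with the
  orderings `λ² ≤ P²` and `S² ≤ (64/9) λ²`.

Comparing a discrete sample with a continuous model is degenerate for
total variation (the distance is identically 1), so the sample is first
smoothed with a normal kernel and the distance is computed density to
density by quadrature — "discretization robustness".

## Worked example

```python
>>> import numpy as np
>>> from nqdist import (Normal, NormalMixture, total_variation,
...                     pistar_fixed_discrete, tv_sample_model, pistar_family)

# discrete: truth (0.7, 0.3) against model (0.5, 0.5)
>>> total_variation([0.7, 0.3], [0.5, 0.5]).value
0.19999999999999998
>>> pistar_fixed_discrete([0.7, 0.3], [0.5, 0.5]).pi_star
0.4

# continuous: a half-contaminated sample scored against N(0,1)
>>> mix = NormalMixture([0.5, 0.5], [0.0, 5.0], [1.0, 1.0])
>>> x = mix.sample(5000, seed=1)
>>> tv_sample_model(x, Normal()).value
0.4896513923940622
>>> res = pistar_family(x, seed=1)
>>> round(res.pi_star, 3), tuple(round(v, 2) for v in res.theta_hat)
(0.502, (0.0, 1.09))
```

The TV value ≈ 0.49 says: using N(0,1) for this half-contaminated
population misassigns at most ~49% probability to some event — here,
essentially the mass of the N(5,1) cluster. The fitted mixture index
≈ 0.50 says half the population must be set aside before a single normal
fits the remainder; the minimizing normal (mean ≈ 0, sd ≈ 1.1) matches the
base component, slightly widened by the kernel bandwidth.

The same operations are available from a shell:

```sh
nqdist dist --measure tv --tau tau.csv --m m.csv
nqdist cdist --measure tv --sample x.csv --model '{"family":"normal","theta":[0,1]}'
nqdist pistar --sample x.csv --family normal --theta0 0,1
nqdist simulate --out results/ --reps 500 --seed 1
nqdist verify
```

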