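# Methods

## Model and scope

Each of k ≥ 2 trials reports an effect estimate θ̂ᵢ on an additive scale
(log rate ratio, log hazard ratio, mean difference) with standard error σᵢ,
and the estimates are taken to be independently normal around trial-specific
true effects: θ̂ᵢ | θᵢ ~ N(θᵢ, σᵢ²). The one-sided p-value function of trial
i is pᵢ(μ) = 1 − Φ((θ̂ᵢ − μ)/σᵢ) for the alternative θᵢ > μ ("greater") and
its mirror image for "less". Only one-sided alternatives are supported:
two-sided p-value functions can be non-monotone and produce disjoint
confidence regions, and trial hypotheses have a defined direction of
benefit.

A combiner g maps the k per-trial p-values to a single p-value that is
uniform under the null whenever the inputs are; the combined p-value
function p(μ) = g(p₁(μ), …, p_k(μ)) is then continuous and strictly
monotone in μ, so it has a well-defined inverse μ̂(a) ("estimation
function"). The median estimate is μ̂(1/2); a two-sided (1 − α) CI is
[μ̂(α/2), μ̂(1 − α/2)] (reported sorted, so it is valid for either
alternative); the two-sided p-value at a null value μ₀ is the centrality
transform 2·min{p(μ₀), 1 − p(μ₀)}. By construction these are mutually
compatible: the two-sided p at μ₀ is below α exactly when the (1 − α) CI
excludes μ₀, and the median estimate lies in every CI.

Implemented combiners: squared maximum (the regulatory two-trials rule,
Wilkinson's r = k case), inverse-variance weighted Stouffer (fixed-effect
meta-analysis), minimum (Tippett, Wilkinson r = 1), product (Fisher, upper
χ²₂ₖ tail of −2Σ log pᵢ), product of complements (Pearson, lower χ²₂ₖ tail
of −2Σ log(1 − pᵢ)), sum (Edgington, Irwin–Hall CDF of order k), and the
general Wilkinson r-of-k rule (binomial upper tail at the r-th smallest
p-value). Out of scope: random-effects pooling, weighted or
dependence-adjusted variants of the non-Stouffer combiners, exact/mid-p
p-value functions, harmonic-mean/Cauchy/inverse-chi-square combiners.

## Closed-form inversions

Let z_q denote the standard normal quantile. For alternative "greater"
(mirrored for "less"):

- squared maximum: the combined p equals a when the largest pᵢ equals
  a^{1/k}, so μ̂(a) = minᵢ {θ̂ᵢ + σᵢ z at a^{1/k}}. For a = 1/2 and equal σ
  this puts the median z at √½ ≈ 0.545 standard errors above the smaller
  estimate, and the equal-trials 95% CI quantiles are z at √0.025 ≈ −1.00
  and z at √0.975 ≈ 2.24.
- minimum: μ̂(a) = maxᵢ {θ̂ᵢ − σᵢ z at (1 − a)^{1/k}}.
- meta-analysis: μ̂(a) = θ̂_MA + σ_MA z_a with inverse-variance pooling.
- sum (two trials): median = (θ̂₁/σ₁ + θ̂₂/σ₂)/(1/σ₁ + 1/σ₂). This
  inverse-SE weighted mean is specific to k = 2; for k > 2 the sum rule is
  inverted numerically (the analogous weighted mean is *not* its median).
- identical trials (θ̂₁ = θ̂₂, σ₁ = σ₂, k = 2): Fisher μ̂(a) = θ̂ + σ z at
  exp{−χ²₄(1 − a)/4} (median shift ≈ −0.171σ), Pearson the mirror image,
  Edgington μ̂(a) = θ̂ + σ z at √(a/2) for a ≤ 1/2 and θ̂ − σ z at
  √((1 − a)/2) above (symmetric CI, 12.2% narrower than the pooled CI).

Every other case is inverted by bracketed Brent root-finding: initial
bracket [min θ̂ᵢ − 10 max σᵢ, max θ̂ᵢ + 10 max σᵢ], doubled on failure up to
60 times, absolute μ-tolerance 1e-12·max(σᵢ, 1). Monotonicity makes the
root unique, and the closed-form and numeric paths are required by tests to
agree to 1e-8·max σᵢ. An exact a = 1/2 routes to the closed-form medians
where they exist.

The quantile orders above (√a, √(1 − a), √(a/2), exp{−χ²₄(·)/4}) were each
derived by direct algebraic inversion of the combiner and validated against
the numeric inverter and the anchor constants (0.545, −1.00/2.24, −0.171,
1.217, the 12.2% narrowing).

## Numerical choices

- Irwin–Hall CDF (sum rule, order k): exact alternating sum
  (1/k!)Σⱼ(−1)ʲC(k,j)(x−j)ᵏ accumulated with `math.fsum`; the terms
  alternate and grow with k, so compensated summation keeps full precision
  up to k = 30, beyond which the order is refused rather than silently
  approximated.
- Tail safety: Fisher/Pearson clip p-values (or complements) at 1e-300
  before logs, warning only when a true zero was clipped. The μ-indexed
  function computes 1 − pᵢ via the mirrored normal tail instead of
  subtraction, and meta-analysis uses the z-statistic
  (θ̂_MA − μ)/σ_MA directly, so both stay accurate far into the tails.
- Ties and degenerate inputs: equal estimates make min/max expressions
  harmless; implicit weights are refused (undefined) when θ̂₁ = θ̂₂; p = 1/2
  does not identify a standard error in `se_from_p` and is rejected; the
  Edgington branch point E = 1 is continuous (both branches give 1/2).
- When several uncertainty summaries are supplied for a trial, precedence
  is SE > CI > p (the standard error is the primitive; CI and p are rounded
  derivatives), with a warning when they disagree beyond 1% relative.

## Operating characteristics

Closed forms: the squared-maximum median for equal σ has expectation
θ₁Φ(δ) + θ₂Φ(−δ) + σ(z at √½ − √2 φ(δ)), δ = (θ₂ − θ₁)/(√2σ) — the
expectation of a minimum of two normals plus the fixed quantile offset —
giving bias σ(z at √½ − 1/√π) ≈ −0.019σ under equal effects, and standard
error σ√(1 − 1/π) ≈ 0.826σ (≈17% below each trial). Meta-analysis has
σ_MA = (1/σ₁² + 1/σ₂²)^{−1/2} ≤ min σᵢ; Edgington's median has
σ_E = √2/(1/σ₁ + 1/σ₂), which satisfies σ_E ≥ σ_MA with equality iff
σ₁ = σ₂ (AM–QM), and σ_E ≤ min σᵢ only when √2 − 1 ≤ σ₂/σ₁ ≤ √2 + 1. The
unequal-σ squared-maximum SE depends on the true effects and has no closed
form here; it is delegated to Monte Carlo.

Asymptotic targets (σᵢ ↓ 0 at fixed variance ratio c = σ₁²/σ₂²): the
squared maximum and Pearson converge to the less extreme true effect,
Tippett and Fisher to the more extreme, meta-analysis to
θ₁/(1+c) + θ₂/(1+1/c), and Edgington's median to the same form with √c.
Edgington's CI limits converge to min and max of the true effects, so its
interval never collapses under heterogeneity — it is the only combiner
here whose CI asymptotically retains both effects.

The Monte Carlo engine draws θ̂ᵢ ~ N(θᵢ, σᵢ²) and inverts the combined
p-value function per replicate using array-valued closed forms where
available and a 90-step vectorized bisection otherwise; tests pin the
vectorized path to the scalar root-finding path. Coverage is assessed at
the common true effect under homogeneity and at the method's own asymptotic
target (its estimand) under heterogeneity. Defaults: n_sim = 1e5 with a
mandatory seed, so the 3-Monte-Carlo-SE tolerances used in tests have known
precision.

## What the simulations do and do not show

`generate_random_pair`/`simulate_oc` emulate exactly the normal
summary-statistic model above: independent trials, known standard errors,
no heterogeneity beyond fixed unequal true effects, no selection or
publication effects, no small-sample or non-normal likelihood features.
Passing tests therefore validate the combination and inversion machinery
under the model's own assumptions; they say nothing about how well the
normal approximation fits any particular trial's likelihood — that is the
user's transformation choice (effects must enter on an additive scale).

## Worked-example inputs

The bundled fixtures are the published summary rows of two pairs of
bronchiectasis trials of inhaled ciprofloxacin (RESPIRE 1/2, 14- and 28-day
regimens; ORBIT 3/4, primary and secondary endpoints), each as estimate,
95% CI and one-sided p-value with alternative "less". Trial standard errors
are reconstructed from the printed 95% CIs, which reproduces the published
combined estimates and CIs at their 2-decimal precision; combined p-values
at the null are instead computed directly from the printed one-sided trial
p-values, which reproduces the published 5-decimal p-values to one unit in
the last digit. Keeping the two pathways separate isolates the two rounding
routes in the printed inputs.

## Known limitations

- Only summary-level inputs; no patient-level modelling, no rate-ratio
  estimation from event counts.
- The two-trials-rule analytic expectation/SE cover the equal-σ (and for
  the SE, equal-effect) case only, as derived; everything else is Monte
  Carlo.
- The Wilkinson r-of-k combiner has closed-form inversion only at r = 1 and
  r = k; intermediate ranks are numeric.
- Implicit weights are defined for two trials only.
- Reported default levels are 0.95 and 0.99875; the latter aligns two-sided
  CIs with the one-sided α² = 0.000625 decision rule of two independent
  trials at α = 0.025.
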