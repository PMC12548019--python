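# pvalfn

Combined p-value function inference for evidence from two (or more)
clinical trials.

Drug regulators usually require two pivotal trials, each significant on its
own (the "two-trials rule"), but that rule by itself yields no combined
effect estimate or confidence interval — and the usual fix, fixed-effect
meta-analysis, can exclude the null value even when the two-trials rule
fails. `pvalfn` resolves this by treating both procedures (and four further
p-value combination methods: Tippett's minimum, Fisher's product, Pearson's
product of complements, Edgington's sum) as *combined p-value functions*
μ ↦ p(μ) = g(p₁(μ), …, p_k(μ)), where pᵢ(μ) = 1 − Φ((θ̂ᵢ − μ)/σᵢ) is trial
i's one-sided p-value function under the normal summary model
θ̂ᵢ ~ N(θᵢ, σᵢ²). Inverting p(μ) gives, for every method:

- a **median estimate** μ̂(½) (median unbiased under effect homogeneity),
- **confidence intervals** [μ̂(α/2), μ̂(1 − α/2)] at any level,
- a **combined one-sided p-value** p(μ₀) at any null value,

all mutually *compatible*: the two-sided p-value 2·min{p(μ₀), 1 − p(μ₀)}
falls below α exactly when the (1 − α) CI excludes μ₀, at every α. The
methods differ in their estimand under heterogeneity — the two-trials rule
and Pearson target the less extreme true effect, Tippett and Fisher the
more extreme, meta-analysis and Edgington weighted averages — and the
package also provides the analytic bias/SE results and a seeded Monte Carlo
engine to study those operating characteristics.

## Worked example

The bundled `respire_14d` fixture holds the published summaries of the two
RESPIRE trials (14-day regimen) of inhaled ciprofloxacin in bronchiectasis:
log rate ratios −0.49 (95% CI −0.85 to −0.13, one-sided p = 0.00351) and
−0.18 (−0.53 to 0.16, p = 0.14400), alternative "less".

```sh
pvalfn combine --fixture respire_14d
```

```
         method  estimate  weight_trial1  ci_lower  ci_upper  ci_width  p_onesided
two_trials_rule     -0.28           0.31     -0.57     -0.00      0.57     0.02074
  meta_analysis     -0.33           0.48     -0.58     -0.08      0.50     0.00424
        tippett     -0.39           0.68     -0.67     -0.08      0.60     0.00701
         fisher     -0.35           0.55     -0.64     -0.08      0.56     0.00434
        pearson     -0.31           0.43     -0.58     -0.04      0.54     0.01138
      edgington     -0.33           0.49     -0.63     -0.04      0.59     0.01088
```

Reading the rows: the two-trials rule gives the most conservative estimate
(−0.28, pulled toward the weaker trial, weight 0.31 on RESPIRE 1) and a
combined one-sided p of 0.02074 = max(0.00351, 0.144)² — not significant at
the regulatory one-sided α² = 0.025² even though the meta-analytic 95% CI
(−0.58, −0.08) excludes zero with p = 0.00424. Tippett's minimum rule is
the most anti-conservative (−0.39, weight 0.68 on the stronger trial);
Edgington's sum rule and meta-analysis land in between on weighted
averages. Every row's p-value, estimate and CI are compatible with each
other by construction. `--level 0.99875` adds the regulatory
99.875% = (1 − 2·0.025²) interval; `--full-precision` removes the display
rounding; `--curves out.csv` exports the full p-value functions for
plotting.

The same computation from your own files: `pvalfn combine --input
trials.csv --alternative less` with columns `id, estimate`, and any of
`se` | `ci_lower, ci_upper[, ci_level]` | `p_onesided`. Monte Carlo
operating characteristics over a scenario grid: `pvalfn simulate --config
scenarios.yaml --out oc.csv`. Everything is also available as library
functions (`PValueFunctionSpec`, `full_inference`, `inference_table`,
`simulate_oc`, …).

## Layout

- `pvalfn.core` — trial summary types, standard-error reconstruction from
  CI or one-sided p, input parsing.
- `pvalfn.combine` — the seven combiners, the μ-indexed combined p-value
  function, Irwin–Hall CDF, centrality transform, curve export.
- `pvalfn.estimation` — closed-form and root-finding inversion, median
  estimates, CIs, implicit weights, result tables.
- `pvalfn.oc` — analytic bias/SE/asymptotic targets and the seeded Monte
  Carlo engine.
- `pvalfn.fixtures` — published trial summaries with provenance.
- `pvalfn.cli` — the `pvalfn` command.

See `docs/methods.md` for the model, the restored closed forms, numerical
choices and limitations.
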