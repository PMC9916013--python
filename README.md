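# expobayes

Bayesian compliance testing for occupational dust exposure. The package is
aimed at occupational hygienists and exposure scientists who must decide,
from limited full-shift monitoring data, whether a job title's exposure is
under control relative to an occupational exposure limit (OEL) — here
respirable coal-mine dust with an OEL of 2 mg/m³.

## Model

Within a job title, eight-hour time-weighted average (TWA8h) concentrations
y are lognormal: ln y ~ N(μ, σ²), with GM = e^μ and GSD = e^σ. The decision
statistic is the 95th percentile of the exposure distribution,

    P95 = exp(μ + z₀.₉₅ σ),   z₀.₉₅ = 1.6449,

compared against the OEL through four control categories: P95 < 0.1·OEL
(very highly controlled), [0.1, 0.5)·OEL (highly controlled), [0.5, 1)·OEL
(adequately controlled), ≥ OEL (poorly controlled).

The posterior of (μ, σ) is sampled by a two-block Gibbs sampler whose full
conditionals are truncated to a bounded box on (GM, GSD) by inverse-CDF.
Three priors are supported:

* **non-informative** — uniform on (ln GM, ln GSD) over the box;
* **historical** — μ ~ N(ȳ₀, s²ᵧ₀/n₀), σ² ~ InvGamma((n₀−1)/2,
  (n₀−1)s²ᵧ₀/2), with ȳ₀ = ln GM and s²ᵧ₀ = (ln GSD)² from an earlier
  monitoring campaign;
* **expert** — the same conjugate pair, with (ȳ₀, s²ᵧ₀) pooled from an
  elicited panel: each expert's (best guess, min, max, confidence) is
  standardised to a common 70% credible level, read as lognormal quartiles,
  fitted by least squares on the CDF, and averaged with equal weights.

Job titles observed in several homogeneous exposure groups (HEGs) are first
screened with a Kruskal–Wallis test; a significant median difference across
HEGs (p < 0.05) excludes the title from the Bayesian step.

The raw study measurements are not deposited, but the lognormal likelihood
is sufficient in (n, mean of logs, SD of logs), so `expobayes.cohort`
rebuilds exactly moment-matched datasets from the published per-job-title
(n, GM, GSD) — every posterior below is a function of published numbers
only.

## Worked example

```python
import expobayes as eb

spec = eb.GeneratorSpec("CM Operator", n=116, target_gm=1.28, target_gsd=3.30, seed=7)
values = [r.twa8h for r in eb.generate_matched_lognormal(spec)]
data = eb.log_sufficient_stats(values)

draws = eb.gibbs_sample(
    data,
    eb.PriorSpec("noninformative"),
    eb.ParameterSpace.default_box(1.28),
    eb.MCMCSettings(chains=4, iterations=25_000, burn_in=5_000, seed=1),
)
s = eb.summarize_posterior(draws)
print(f"GM  {s.gm.median:.2f} ({s.gm.lo:.2f}, {s.gm.hi:.2f})")
print(f"P95 {s.p95.median:.2f} ({s.p95.lo:.2f}, {s.p95.hi:.2f})")
print("category %:", eb.category_probabilities(draws.flat("p95")).as_percent())
```

prints

```
GM  1.28 (1.03, 1.59)
P95 9.24 (6.78, 13.39)
category %: (0.0, 0.0, 0.0, 100.0)
```

The posterior median GM of 1.28 mg/m³ sits below the 2 mg/m³ OEL, but the
P95 — the compliance statistic — is far above it: effectively all posterior
mass puts this job title in category 4 (poorly controlled).

## Analysis pipeline

The numbered drivers under `analysis/` rerun the whole study end to end and
write their tables under `results/`:

1. `01_build_cohort.py` — regenerate the 10-job-title cohort (455 current
   and 108 historical observations) from its published summaries;
2. `02_expert_priors.py` — synthetic elicitation panels and pooled expert
   priors (the raw judgements were never published);
3. `03_fit_posteriors.py` — posterior GM/GSD/P95 and category probabilities
   for every job title under all three prior variants;
4. `04_sensitivity.py` — the parameter-space sensitivity grid for the pump
   attendant and shuttle car operator.

The same steps are available as a CLI: `expobayes run`, `expobayes
sensitivity`, `expobayes simulate`.

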