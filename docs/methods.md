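# Methods

## Model and assumptions

Full-shift TWA8h concentrations within one job title are treated as
i.i.d. lognormal: ln y ~ N(μ, σ²), GM = e^μ, GSD = e^σ. Measurements are
exchangeable — no within-worker autocorrelation or repeated-measures
structure is modelled. The compliance statistic is P95 = exp(μ + z₀.₉₅σ)
with z₀.₉₅ fixed at 1.6449 (the 4-decimal standard-normal quantile), and
decisions are expressed as posterior probabilities of P95 falling in four
OEL-relative control categories with boundaries 0.1·OEL, 0.5·OEL and OEL.
Each boundary belongs to the upper category (a P95 exactly at the OEL is
"poorly controlled"). Category probabilities are exact draw fractions and
sum to 1 before any rounding; rounding to two decimals happens only in the
reporting layer.

The posterior is restricted to a box on (GM, GSD): concentrations cannot be
zero or unbounded, and a GSD below 1 is dimensionally impossible. A stated
GSD lower bound below 1 is accepted but clamped to 1 with a warning. The
default box is GM ∈ [10⁻⁵, 100·sample GM], GSD ∈ [1.01, 10] — wide enough
that it never binds at the data scales analysed here; an "unrestricted" box
(GM ∈ [10⁻¹², 10¹²], GSD ∈ (1, 10⁶]) and a "just above the sample value"
box (upper bounds = sample GM + 0.01, sample GSD + 0.01) are provided for
sensitivity analysis.

## Priors

* Non-informative: uniform on (μ, σ) = (ln GM, ln GSD) over the box. The
  uniform is placed on σ, not σ²; the induced conditional for σ is handled
  exactly (below).
* Informative: μ ~ N(ȳ₀, s²ᵧ₀/n₀) and σ² ~ InvGamma(a, rate) with
  a = (n₀−1)/2, rate = (n₀−1)s²ᵧ₀/2. Two parameterisations of the second
  inverse-gamma argument circulate (rate and its reciprocal);
  `ig_shape_scale` returns both and the sampler consumes the shape/rate
  form. n₀ > 1 is required.
* Historical priors take ȳ₀ = ln GM and s²ᵧ₀ = (ln GSD)² from an earlier
  campaign's summary, with n₀ defaulting to the historical sample size
  (override available, e.g. n₀ = 5 to cap the prior weight at roughly
  10–40% of the current data).
* Expert priors: each expert's (B, L, U, C) is standardised to the S = 70%
  credible level by linear extrapolation, B − (B−L)·S/C and B + (U−B)·S/C,
  truncated into [0, 100]; (standardised min, B, standardised max) are read
  as (Q1, median, Q3); a lognormal is fitted per expert by least squares on
  the CDF at probabilities (0.25, 0.5, 0.75); fits are pooled with equal
  weights (mean of meanlogs, mean of sdlog²) with n₀ = 5 by default.
  The elicited quantity is a percentage, yet its fitted log-scale
  parameters are consumed directly as a prior on log concentration; this
  dimensional mismatch is inherent to the elicitation design being
  reproduced and is flagged here rather than resolved.

Quartile fitting is deterministic: a closed-form seed (meanlog = ln median,
sdlog = ln(Q3/Q1)/(2·0.67449)) is returned immediately when it already fits
exactly (log-consistent triples); otherwise a fixed coarse grid of starts
around the seed is refined by Nelder–Mead and ties are broken toward the
smallest sdlog. Degenerate triples (Q1 = Q3, non-positive quantiles) are
rejected.

## Gibbs sampler

Two-block Gibbs on (μ, σ), all truncations by inverse CDF on the truncated
support — never unbounded rejection, so every retained draw is inside the
box by construction.

* μ | σ²: truncated normal. Informative: precision n₀/s²ᵧ₀ + n/σ², mean the
  precision-weighted combination of ȳ₀ and the data mean ȳ. Non-informative:
  N(ȳ, σ²/n).
* σ | μ, informative: σ² ~ InvGamma((n₀−1)/2 + n/2,
  [(n₀−1)s²ᵧ₀ + Σ(ln yᵢ − μ)²]/2) truncated to the box, drawn through
  1/σ² ~ Gamma(·) with `gammainc`/`gammaincinv`.
* σ | μ, non-informative: density ∝ σ^(−n) exp(−SS(μ)/(2σ²)) on the box.
  The change of variables t = σ⁻² makes this Gamma((n−1)/2, rate SS(μ)/2)
  truncated to [σ_hi⁻², σ_lo⁻²], so the draw is the exact inverse CDF of
  the conditional — chosen over a gridded numeric inverse CDF because it is
  both exact and cheaper.

Chains advance in lock-step as vectorised draws; they differ only through
the RNG stream, and each (job title, prior variant) cell derives its own
substream from the master seed by CRC-32 hashing of the labels, so adding
or removing cells never perturbs other cells' draws. Chains start from the
sample statistics (clipped to the box) with small jitter. Defaults: 4
chains × 25,000 iterations, 5,000 burn-in, no thinning. A truncation region
containing essentially no posterior mass (CDF mass below ~10⁻³⁰⁰) raises a
diagnostic error naming the bounds rather than returning degenerate draws.

Convergence uses the classical Gelman–Rubin statistic,
R̂ = √(((n−1)/n·W + B/n)/W), threshold 1.1; equal constant chains define
R̂ = 1 and distinct constant chains R̂ = ∞. The pipeline refuses to publish
summaries for a cell that fails R̂ (the diagnostics are reported instead)
and exits non-zero from the CLI. Posterior summaries are medians and
equal-tailed 95% credible intervals via linear interpolation between order
statistics; fewer than 100 kept draws triggers a precision warning.

## Screening

A job title present in ≥ 2 HEGs is screened by the Kruskal–Wallis test
(mid-ranks, standard tie correction, chi-square reference with k−1 degrees
of freedom); p < 0.05 excludes it. All values tied defines H = 0, p = 1. A
title observed in a single HEG cannot display heterogeneity and is retained
with sentinel p = 1.0. Summary statistics use the sample (n−1) denominator
for both SD and log-SD (GSD); with n = 1 both spreads are defined as zero.
The published summary table does not state its denominator convention; at
its 2-decimal precision the choice is not detectable, and the n−1
convention matches common occupational-hygiene practice.

## Synthetic data

The generator serves two purposes:

* **Exact moment matching** regenerates a dataset whose sample (n, GM, GSD)
  equal published values to machine precision, by standardising standard-
  normal deviates in log space and affinely rescaling (degenerate zero-SD
  draws are regenerated with an incremented seed). Because the likelihood
  is sufficient in these statistics, every downstream posterior depends
  only on the published numbers — the core reproducibility device. AM and
  SD are deliberately not matched; the analysis never consumes them.
* **Random mode** draws plain lognormal samples for power, coverage and
  calibration studies where sampling variability must be real.

Synthetic expert panels perturb the true lognormal quartiles
multiplicatively and invert the standardisation map so that standardising
the stated (B, L, U, C) at S = 70 reproduces the quartiles exactly; with
zero noise the pooled prior recovers the generating parameters to optimizer
tolerance. An overconfidence factor shrinks stated quartile spreads in log
space. Multi-HEG datasets share a GSD and shift per-HEG medians by given
multipliers, exercising both the null (retention rate ≈ 1 − α) and the
power of the screen.

What the generator does not emulate: censored/below-LOD values, seasonal or
campaign effects, within-worker correlation, and real expert behaviour
(anchoring, heaping on round numbers). Passing tests therefore demonstrate
correctness of the statistical machinery on data satisfying the model's
assumptions, not robustness to violations of them.

## Analysis problem sizes

The drivers and the acceptance script run the full 4 × 25,000 / 5,000
configuration per cell. Property and calibration tests use smaller,
explicitly stated configurations (e.g. 2 × 1,500 iterations per replicate
for the 200-replicate coverage study; 12,000-iteration runs against the
quadrature oracle), which the draws' effective sample sizes show to be
ample for the tolerances tested.

## Known limitations and open points

* The truncation boxes actually used for the published posterior tables
  were never printed; published posterior GSD medians imply binding bounds
  that cannot be reconstructed. Under the wide default box this package
  reproduces the published GM medians and the saturated (100%) category
  cells, while GSD/P95 medians and intermediate category percentages
  legitimately differ. These are checked instead by properties: agreement
  with deterministic 2-D quadrature at small n, CrI coverage calibration,
  sufficiency invariance, and truncation monotonicity (a larger box can
  only increase the exceedance probability).
* The published sensitivity table reports 100% exceedance for the pump
  attendant with no bounds at all; the unbounded-uniform posterior for that
  dataset analytically places only ~80–90% of P95 mass above the OEL, so
  that cell is not reproducible as printed and is covered by the
  monotonicity property instead.
* Equal-weight pooling is the only aggregation offered; performance-based
  weights would need calibration data that do not exist for this panel.
* Each job title is fitted independently; no hierarchical sharing across
  titles or HEGs.
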