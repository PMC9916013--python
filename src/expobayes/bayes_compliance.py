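"""Bayesian engine for lognormal exposure compliance testing.

Model
-----
Shift-long exposures y within one job title are lognormal: ln y ~ N(μ, σ²),
so GM = exp(μ), GSD = exp(σ) and the 95th percentile of the exposure
distribution is P95 = exp(μ + z₀.₉₅ σ).  Compliance is decided from the
posterior distribution of P95 relative to the occupational exposure limit
(OEL): the posterior probability of P95 in each of four control categories
(<0.1·OEL, [0.1, 0.5)·OEL, [0.5, 1)·OEL, ≥OEL) is reported.

Priors
------
* informative: μ ~ N(ȳ₀, s²ᵧ₀/n₀) and σ² ~ InvGamma((n₀−1)/2, rate
  (n₀−1)·s²ᵧ₀/2), with (ȳ₀, s²ᵧ₀, n₀) from elicitation or historical data;
* non-informative: uniform on (μ, σ) = (ln GM, ln GSD) over a bounded box.

Both are restricted to a bounded parameter space (a box on GM and GSD):
physically a dust concentration cannot be zero or unbounded, so the box
keeps the sampler away from impossible parameter values.

Sampling
--------
A two-block Gibbs sampler alternates exact draws from the full conditionals,
each truncated to the box by inverse-CDF (never by unbounded rejection), so
every retained draw satisfies the bounds by construction.  Convergence is
checked with the Gelman–Rubin potential scale reduction factor across
chains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import special

__all__ = [
    "Z95",
    "LikelihoodData",
    "PriorSpec",
    "ParameterSpace",
    "MCMCSettings",
    "PosteriorDraws",
    "PosteriorSummary",
    "CategoryScheme",
    "CategoryReport",
    "ConvergenceReport",
    "log_sufficient_stats",
    "ig_shape_scale",
    "gibbs_sample",
    "derive_quantities",
    "category_probabilities",
    "gelman_rubin",
    "summarize_posterior",
]

#: 95th standard-normal quantile, fixed at 4 decimal places.
Z95 = 1.6449


@dataclass(frozen=True)
class LikelihoodData:
    """Sufficient statistics of log-exposures: (n, ȳ, s_y, Σ(ln yᵢ − ȳ)²).

    The lognormal likelihood depends on the data only through these, so two
    datasets sharing them yield identical posteriors.
    """

    n: int
    mean_log: float
    sd_log: float
    sum_sq: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 observations")
        if self.sd_log < 0:
            raise ValueError("sd_log must be >= 0")
        expected = (self.n - 1) * self.sd_log**2
        if not math.isclose(self.sum_sq, expected, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("sum_sq inconsistent with (n-1)*sd_log**2")


def log_sufficient_stats(values: Sequence[float]) -> LikelihoodData:
    """Reduce positive concentrations to the log-scale sufficient statistics."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.any(x <= 0):
        raise ValueError("all values must be strictly positive")
    logs = np.log(x)
    mean_log = float(np.mean(logs))
    sum_sq = float(np.sum((logs - mean_log) ** 2))
    sd_log = math.sqrt(sum_sq / (x.size - 1))
    return LikelihoodData(n=int(x.size), mean_log=mean_log, sd_log=sd_log, sum_sq=sum_sq)


@dataclass(frozen=True)
class PriorSpec:
    """Prior choice: non-informative (uniform over the box) or informative.

    The informative prior is the conjugate normal–inverse-gamma pair
    parameterised by (prior_mean ȳ₀, prior_variance s²ᵧ₀, prior_n n₀).
    """

    kind: Literal["noninformative", "informative"]
    prior_mean: float | None = None
    prior_variance: float | None = None
    prior_n: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "informative":
            if self.prior_mean is None or self.prior_variance is None or self.prior_n is None:
                raise ValueError("informative prior needs prior_mean, prior_variance, prior_n")
            if self.prior_n <= 1:
                raise ValueError("informative prior requires prior_n > 1")
            if self.prior_variance <= 0:
                raise ValueError("informative prior requires prior_variance > 0")
        elif self.kind != "noninformative":
            raise ValueError(f"unknown prior kind: {self.kind}")


class IGParams(NamedTuple):
    """Inverse-gamma hyper-parameters in both printed conventions."""

    shape: float
    rate: float       # shape/rate convention: density ∝ x^(−a−1) exp(−rate/x)
    inv_rate: float   # the reciprocal of ``rate`` (scale-style bookkeeping)


def ig_shape_scale(prior_n: float, prior_variance: float) -> IGParams:
    """Inverse-gamma hyper-parameters for the σ² prior.

    shape = (n₀−1)/2 and rate = (n₀−1)·s²ᵧ₀/2; the reciprocal of the rate is
    also returned for traceability since both conventions circulate.  The
    sampler consumes the shape/rate form.
    """
    if prior_n <= 1:
        raise ValueError("prior_n must be > 1")
    if prior_variance <= 0:
        raise ValueError("prior_variance must be > 0")
    shape = (prior_n - 1.0) / 2.0
    rate = (prior_n - 1.0) * prior_variance / 2.0
    return IGParams(shape=shape, rate=rate, inv_rate=1.0 / rate)


@dataclass(frozen=True)
class ParameterSpace:
    """Bounded support for (GM, GSD): the truncation box of the posterior.

    A GSD below 1 is dimensionally impossible (it is exp of a standard
    deviation); a stated lower bound such as 1e-5 is accepted but clamped to
    1 with a warning, i.e. ln GSD is bounded below by ~0.
    """

    gm_lower: float
    gm_upper: float
    gsd_lower: float
    gsd_upper: float

    def __post_init__(self) -> None:
        if not (0 < self.gm_lower < self.gm_upper):
            raise ValueError("need 0 < gm_lower < gm_upper")
        if self.gsd_lower < 1.0:
            warnings.warn(
                f"gsd_lower={self.gsd_lower} < 1 is impossible for a GSD; clamping to 1",
                stacklevel=2,
            )
            object.__setattr__(self, "gsd_lower", 1.0)
        if not (self.gsd_lower < self.gsd_upper):
            raise ValueError("need effective gsd_lower < gsd_upper")

    @property
    def mu_bounds(self) -> tuple[float, float]:
        return (math.log(self.gm_lower), math.log(self.gm_upper))

    @property
    def sigma_bounds(self) -> tuple[float, float]:
        # ln GSD = 0 exactly (all-equal exposures) has zero posterior mass;
        # keep sigma strictly positive for numerical stability.
        lo = max(math.log(self.gsd_lower), 1e-10)
        return (lo, math.log(self.gsd_upper))

    @classmethod
    def default_box(cls, sample_gm: float) -> "ParameterSpace":
        """Wide data-scaled box: GM ∈ [1e-5, 100·sample GM], GSD ∈ [1.01, 10]."""
        return cls(gm_lower=1e-5, gm_upper=100.0 * sample_gm, gsd_lower=1.01, gsd_upper=10.0)

    @classmethod
    def unrestricted(cls) -> "ParameterSpace":
        """Effectively unbounded box (no binding truncation at any data scale)."""
        return cls(gm_lower=1e-12, gm_upper=1e12, gsd_lower=1.0 + 1e-9, gsd_upper=1e6)

    @classmethod
    def just_above(cls, sample_gm: float, sample_gsd: float, margin: float = 0.01) -> "ParameterSpace":
        """Upper bounds placed just above the sample GM and GSD (+0.01 each)."""
        return cls(
            gm_lower=1e-5,
            gm_upper=round(sample_gm + margin, 10),
            gsd_lower=1.0 + 1e-9,
            gsd_upper=round(sample_gsd + margin, 10),
        )


@dataclass(frozen=True)
class MCMCSettings:
    """Gibbs sampler run configuration."""

    chains: int = 4
    iterations: int = 25_000
    burn_in: int = 5_000
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")


class TruncationError(RuntimeError):
    """The parameter box excludes essentially all posterior mass."""


@dataclass
class PosteriorDraws:
    """Post-burn-in Gibbs draws of (μ, σ), per chain, with derived quantities."""

    mu: np.ndarray      # shape (chains, kept)
    sigma: np.ndarray   # shape (chains, kept)
    space: ParameterSpace
    settings: MCMCSettings

    @property
    def gm(self) -> np.ndarray:
        return np.exp(self.mu)

    @property
    def gsd(self) -> np.ndarray:
        return np.exp(self.sigma)

    @property
    def p95(self) -> np.ndarray:
        return np.exp(self.mu + Z95 * self.sigma)

    def flat(self, name: str) -> np.ndarray:
        return getattr(self, name).reshape(-1)


class CredibleInterval(NamedTuple):
    median: float
    lo: float
    hi: float


@dataclass(frozen=True)
class PosteriorSummary:
    """Median and equal-tailed 95% credible interval for GM, GSD and P95."""

    gm: CredibleInterval
    gsd: CredibleInterval
    p95: CredibleInterval


@dataclass(frozen=True)
class CategoryScheme:
    """OEL-relative exposure control categories.

    1: P95 < 0.1·OEL (very highly controlled); 2: [0.1, 0.5)·OEL (highly
    controlled); 3: [0.5, 1)·OEL (adequately controlled); 4: ≥ OEL (poorly
    controlled).  Each boundary belongs to the upper category.
    """

    oel: float = 2.0

    def __post_init__(self) -> None:
        if self.oel <= 0:
            raise ValueError("oel must be > 0")

    @property
    def thresholds(self) -> tuple[float, float, float]:
        return (0.1 * self.oel, 0.5 * self.oel, self.oel)


@dataclass(frozen=True)
class CategoryReport:
    """Posterior probability of the P95 in each control category (sums to 1)."""

    probabilities: tuple[float, float, float, float]
    scheme: CategoryScheme

    def as_percent(self, decimals: int = 2) -> tuple[float, float, float, float]:
        return tuple(round(100.0 * p, decimals) for p in self.probabilities)


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter Gelman–Rubin R-hat and the overall pass flag."""

    rhat_mu: float
    rhat_sigma: float
    threshold: float

    @property
    def passed(self) -> bool:
        return self.rhat_mu < self.threshold and self.rhat_sigma < self.threshold


# ----------------------------------------------------------------------
# truncated-draw primitives (inverse CDF on the truncated support)

_MIN_MASS = 1e-300


def _trunc_normal(rng: np.random.Generator, mean, sd, lo: float, hi: float) -> np.ndarray:
    """Vectorised truncated-normal draw via inverse CDF."""
    a = special.ndtr((lo - mean) / sd)
    b = special.ndtr((hi - mean) / sd)
    mass = b - a
    if np.any(mass <= _MIN_MASS):
        raise TruncationError(
            f"mu bounds [{lo:.6g}, {hi:.6g}] exclude essentially all posterior mass"
        )
    u = a + rng.random(np.shape(mean)) * mass
    return mean + sd * special.ndtri(u)


def _trunc_gamma(rng: np.random.Generator, shape: float, rate, lo, hi) -> np.ndarray:
    """Vectorised truncated-Gamma(shape, rate) draw on [lo, hi] via inverse CDF."""
    a = special.gammainc(shape, rate * lo)
    b = special.gammainc(shape, rate * hi)
    mass = b - a
    if np.any(mass <= _MIN_MASS):
        raise TruncationError("sigma bounds exclude essentially all posterior mass")
    u = a + rng.random(np.shape(rate)) * mass
    return special.gammaincinv(shape, u) / rate


def _draw_sigma_noninformative(
    rng: np.random.Generator, n: int, ss: np.ndarray, sig_lo: float, sig_hi: float
) -> np.ndarray:
    """Draw σ from p(σ) ∝ σ^(−n)·exp(−SS/(2σ²)) on [sig_lo, sig_hi].

    Change of variables t = σ⁻² turns this into Gamma((n−1)/2, rate = SS/2)
    truncated to [sig_hi⁻², sig_lo⁻²]; the draw is the exact inverse CDF of
    the truncated conditional, mapped back as σ = t^(−1/2).
    """
    t = _trunc_gamma(rng, (n - 1) / 2.0, ss / 2.0, sig_hi**-2, sig_lo**-2)
    return 1.0 / np.sqrt(t)


def _draw_sigma_informative(
    rng: np.random.Generator,
    shape: float,
    rate: np.ndarray,
    sig_lo: float,
    sig_hi: float,
) -> np.ndarray:
    """Draw σ² ~ InvGamma(shape, rate) truncated so σ ∈ [sig_lo, sig_hi].

    Uses 1/σ² ~ Gamma(shape, rate): an inverse-gamma truncated to
    σ² ∈ [sig_lo², sig_hi²] is the reciprocal of a gamma truncated to
    [sig_hi⁻², sig_lo⁻²].
    """
    t = _trunc_gamma(rng, shape, rate, sig_hi**-2, sig_lo**-2)
    return 1.0 / np.sqrt(t)


def gibbs_sample(
    data: LikelihoodData,
    prior: PriorSpec,
    space: ParameterSpace,
    settings: MCMCSettings,
) -> PosteriorDraws:
    """Two-block Gibbs sampler for (μ, σ) on the truncated parameter box.

    Full conditionals (each truncated to the box by inverse CDF):

    * μ | σ², data — informative: normal with precision n₀/s²ᵧ₀ + n/σ²
      combining the prior mean ȳ₀ with the data mean ȳ; non-informative:
      N(ȳ, σ²/n).
    * σ² | μ, data — informative: InvGamma((n₀−1)/2 + n/2,
      rate [(n₀−1)s²ᵧ₀ + Σ(ln yᵢ − μ)²]/2); non-informative (uniform on σ
      over the box): density ∝ σ^(−n)·exp(−Σ(ln yᵢ−μ)²/(2σ²)), drawn
      exactly through the Gamma change of variables t = σ⁻².

    All chains advance in lock-step as vectorised draws; chains differ only
    through their RNG substreams, spawned from ``settings.seed``.
    """
    mu_lo, mu_hi = space.mu_bounds
    sig_lo, sig_hi = space.sigma_bounds
    n = data.n
    ybar = data.mean_log
    sum_sq = data.sum_sq

    if prior.kind == "informative":
        prior_prec = prior.prior_n / prior.prior_variance
        ig = ig_shape_scale(prior.prior_n, prior.prior_variance)
        sig_shape = ig.shape + n / 2.0
    else:
        prior_prec = 0.0

    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    chains = settings.chains

    # start each chain from the (clipped) sample statistics, jittered so the
    # between-chain variance in the diagnostic is not artificially zero
    mu = np.clip(
        ybar + 0.1 * max(data.sd_log, 0.1) * rng.standard_normal(chains), mu_lo, mu_hi
    )
    sigma = np.clip(
        max(data.sd_log, 0.05) * np.exp(0.1 * rng.standard_normal(chains)), sig_lo, sig_hi
    )

    kept = settings.iterations - settings.burn_in
    out_mu = np.empty((chains, kept))
    out_sigma = np.empty((chains, kept))

    for it in range(settings.iterations):
        var = sigma**2
        if prior.kind == "informative":
            prec = prior_prec + n / var
            mean = (prior_prec * prior.prior_mean + (n / var) * ybar) / prec
            mu = _trunc_normal(rng, mean, np.sqrt(1.0 / prec), mu_lo, mu_hi)
            ss_mu = sum_sq + n * (ybar - mu) ** 2
            sigma = _draw_sigma_informative(
                rng, sig_shape, ig.rate + ss_mu / 2.0, sig_lo, sig_hi
            )
        else:
            mu = _trunc_normal(rng, ybar, sigma / math.sqrt(n), mu_lo, mu_hi)
            ss_mu = sum_sq + n * (ybar - mu) ** 2
            sigma = _draw_sigma_noninformative(rng, n, ss_mu, sig_lo, sig_hi)
        if it >= settings.burn_in:
            j = it - settings.burn_in
            out_mu[:, j] = mu
            out_sigma[:, j] = sigma

    return PosteriorDraws(mu=out_mu, sigma=out_sigma, space=space, settings=settings)


def derive_quantities(mu: float, sigma: float) -> tuple[float, float, float]:
    """Map one (μ, σ) draw to (GM, GSD, P95) = (e^μ, e^σ, e^(μ+z₀.₉₅σ))."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return (math.exp(mu), math.exp(sigma), math.exp(mu + Z95 * sigma))


def category_probabilities(
    p95_draws: np.ndarray, scheme: CategoryScheme = CategoryScheme()
) -> CategoryReport:
    """Fraction of posterior P95 draws in each OEL-relative control category.

    Boundaries belong to the upper category (a P95 exactly at 0.1·OEL counts
    as category 2, at the OEL as category 4).
    """
    x = np.asarray(p95_draws, dtype=float).reshape(-1)
    if x.size == 0:
        raise ValueError("need at least one draw")
    t1, t2, t3 = scheme.thresholds
    p1 = np.mean(x < t1)
    p2 = np.mean((x >= t1) & (x < t2))
    p3 = np.mean((x >= t2) & (x < t3))
    p4 = np.mean(x >= t3)
    return CategoryReport(probabilities=(float(p1), float(p2), float(p3), float(p4)), scheme=scheme)


def gelman_rubin(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (m, n): m ≥ 2 chains of equal length n ≥ 2.  R-hat =
    sqrt(((n−1)/n·W + B/n) / W) with W the mean within-chain variance and B
    the between-chain variance of the chain means (times n).  Degenerate
    cases: all chains constant and equal → 1.0; constant chains at different
    values → +inf.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 chains (2-D array, chains as rows)")
    m, n = c.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    within = float(np.mean(np.var(c, axis=1, ddof=1)))
    between = float(n * np.var(np.mean(c, axis=1), ddof=1))
    if within == 0.0:
        return 1.0 if between == 0.0 else float("inf")
    var_hat = (n - 1) / n * within + between / n
    return float(math.sqrt(var_hat / within))


def convergence_report(draws: PosteriorDraws) -> ConvergenceReport:
    """R-hat for μ and σ over the post-burn-in draws."""
    return ConvergenceReport(
        rhat_mu=gelman_rubin(draws.mu),
        rhat_sigma=gelman_rubin(draws.sigma),
        threshold=draws.settings.rhat_threshold,
    )


def _interval(x: np.ndarray) -> CredibleInterval:
    med, lo, hi = np.percentile(x, [50.0, 2.5, 97.5])
    return CredibleInterval(median=float(med), lo=float(lo), hi=float(hi))


def summarize_posterior(draws: PosteriorDraws) -> PosteriorSummary:
    """Medians and equal-tailed 95% CrIs of GM, GSD and P95.

    Percentiles use linear interpolation between order statistics.  Fewer
    than 100 post-burn-in draws triggers a precision warning.
    """
    if draws.mu.size < 100:
        warnings.warn("fewer than 100 post-burn-in draws: summaries are imprecise", stacklevel=2)
    return PosteriorSummary(
        gm=_interval(draws.flat("gm")),
        gsd=_interval(draws.flat("gsd")),
        p95=_interval(draws.flat("p95")),
    )
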