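"""Expert elicitation → pooled informative prior for the lognormal exposure model.

Each expert supplies, for a job title, a best guess B, a minimum L, a maximum
U (all percentages) and a confidence level C.  The stated (L, U) range is
standardised to a common credible level S by linear extrapolation,

    standardised minimum = B − (B − L)·(S/C)
    standardised maximum = B + (U − B)·(S/C),

truncated into [0, 100].  The triple (standardised min, B, standardised max)
is read as lognormal quartiles (Q1, median, Q3) and a lognormal is fitted to
them by least squares on the CDF.  Experts are pooled with equal weights: the
prior mean is the arithmetic mean of the fitted meanlogs, the prior variance
the arithmetic mean of the fitted sdlog², paired with an effective prior
sample size n₀.

A historical-data prior bypasses elicitation: it takes prior mean = ln GM and
prior variance = (ln GSD)² from an earlier monitoring campaign's summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .exposure_data import JobTitleSummary

__all__ = [
    "ExpertJudgement",
    "StandardizedJudgement",
    "LognormalFit",
    "AggregatedPrior",
    "standardize_interval",
    "judgement_to_quartiles",
    "fit_lognormal_quartiles",
    "aggregate_experts",
    "subset_experts",
    "historical_prior",
]

#: z-score of the 75th standard-normal percentile; maps quartiles to sdlog.
Z_Q3 = 0.6744897501960817

#: Default credible level (in %) to which expert intervals are standardised.
DEFAULT_S = 70.0


@dataclass(frozen=True)
class ExpertJudgement:
    """One expert's elicited judgement: best guess, range, and confidence (all %)."""

    expert_id: str
    job_title: str
    best_guess: float
    minimum: float
    maximum: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.minimum <= self.best_guess <= self.maximum <= 100.0):
            raise ValueError(
                f"need 0 <= L <= B <= U <= 100, got L={self.minimum}, "
                f"B={self.best_guess}, U={self.maximum}"
            )
        if not (self.confidence > 0):
            raise ValueError("confidence must be > 0")


@dataclass(frozen=True)
class StandardizedJudgement:
    """Quartile triple (Q1, median, Q3) after interval standardisation."""

    expert_id: str
    q1: float
    median: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("need q1 <= median <= q3")


@dataclass(frozen=True)
class LognormalFit:
    """Least-squares lognormal fit to a quartile triple."""

    meanlog: float
    sdlog: float
    sse: float

    def __post_init__(self) -> None:
        if not (self.sdlog > 0):
            raise ValueError("sdlog must be > 0")
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


@dataclass(frozen=True)
class AggregatedPrior:
    """Pooled prior (ȳ₀, s²ᵧ₀, n₀) for the normal–inverse-gamma prior pair."""

    prior_mean: float
    prior_variance: float
    prior_n: float
    provenance: str = "expert"

    def __post_init__(self) -> None:
        if not (self.prior_variance > 0):
            raise ValueError("prior_variance must be > 0")
        if not (self.prior_n > 1):
            raise ValueError("prior_n must be > 1")


def standardize_interval(
    best_guess: float,
    minimum: float,
    maximum: float,
    s: float = DEFAULT_S,
    confidence: float = 100.0,
) -> tuple[float, float]:
    """Standardise an expert's (min, max) range to credible level ``s``.

    Linear extrapolation about the best guess by the factor s/C, then
    truncation into the closed probability interval [0, 100].
    """
    if confidence <= 0:
        raise ValueError("confidence must be > 0")
    if s <= 0:
        raise ValueError("standardization level s must be > 0")
    if not (minimum <= best_guess <= maximum):
        raise ValueError("need minimum <= best_guess <= maximum")
    factor = s / confidence
    lo = best_guess - (best_guess - minimum) * factor
    hi = best_guess + (maximum - best_guess) * factor
    return (min(max(lo, 0.0), 100.0), min(max(hi, 0.0), 100.0))


def judgement_to_quartiles(j: ExpertJudgement, s: float = DEFAULT_S) -> StandardizedJudgement:
    """Standardise a judgement and read (Q1, median, Q3) from it.

    The best guess plays the median; the standardised minimum and maximum
    play the lower and upper quartiles.
    """
    lo, hi = standardize_interval(j.best_guess, j.minimum, j.maximum, s=s, confidence=j.confidence)
    return StandardizedJudgement(expert_id=j.expert_id, q1=lo, median=j.best_guess, q3=hi)


def _quartile_sse(meanlog: float, sdlog: float, q: np.ndarray) -> float:
    probs = np.array([0.25, 0.5, 0.75])
    cdf = special.ndtr((np.log(q) - meanlog) / sdlog)
    return float(np.sum((cdf - probs) ** 2))


def fit_lognormal_quartiles(q1: float, median: float, q3: float) -> LognormalFit:
    """Fit a lognormal to (Q1, median, Q3) by least squares on the CDF.

    Minimises Σₖ (F(qₖ; meanlog, sdlog) − pₖ)² with pₖ = 0.25, 0.5, 0.75.
    A deterministic multi-start (closed-form seed plus a coarse grid around
    it, each refined by Nelder–Mead) keeps the fit reproducible; ties are
    broken toward the smallest sdlog.  A log-consistent triple (q3/median =
    median/q1) is recovered exactly with sse ≈ 0.
    """
    if not (0 < q1 <= median <= q3):
        raise ValueError("need 0 < q1 <= median <= q3")
    if q1 == q3:
        raise ValueError("degenerate spread: q1 == q3 admits no lognormal fit")

    q = np.array([q1, median, q3], dtype=float)
    # Closed-form start from the quartile spread; exact when consistent.
    mu0 = math.log(median)
    sig0 = math.log(q3 / q1) / (2.0 * Z_Q3)
    if sig0 > 0:
        sse0 = _quartile_sse(mu0, sig0, q)
        if sse0 < 1e-16:  # log-consistent triple: closed form is the optimum
            return LognormalFit(meanlog=mu0, sdlog=sig0, sse=sse0)

    starts = [(mu0, sig0)]
    for dm in (-0.5, 0.0, 0.5):
        for fs in (0.5, 1.0, 2.0):
            starts.append((mu0 + dm, max(sig0 * fs, 1e-3)))

    best: tuple[float, float, float] | None = None
    for m0, s0 in starts:
        res = optimize.minimize(
            lambda th: _quartile_sse(th[0], abs(th[1]) + 1e-12, q),
            x0=[m0, s0],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
        )
        m, s_ = res.x[0], abs(res.x[1]) + 1e-12
        sse = _quartile_sse(m, s_, q)
        key = (sse, s_)
        if best is None or key < (best[2], best[1]):
            best = (m, s_, sse)
    assert best is not None
    return LognormalFit(meanlog=float(best[0]), sdlog=float(best[1]), sse=float(best[2]))


def aggregate_experts(fits: Sequence[LognormalFit], n0: float = 5.0) -> AggregatedPrior:
    """Pool per-expert lognormal fits with equal weights.

    prior_mean = mean of meanlogs; prior_variance = mean of sdlog²;
    prior_n = the supplied effective prior sample size n₀.
    """
    if len(fits) == 0:
        raise ValueError("cannot aggregate an empty collection of fits")
    mean = float(np.mean([f.meanlog for f in fits]))
    var = float(np.mean([f.sdlog**2 for f in fits]))
    return AggregatedPrior(prior_mean=mean, prior_variance=var, prior_n=float(n0), provenance="expert")


def subset_experts(
    judgements: Sequence[ExpertJudgement], k: int, seed: int
) -> list[ExpertJudgement]:
    """Uniformly random subset of ``k`` experts, reproducible from ``seed``."""
    if not (1 <= k <= len(judgements)):
        raise ValueError(f"subset size {k} out of range for panel of {len(judgements)}")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(judgements), size=k, replace=False))
    return [judgements[i] for i in idx]


def historical_prior(summary: JobTitleSummary, n0: float | None = None) -> AggregatedPrior:
    """Informative prior from a historical monitoring campaign's summary.

    prior_mean = ln GM, prior_variance = (ln GSD)²; n₀ defaults to the
    historical sample size but can be overridden (e.g. to cap the prior's
    weight relative to the current data).
    """
    if summary.n < 2:
        raise ValueError("historical prior needs n >= 2")
    if summary.gsd <= 1.0:
        raise ValueError("historical GSD of 1 gives a zero-variance prior")
    n_eff = float(summary.n if n0 is None else n0)
    return AggregatedPrior(
        prior_mean=math.log(summary.gm),
        prior_variance=math.log(summary.gsd) ** 2,
        prior_n=n_eff,
        provenance="historical",
    )


EXPERT_COLUMNS = (
    "expert_id",
    "job_title",
    "best_guess_pct",
    "min_pct",
    "max_pct",
    "confidence_pct",
)


def read_experts(path) -> list[ExpertJudgement]:
    """Read an expert-judgement CSV (one row per expert per job title)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in EXPERT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expert CSV missing column(s): {', '.join(missing)}")
    return [
        ExpertJudgement(
            expert_id=str(r.expert_id),
            job_title=str(r.job_title),
            best_guess=float(r.best_guess_pct),
            minimum=float(r.min_pct),
            maximum=float(r.max_pct),
            confidence=float(r.confidence_pct),
        )
        for r in df.itertuples(index=False)
    ]


def export_prior(prior: AggregatedPrior, path, seed: int | None = None) -> None:
    """Write a pooled prior as a small key: value text file."""
    lines = [
        f"prior_mean: {prior.prior_mean!r}",
        f"prior_variance: {prior.prior_variance!r}",
        f"prior_n: {prior.prior_n!r}",
        f"provenance: {prior.provenance}",
    ]
    if seed is not None:
        lines.append(f"seed: {seed}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def panel_prior(
    judgements: Sequence[ExpertJudgement],
    n0: float = 5.0,
    s: float = DEFAULT_S,
) -> AggregatedPrior:
    """Full elicitation path: standardise, fit each expert, pool equally."""
    fits = [
        fit_lognormal_quartiles(sj.q1, sj.median, sj.q3)
        for sj in (judgement_to_quartiles(j, s=s) for j in judgements)
    ]
    return aggregate_experts(fits, n0=n0)
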