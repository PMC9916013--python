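"""Synthetic exposure datasets and expert panels with known ground truth.

The raw monitoring measurements behind the published cohort summaries are
not deposited, but the lognormal likelihood depends on the data only through
(n, mean of logs, SD of logs).  Exact moment matching therefore regenerates
datasets whose sample GM, GSD and n equal the published values to machine
precision, making every downstream posterior a function of published numbers
only.  Random-mode generation and synthetic expert panels support power,
coverage and recovery studies where the truth must be known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .elicitation_prior import DEFAULT_S, Z_Q3, ExpertJudgement
from .exposure_data import ExposureRecord

__all__ = [
    "GeneratorSpec",
    "generate_matched_lognormal",
    "generate_expert_panel",
    "generate_heg_dataset",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic job-title dataset.

    ``exact`` match mode reproduces (n, target_gm, target_gsd) as the sample
    statistics to machine precision; ``random`` draws a plain lognormal
    sample whose statistics only converge to the targets as n grows.
    """

    job_title: str
    n: int
    target_gm: float
    target_gsd: float
    seed: int
    match_mode: Literal["exact", "random"] = "exact"
    heg_id: str = "HEG-1"
    year: int = 2018

    def __post_init__(self) -> None:
        if self.target_gm <= 0:
            raise ValueError("target_gm must be > 0")
        if self.target_gsd < 1:
            raise ValueError("target_gsd must be >= 1")
        if self.match_mode == "exact":
            if self.n < 2:
                raise ValueError("exact matching needs n >= 2")
            if self.target_gsd <= 1:
                raise ValueError("exact matching needs target_gsd > 1")
        elif self.match_mode != "random":
            raise ValueError(f"unknown match_mode: {self.match_mode}")


def _matched_logs(n: int, meanlog: float, sdlog: float, seed: int) -> np.ndarray:
    """n log-values with sample mean ``meanlog`` and sample SD (n−1) ``sdlog``.

    Standard-normal draws are standardised (subtract sample mean, divide by
    sample SD) and affinely rescaled; a degenerate draw with zero sample SD
    is regenerated with an incremented seed.
    """
    while True:
        z = np.random.default_rng(seed).standard_normal(n)
        s = z.std(ddof=1)
        if s > 0:
            break
        seed += 1
    z = (z - z.mean()) / s
    return meanlog + sdlog * z


def generate_matched_lognormal(spec: GeneratorSpec) -> list[ExposureRecord]:
    """Generate one job title's synthetic exposure records.

    Exact mode pins the sample GM and GSD to the targets; random mode draws
    i.i.d. lognormal values with those population parameters.
    """
    meanlog = math.log(spec.target_gm)
    sdlog = math.log(spec.target_gsd)
    if spec.match_mode == "exact":
        logs = _matched_logs(spec.n, meanlog, sdlog, spec.seed)
    else:
        rng = np.random.default_rng(spec.seed)
        logs = meanlog + sdlog * rng.standard_normal(spec.n)
    return [
        ExposureRecord(
            job_title=spec.job_title,
            heg_id=spec.heg_id,
            year=spec.year,
            twa8h=float(v),
        )
        for v in np.exp(logs)
    ]


def generate_expert_panel(
    true_meanlog: float,
    true_sdlog: float,
    k: int = 6,
    noise_scale: float = 0.0,
    overconfidence_factor: float = 1.0,
    seed: int = 0,
    job_title: str = "synthetic",
    confidence: float = 100.0,
) -> list[ExpertJudgement]:
    """Synthetic panel of ``k`` experts around a known lognormal.

    Each expert's (Q1, median, Q3) are the true lognormal quartiles
    perturbed multiplicatively by ``noise_scale`` (lognormal noise on each
    quantile); ``overconfidence_factor`` > 1 shrinks the stated quartile
    spread in log space, mimicking overconfident experts.  The quartiles are
    then mapped back through the inverse of the interval-standardisation
    formula, so that standardising the returned (B, L, U, C) at the default
    level S reproduces the quartiles exactly.  With zero noise the panel is
    perfectly consistent with the generating parameters.
    """
    if k < 1:
        raise ValueError("need k >= 1 experts")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    judgements = []
    for i in range(k):
        m = true_meanlog + noise_scale * rng.standard_normal()
        half = Z_Q3 * true_sdlog / overconfidence_factor
        half *= math.exp(noise_scale * rng.standard_normal()) if noise_scale > 0 else 1.0
        q1, med, q3 = math.exp(m - half), math.exp(m), math.exp(m + half)
        # invert: std_min = B − (B−L)·S/C = q1  ⇒  L = B − (B−q1)·C/S
        b = med
        lo = b - (b - q1) * confidence / DEFAULT_S
        hi = b + (q3 - b) * confidence / DEFAULT_S
        if lo < 0.0 or hi > 100.0:
            raise ValueError(
                "panel quantiles map outside the [0, 100] judgement range; "
                "use a smaller true scale, noise, or confidence"
            )
        judgements.append(
            ExpertJudgement(
                expert_id=f"E{i + 1}",
                job_title=job_title,
                best_guess=b,
                minimum=lo,
                maximum=hi,
                confidence=confidence,
            )
        )
    return judgements


def generate_heg_dataset(
    base_spec: GeneratorSpec,
    heg_shifts: Mapping[str, float],
) -> list[ExposureRecord]:
    """Synthetic multi-HEG dataset for one job title.

    Each HEG gets an independent lognormal sample of ``base_spec.n`` values
    sharing the target GSD, with its median (GM) multiplied by the given
    shift; all shifts equal to 1 is the homogeneous-profile null that the
    screening test should retain.
    """
    if len(heg_shifts) < 2:
        raise ValueError("need >= 2 HEGs")
    records: list[ExposureRecord] = []
    ss = np.random.SeedSequence(base_spec.seed)
    for child, (heg, shift) in zip(ss.spawn(len(heg_shifts)), sorted(heg_shifts.items())):
        rng = np.random.default_rng(child)
        logs = (
            math.log(base_spec.target_gm * shift)
            + math.log(base_spec.target_gsd) * rng.standard_normal(base_spec.n)
        )
        records.extend(
            ExposureRecord(
                job_title=base_spec.job_title,
                heg_id=heg,
                year=base_spec.year,
                twa8h=float(v),
            )
            for v in np.exp(logs)
        )
    return records
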