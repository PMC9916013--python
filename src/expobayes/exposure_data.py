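"""Exposure measurement records, lognormal summary statistics, and job-title screening.

Personal dust sampling in underground mining is reported as the eight-hour
time-weighted average (TWA8h) concentration in mg/m³.  Exposure data are
conventionally summarised on both the arithmetic scale (AM, SD) and the
geometric scale (GM, GSD), the latter being the natural location/spread
parameters of the lognormal distribution that full-shift exposures follow.

A job title can occur in several homogeneous exposure groups (HEGs).  Before
pooling its measurements, the median exposure is compared across HEGs with a
Kruskal–Wallis rank test; a significant difference means the job title does
not have a single exposure profile and it is excluded from the Bayesian
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExposureRecord",
    "JobTitleSummary",
    "ScreeningResult",
    "read_exposures",
    "summarize_exposures",
    "kruskal_wallis",
    "screen_job_title",
]

EXPOSURE_COLUMNS = ("job_title", "heg_id", "year", "twa8h_mg_m3")


@dataclass(frozen=True)
class ExposureRecord:
    """One personal TWA8h measurement.

    ``twa8h`` is a full-shift respirable dust concentration in mg/m³ and must
    be strictly positive (gravimetric results of zero or below are rejected
    at the I/O layer, never silently log-transformed).
    """

    job_title: str
    heg_id: str
    year: int
    twa8h: float

    def __post_init__(self) -> None:
        if not self.job_title:
            raise ValueError("job_title must be non-empty")
        if not self.heg_id:
            raise ValueError("heg_id must be non-empty")
        if not (self.twa8h > 0):
            raise ValueError(f"twa8h must be > 0, got {self.twa8h}")


@dataclass(frozen=True)
class JobTitleSummary:
    """Per-job-title summary: n, AM, SD (arithmetic) and GM, GSD (geometric).

    SD and the log-scale SD behind GSD use the sample (n−1) denominator.
    For n = 1 both spreads are defined as zero spread (sd = 0, gsd = 1).
    """

    job_title: str
    n: int
    am: float
    sd: float
    gm: float
    gsd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.gsd < 1:
            raise ValueError("gsd must be >= 1")


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the across-HEG homogeneity screen for one job title."""

    job_title: str
    h_statistic: float
    p_value: float
    retained: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


class SchemaError(ValueError):
    """An input table is missing a required column."""


class EmptyInputError(ValueError):
    """An input table contains no rows."""


def read_exposures(path) -> tuple[list[ExposureRecord], int]:
    """Read an exposure CSV into records, rejecting invalid concentrations.

    The file must have columns ``job_title,heg_id,year,twa8h_mg_m3``.  Rows
    whose concentration is non-numeric or not strictly positive are dropped.

    Returns
    -------
    (records, n_rejected)
        The parsed records and the count of rejected rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in EXPOSURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"exposure CSV missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"exposure CSV has no data rows: {path}")

    conc = pd.to_numeric(df["twa8h_mg_m3"], errors="coerce")
    valid = conc.notna() & (conc > 0)
    n_rejected = int((~valid).sum())
    records = [
        ExposureRecord(
            job_title=str(row.job_title),
            heg_id=str(row.heg_id),
            year=int(row.year),
            twa8h=float(c),
        )
        for row, c in zip(df[valid].itertuples(index=False), conc[valid])
    ]
    return records, n_rejected


def summarize_exposures(values: Sequence[float], job_title: str = "") -> JobTitleSummary:
    """Summarise positive concentrations as (n, AM, SD, GM, GSD).

    GM = exp(mean of logs); GSD = exp(sample SD of logs).  Both SDs use the
    n−1 denominator; a single observation has sd = 0 and gsd = 1.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise EmptyInputError("cannot summarise an empty sample")
    if np.any(x <= 0):
        raise ValueError("all concentrations must be strictly positive")
    n = int(x.size)
    am = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n >= 2 else 0.0
    logs = np.log(x)
    gm = float(np.exp(np.mean(logs)))
    gsd = float(np.exp(np.std(logs, ddof=1))) if n >= 2 else 1.0
    return JobTitleSummary(job_title=job_title, n=n, am=am, sd=sd, gm=gm, gsd=gsd)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H and its chi-square p-value across two or more groups.

    Mid-ranks with the standard tie correction; the degenerate case where
    every pooled value is identical is defined as H = 0, p = 1 (no rank
    separation to detect).
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def screen_job_title(
    groups_by_heg: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    job_title: str = "",
) -> ScreeningResult:
    """Screen one job title for a homogeneous exposure profile across HEGs.

    Retained iff the Kruskal–Wallis p-value is >= ``alpha`` (no significant
    median difference).  A job title observed in a single HEG cannot show
    heterogeneity and is retained with a sentinel p-value of 1.0.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if len(groups_by_heg) == 0:
        raise EmptyInputError("no HEG groups supplied")
    if len(groups_by_heg) == 1:
        return ScreeningResult(job_title=job_title, h_statistic=0.0, p_value=1.0, retained=True)
    h, p = kruskal_wallis(list(groups_by_heg.values()))
    return ScreeningResult(job_title=job_title, h_statistic=h, p_value=p, retained=p >= alpha)


def group_records(
    records: Iterable[ExposureRecord],
) -> dict[str, dict[str, list[float]]]:
    """Group record concentrations as {job_title: {heg_id: [values]}}."""
    out: dict[str, dict[str, list[float]]] = {}
    for r in records:
        out.setdefault(r.job_title, {}).setdefault(r.heg_id, []).append(r.twa8h)
    return out
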