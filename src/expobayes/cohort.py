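"""Published cohort summaries for the South African underground coal-mine study.

Ten job titles with both a current monitoring campaign and an earlier
historical campaign.  The raw measurements are not deposited; each row below
carries the published per-job-title summary (n, AM, SD, GM, GSD) plus, for
the current campaign, the across-HEG Kruskal–Wallis p-value.  Because the
lognormal analysis is sufficient in (n, GM, GSD), exact moment matching
(:func:`expobayes.synthetic_data.generate_matched_lognormal`) rebuilds
working datasets that reproduce every downstream posterior from these
printed values alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exposure_data import ExposureRecord, JobTitleSummary
from .synthetic_data import GeneratorSpec, generate_matched_lognormal

__all__ = ["CohortRow", "CURRENT_ROWS", "HISTORICAL_ROWS", "build_cohort_records"]


@dataclass(frozen=True)
class CohortRow:
    """One published summary row (one job title within one campaign)."""

    job_title: str
    year: int
    n: int
    am: float
    sd: float
    gm: float
    gsd: float
    p_value: float | None = None  # across-HEG homogeneity p (current rows)

    def summary(self) -> JobTitleSummary:
        return JobTitleSummary(
            job_title=self.job_title, n=self.n, am=self.am, sd=self.sd, gm=self.gm, gsd=self.gsd
        )


CURRENT_ROWS: tuple[CohortRow, ...] = (
    CohortRow("Beltsman", 2015, 18, 0.76, 0.72, 0.48, 2.94, 0.5694),
    CohortRow("CM Operator", 2018, 116, 2.08, 1.87, 1.28, 3.30, 0.1014),
    CohortRow("Conveyer belt Attendant", 2015, 29, 0.93, 0.75, 0.66, 2.41, 0.0917),
    CohortRow("Emico Driver", 2015, 24, 1.13, 1.02, 0.54, 5.11, 0.3116),
    CohortRow("Electrician", 2015, 52, 1.55, 1.52, 0.87, 3.75, 0.0617),
    CohortRow("Face Boss", 2018, 35, 1.56, 1.76, 0.80, 3.68, 0.8640),
    CohortRow("Pump Attendant", 2016, 18, 0.74, 0.82, 0.41, 3.41, 0.3955),
    CohortRow("Roofbolt Operator", 2018, 101, 1.77, 1.66, 1.11, 3.03, 0.0853),
    CohortRow("Safety Officer", 2018, 16, 2.78, 2.05, 2.06, 2.45, 0.8169),
    CohortRow("Shuttle Car Operator", 2018, 46, 1.60, 1.34, 1.08, 2.62, 0.1615),
)

HISTORICAL_ROWS: tuple[CohortRow, ...] = (
    CohortRow("Beltsman", 2009, 14, 1.07, 0.89, 0.66, 3.31, 0.1653),
    CohortRow("CM Operator", 2009, 11, 2.10, 2.05, 0.70, 8.46, 0.1573),
    CohortRow("Conveyer belt Attendant", 2009, 7, 0.64, 0.56, 0.42, 2.92, 0.3012),
    CohortRow("Emico Driver", 2009, 6, 0.81, 0.73, 0.43, 4.29, 0.5319),
    CohortRow("Electrician", 2009, 14, 1.70, 2.03, 0.75, 5.31, 0.3618),
    CohortRow("Face Boss", 2009, 22, 1.00, 0.97, 0.46, 4.89, 0.8495),
    CohortRow("Pump Attendant", 2009, 8, 0.66, 0.69, 0.42, 2.86, 0.3679),
    CohortRow("Roofbolt Operator", 2009, 8, 1.70, 2.58, 0.81, 3.54, 0.5319),
    CohortRow("Safety Officer", 2009, 8, 0.70, 0.56, 0.38, 4.57, 0.4060),
    CohortRow("Shuttle Car Operator", 2016, 10, 1.3, 1.11, 0.69, 4.59, 0.2352),
)


def build_cohort_records(
    rows: tuple[CohortRow, ...], base_seed: int = 20230131
) -> dict[str, list[ExposureRecord]]:
    """Exact-mode synthetic records for every row, keyed by job title.

    Each job title gets a stable seed offset so record values are
    reproducible while the sample (n, GM, GSD) match the row exactly.
    """
    out: dict[str, list[ExposureRecord]] = {}
    for i, row in enumerate(rows):
        spec = GeneratorSpec(
            job_title=row.job_title,
            n=row.n,
            target_gm=row.gm,
            target_gsd=row.gsd,
            seed=(base_seed + 1000 * i) % 2**31,
            match_mode="exact",
            year=row.year,
        )
        out[row.job_title] = generate_matched_lognormal(spec)
    return out
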