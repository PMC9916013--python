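"""End-to-end orchestration: screen → build priors → sample → report.

One analysis run takes an exposure CSV (current monitoring data), optional
historical exposure and expert-judgement CSVs, and a configuration (OEL,
parameter-space bounds, MCMC settings, prior variants).  Per job title and
per prior variant it emits the posterior medians/CrIs of GM, GSD and P95,
the four control-category probabilities, and the Gelman–Rubin diagnostics.
A sensitivity run repeats selected job titles under alternative
parameter-space boxes and tabulates the category probabilities side by side.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from . import __version__
from .bayes_compliance import (
    CategoryScheme,
    MCMCSettings,
    ParameterSpace,
    PosteriorDraws,
    PriorSpec,
    category_probabilities,
    convergence_report,
    gibbs_sample,
    log_sufficient_stats,
    summarize_posterior,
)
from .elicitation_prior import (
    AggregatedPrior,
    ExpertJudgement,
    historical_prior,
    panel_prior,
    read_experts,
    subset_experts,
)
from .exposure_data import (
    ExposureRecord,
    group_records,
    read_exposures,
    screen_job_title,
    summarize_exposures,
)

log = logging.getLogger("expobayes")

VARIANTS = ("noninformative", "historical", "expert")

RESULT_COLUMNS = [
    "job_title",
    "prior_kind",
    "gm_median",
    "gm_lo",
    "gm_hi",
    "gsd_median",
    "gsd_lo",
    "gsd_hi",
    "p95_median",
    "p95_lo",
    "p95_hi",
    "cat1_pct",
    "cat2_pct",
    "cat3_pct",
    "cat4_pct",
    "rhat_mu",
    "rhat_sigma",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one full analysis run."""

    exposures_csv: str | Path
    experts_csv: str | Path | None = None
    historical_csv: str | Path | None = None
    oel: float = 2.0
    variants: tuple[str, ...] = ("noninformative",)
    alpha: float = 0.05
    expert_n0: float = 5.0
    expert_subset_k: int | None = 5
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    # box per job title; None → wide default scaled to the sample GM
    space: ParameterSpace | None = None
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown prior variant(s): {sorted(unknown)}")
        if not self.variants:
            raise ValueError("at least one prior variant is required")


@dataclass(frozen=True)
class SensitivityPlan:
    """Named parameter-space variants applied to selected job titles."""

    job_titles: tuple[str, ...]
    spaces: tuple[tuple[str, str], ...] = (
        ("bda_style", "default"),
        ("unrestricted", "unrestricted"),
        ("just_above_sample", "just_above"),
    )

    def __post_init__(self) -> None:
        if len(self.spaces) < 2:
            raise ValueError("a sensitivity plan needs >= 2 parameter-space variants")
        names = [n for n, _ in self.spaces]
        if len(set(names)) != len(names):
            raise ValueError("parameter-space variant names must be distinct")


class EmptyCohortError(RuntimeError):
    """Screening excluded every job title."""


def variant_seed(master_seed: int, job_title: str, variant: str, extra: str = "") -> int:
    """Stable per-(job title, variant) RNG substream seed.

    Uses CRC-32 of the labels so adding or removing other job titles or
    variants never perturbs an existing run's draws.
    """
    tag = f"{job_title}|{variant}|{extra}".encode()
    return (zlib.crc32(tag) ^ (master_seed * 2654435761 % 2**31)) % 2**31


def _space_for(kind: str, sample_gm: float, sample_gsd: float) -> ParameterSpace:
    if kind == "default":
        return ParameterSpace.default_box(sample_gm)
    if kind == "unrestricted":
        return ParameterSpace.unrestricted()
    if kind == "just_above":
        return ParameterSpace.just_above(sample_gm, sample_gsd)
    raise ValueError(f"unknown parameter-space kind: {kind}")


def screen_cohort(
    records: Sequence[ExposureRecord], alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Apply the across-HEG homogeneity screen to every job title.

    Returns the retained job titles (in first-seen order) and a screening
    table with H, p and the decision per title.
    """
    grouped = group_records(records)
    rows = []
    retained = []
    for job, by_heg in grouped.items():
        res = screen_job_title(by_heg, alpha=alpha, job_title=job)
        rows.append(
            {
                "job_title": job,
                "n_hegs": len(by_heg),
                "h_statistic": res.h_statistic,
                "p_value": res.p_value,
                "retained": res.retained,
            }
        )
        if res.retained:
            retained.append(job)
        log.info(
            "screening %s: %d HEG(s), p=%.4f -> %s",
            job, len(by_heg), res.p_value, "retained" if res.retained else "excluded",
        )
    return retained, pd.DataFrame(rows)


def _build_priors(
    config: RunConfig,
    job_titles: Sequence[str],
) -> dict[str, dict[str, AggregatedPrior]]:
    """Per-variant, per-job-title informative priors (empty for noninformative)."""
    priors: dict[str, dict[str, AggregatedPrior]] = {v: {} for v in config.variants}

    if "historical" in config.variants:
        if config.historical_csv is None:
            raise ValueError("historical variant requested but no historical CSV given")
        hist_records, rej = read_exposures(config.historical_csv)
        if rej:
            log.info("historical CSV: rejected %d invalid rows", rej)
        by_job = group_records(hist_records)
        for job in job_titles:
            if job not in by_job:
                log.warning("no historical data for %s; variant skipped for this title", job)
                continue
            values = [v for heg in by_job[job].values() for v in heg]
            priors["historical"][job] = historical_prior(summarize_exposures(values, job))

    if "expert" in config.variants:
        if config.experts_csv is None:
            log.warning("expert variant requested but no expert CSV given; variant skipped")
        else:
            judgements = read_experts(config.experts_csv)
            by_job: dict[str, list[ExpertJudgement]] = {}
            for j in judgements:
                by_job.setdefault(j.job_title, []).append(j)
            for job in job_titles:
                panel = by_job.get(job)
                if not panel:
                    log.warning("no expert panel for %s; variant skipped for this title", job)
                    continue
                if config.expert_subset_k is not None and config.expert_subset_k < len(panel):
                    panel = subset_experts(
                        panel,
                        config.expert_subset_k,
                        seed=variant_seed(config.mcmc.seed, job, "expert", "subset"),
                    )
                priors["expert"][job] = panel_prior(panel, n0=config.expert_n0)
    return priors


def analyze_one(
    values: Sequence[float],
    prior: PriorSpec,
    space: ParameterSpace,
    settings: MCMCSettings,
    scheme: CategoryScheme,
    job_title: str = "",
    prior_kind_label: str | None = None,
) -> tuple[dict, PosteriorDraws]:
    """Sample one (job title, prior) cell and flatten it to a result row."""
    data = log_sufficient_stats(values)
    draws = gibbs_sample(data, prior, space, settings)
    conv = convergence_report(draws)
    summ = summarize_posterior(draws)
    cats = category_probabilities(draws.flat("p95"), scheme)
    pct = cats.as_percent()
    row = {
        "job_title": job_title,
        "prior_kind": prior_kind_label or prior.kind,
        "gm_median": summ.gm.median,
        "gm_lo": summ.gm.lo,
        "gm_hi": summ.gm.hi,
        "gsd_median": summ.gsd.median,
        "gsd_lo": summ.gsd.lo,
        "gsd_hi": summ.gsd.hi,
        "p95_median": summ.p95.median,
        "p95_lo": summ.p95.lo,
        "p95_hi": summ.p95.hi,
        "cat1_pct": pct[0],
        "cat2_pct": pct[1],
        "cat3_pct": pct[2],
        "cat4_pct": pct[3],
        "rhat_mu": conv.rhat_mu,
        "rhat_sigma": conv.rhat_sigma,
        "converged": conv.passed,
    }
    return row, draws


def run_analysis(config: RunConfig) -> pd.DataFrame:
    """Screen the cohort, build priors, sample every (job title, variant) cell.

    A cell whose chains fail the R-hat threshold is reported with NaN
    summaries but its diagnostics kept, so a convergence failure is visible
    rather than silently published; the run continues for other titles.
    """
    records, rejected = read_exposures(config.exposures_csv)
    if rejected:
        log.info("exposure CSV: rejected %d invalid rows", rejected)
    retained, screening = screen_cohort(records, alpha=config.alpha)
    if not retained:
        raise EmptyCohortError("screening excluded every job title")

    by_job = group_records(records)
    priors = _build_priors(config, retained)
    scheme = CategoryScheme(oel=config.oel)

    rows = []
    for job in retained:
        values = [v for heg in by_job[job].values() for v in heg]
        sample = summarize_exposures(values, job)
        space = config.space or ParameterSpace.default_box(sample.gm)
        for variant in config.variants:
            if variant == "noninformative":
                prior = PriorSpec(kind="noninformative")
            else:
                agg = priors[variant].get(job)
                if agg is None:
                    continue
                prior = PriorSpec(
                    kind="informative",
                    prior_mean=agg.prior_mean,
                    prior_variance=agg.prior_variance,
                    prior_n=agg.prior_n,
                )
            settings = replace(config.mcmc, seed=variant_seed(config.mcmc.seed, job, variant))
            row, _ = analyze_one(
                values, prior, space, settings, scheme, job_title=job, prior_kind_label=variant
            )
            if not row["converged"]:
                log.warning(
                    "R-hat failure for %s/%s (mu %.3f, sigma %.3f); summaries withheld",
                    job, variant, row["rhat_mu"], row["rhat_sigma"],
                )
                for k in RESULT_COLUMNS[2:15]:
                    row[k] = float("nan")
            rows.append(row)

    results = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        screening.to_csv(out / "screening.csv", index=False)
        report_tables(results, out, config)
    return results


def run_sensitivity(plan: SensitivityPlan, config: RunConfig) -> pd.DataFrame:
    """Compare category probabilities across parameter-space variants.

    Emits one row per (job title, prior variant, space variant) with the
    four category percentages — the sensitivity-comparison grid.
    """
    records, _ = read_exposures(config.exposures_csv)
    by_job = group_records(records)
    missing = [j for j in plan.job_titles if j not in by_job]
    if missing:
        raise ValueError(f"sensitivity job titles not in data: {missing}")
    priors = _build_priors(config, plan.job_titles)
    scheme = CategoryScheme(oel=config.oel)

    rows = []
    for job in plan.job_titles:
        values = [v for heg in by_job[job].values() for v in heg]
        sample = summarize_exposures(values, job)
        for variant in config.variants:
            if variant == "noninformative":
                prior = PriorSpec(kind="noninformative")
            else:
                agg = priors[variant].get(job)
                if agg is None:
                    continue
                prior = PriorSpec(
                    kind="informative",
                    prior_mean=agg.prior_mean,
                    prior_variance=agg.prior_variance,
                    prior_n=agg.prior_n,
                )
            for space_name, space_kind in plan.spaces:
                space = _space_for(space_kind, sample.gm, sample.gsd)
                settings = replace(
                    config.mcmc,
                    seed=variant_seed(config.mcmc.seed, job, variant, space_name),
                )
                row, _ = analyze_one(
                    values, prior, space, settings, scheme,
                    job_title=job, prior_kind_label=variant,
                )
                row["space"] = space_name
                rows.append(row)

    cols = ["job_title", "prior_kind", "space", "cat1_pct", "cat2_pct", "cat3_pct", "cat4_pct",
            "p95_median", "rhat_mu", "rhat_sigma", "converged"]
    results = pd.DataFrame(rows)[cols]
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results_rounded = results.copy()
        num = results_rounded.select_dtypes("number").columns
        results_rounded[num] = results_rounded[num].round(2)
        results_rounded.to_csv(out / "sensitivity.csv", index=False)
    return results


def report_tables(results: pd.DataFrame, out_dir: str | Path, config: RunConfig) -> Path:
    """Write the results CSV (2-decimal precision) and a run manifest.

    Deterministic column order; identical config + seed reproduces the files
    byte for byte.
    """
    if len(results) == 0:
        raise ValueError("no result rows to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = results[RESULT_COLUMNS].copy()
    num = table.select_dtypes("number").columns
    table[num] = table[num].round(2)
    path = out / "results.csv"
    table.to_csv(path, index=False)

    cfg_repr = {
        "exposures_csv": str(config.exposures_csv),
        "experts_csv": str(config.experts_csv),
        "historical_csv": str(config.historical_csv),
        "oel": config.oel,
        "variants": list(config.variants),
        "alpha": config.alpha,
        "mcmc": {
            "chains": config.mcmc.chains,
            "iterations": config.mcmc.iterations,
            "burn_in": config.mcmc.burn_in,
            "seed": config.mcmc.seed,
            "rhat_threshold": config.mcmc.rhat_threshold,
        },
    }
    blob = json.dumps(cfg_repr, sort_keys=True)
    manifest = {
        "config": cfg_repr,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": config.mcmc.seed,
        "version": __version__,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def write_exposure_csv(records: Sequence[ExposureRecord], path: str | Path) -> None:
    """Write records in the canonical exposure CSV schema."""
    df = pd.DataFrame(
        {
            "job_title": [r.job_title for r in records],
            "heg_id": [r.heg_id for r in records],
            "year": [r.year for r in records],
            "twa8h_mg_m3": [r.twa8h for r in records],
        }
    )
    df.to_csv(path, index=False)
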