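"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by brute force (enumeration, grid search,
or deterministic quadrature) without touching the implementation path it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def kruskal_h(groups: list[list[float]]) -> float:
    """H from first principles: mid-ranks, rank sums, tie correction."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def kw_exact_pvalue(groups: list[list[float]]) -> float:
    """Exact permutation p-value P(H >= H_obs) for two small groups."""
    assert len(groups) == 2
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n1 = len(groups[0])
    h_obs = kruskal_h(groups)
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(comb)] = True
        h = kruskal_h([list(pooled[mask]), list(pooled[~mask])])
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def grid_quartile_fit(
    q1: float, median: float, q3: float, n_grid: int = 220
) -> tuple[float, float]:
    """Brute-force grid minimiser of the quartile-CDF least-squares objective."""
    probs = np.array([0.25, 0.5, 0.75])
    logq = np.log([q1, median, q3])
    mus = np.linspace(logq[0] - 1.0, logq[2] + 1.0, n_grid)
    sigs = np.linspace(1e-3, 2.0 * (logq[2] - logq[0]) + 1.0, n_grid)
    best = (np.inf, np.nan, np.nan)
    for m in mus:
        cdf = stats.norm.cdf((logq[None, :] - m) / sigs[:, None])
        sse = np.sum((cdf - probs[None, :]) ** 2, axis=1)
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            best = (float(sse[j]), float(m), float(sigs[j]))
    return best[1], best[2]


def grid_posterior_moments(data, prior, space, n_grid: int = 500):
    """Deterministic 2-D quadrature of the truncated posterior.

    Returns (E[mu], E[sigma]) under the same model the Gibbs sampler targets:
    lognormal likelihood in (mu, sigma), either a uniform-on-(mu, sigma)
    prior over the box or the conjugate normal/inverse-gamma prior, all
    truncated to the box.
    """
    mu_lo, mu_hi = space.mu_bounds
    sig_lo, sig_hi = space.sigma_bounds
    n, ybar, ss = data.n, data.mean_log, data.sum_sq
    sd = max(data.sd_log, 1e-6)

    centers = [ybar]
    if prior.kind == "informative":
        centers.append(prior.prior_mean)
    span = 12.0 * sd / math.sqrt(n)
    mu_a = max(mu_lo, min(centers) - span)
    mu_b = min(mu_hi, max(centers) + span)
    sig_a = max(sig_lo, sd / 5.0)
    sig_b = min(sig_hi, sd * 5.0)

    mu = np.linspace(mu_a, mu_b, n_grid)
    sig = np.linspace(sig_a, sig_b, n_grid)
    M, S = np.meshgrid(mu, sig, indexing="ij")

    ss_mu = ss + n * (ybar - M) ** 2
    logp = -n * np.log(S) - ss_mu / (2.0 * S**2)
    if prior.kind == "informative":
        prior_var = prior.prior_variance / prior.prior_n
        logp = logp - (M - prior.prior_mean) ** 2 / (2.0 * prior_var)
        a = (prior.prior_n - 1.0) / 2.0
        rate = (prior.prior_n - 1.0) * prior.prior_variance / 2.0
        # inverse-gamma density on sigma^2, with Jacobian d(sigma^2)/d(sigma) = 2 sigma
        logp = logp + (-(a + 1.0) * 2.0 * np.log(S) - rate / S**2 + np.log(2.0 * S))

    w = np.exp(logp - logp.max())
    z = np.trapezoid(np.trapezoid(w, sig, axis=1), mu)
    e_mu = np.trapezoid(np.trapezoid(w * M, sig, axis=1), mu) / z
    e_sig = np.trapezoid(np.trapezoid(w * S, sig, axis=1), mu) / z
    return float(e_mu), float(e_sig)


def mc_se(chains: np.ndarray) -> float:
    """Monte-Carlo standard error of the mean from ESS (via arviz)."""
    import arviz as az

    arr = chains[None] if chains.ndim == 1 else chains
    ess = float(az.ess(az.convert_to_dataset(arr))["x"].values)
    return float(np.std(arr) / math.sqrt(max(ess, 1.0)))
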