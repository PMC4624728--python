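"""Monte-Carlo uncertainty over the milestoning model and convergence checks.

Transition counts out of a milestone are multinomial, so the rows of the
transition kernel get the conjugate treatment: row i of K is drawn from
Dirichlet(N_ij + alpha) over the observed destinations (alpha = 1/2, a
Jeffreys-style prior, by default).  The mean incubation time of row i is
drawn from a gamma distribution with shape equal to the row's transition
count and the observed mean preserved, so its posterior spread shrinks as
1/sqrt(count).  Every sampled model is pushed through the full estimator
(beta, two-regime k_on, MFPT, free energies) to yield central credible
intervals, and running estimates over the event stream monitor convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .milestoning import (RateEstimate, TransitionKernel, TransitionStatistics,
                          beta_from_flux, estimate_kernel, free_energy_profile,
                          kon_two_regime, mfpt, recycled_kernel,
                          stationary_flux)
from .network import MilestoneNetwork


@dataclass(frozen=True)
class KernelPosteriorSample:
    """One posterior draw of the milestoning model."""

    K_sample: np.ndarray
    t_sample: np.ndarray
    draw_index: int


def sample_kernel_posterior(stats: TransitionStatistics, n_samples: int,
                            seed: int, alpha_prior: float = 0.5,
                            support: np.ndarray | None = None,
                            ) -> list[KernelPosteriorSample]:
    """Posterior draws of (K, t) given the observed crossing statistics.

    ``support`` optionally fixes the admissible destinations per row (e.g.
    the nearest-neighbour adjacency); by default the support is the set of
    destinations actually observed.  Rows with no counts and no declared
    support are excluded with a warning (their K row stays zero).
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    n = stats.n
    counts = stats.counts
    row_tot = stats.row_totals
    if not row_tot.any():
        raise ValueError("no transitions observed")
    if support is None:
        support = counts > 0
    support = np.asarray(support, dtype=bool)
    t_hat = np.zeros(n)
    obs = row_tot > 0
    t_hat[obs] = stats.incubation_total[obs] / row_tot[obs]

    skipped = [i for i in range(n) if not support[i].any() and row_tot[i] > 0]
    empty = [i for i in range(n) if row_tot[i] == 0 and not support[i].any()]
    if empty:
        warnings.warn(f"rows with zero counts excluded from sampling: {empty}",
                      stacklevel=2)
    if skipped:
        raise ValueError(f"support excludes every observed destination of rows {skipped}")

    out: list[KernelPosteriorSample] = []
    for d in range(n_samples):
        K = np.zeros((n, n))
        t = np.full(n, np.nan)
        for i in range(n):
            cols = np.flatnonzero(support[i])
            if cols.size == 0:
                continue
            K[i, cols] = rng.dirichlet(counts[i, cols] + alpha_prior)
            if row_tot[i] > 0:
                # gamma with shape = count, mean preserved
                t[i] = rng.gamma(shape=row_tot[i],
                                 scale=t_hat[i] / row_tot[i])
            else:
                t[i] = np.nan
        out.append(KernelPosteriorSample(K_sample=K, t_sample=t, draw_index=d))
    return out


def _estimate_from_sample(sample: KernelPosteriorSample,
                          network: MilestoneNetwork,
                          start: np.ndarray,
                          k_b: float | None, k_q: float | None,
                          T: float):
    kernel = TransitionKernel(sample.K_sample, sample.t_sample,
                              sink_set=network.sink_indices)
    beta = beta_from_flux(kernel, network)
    tau = mfpt(kernel, start)
    kon = kon_two_regime(k_b, k_q, beta) if k_b is not None and k_q is not None else np.nan
    stat = stationary_flux(recycled_kernel(kernel, network.b_index))
    dG = free_energy_profile(stat, ref_index=network.b_index, T=T)
    return beta, tau, kon, dG


def propagate_uncertainty(samples: list[KernelPosteriorSample],
                          network: MilestoneNetwork,
                          k_b: float | None = None,
                          k_q: float | None = None,
                          T: float = 300.0,
                          start: np.ndarray | None = None,
                          level: float = 0.95) -> RateEstimate:
    """Push posterior kernel samples through the estimator.

    Returns the posterior median of beta, k_on (two-regime composition when
    k_b and k_q are supplied), MFPT from the b-surface, and the free-energy
    profile, each with a central credible interval at ``level``.  Samples
    whose linear solves fail are dropped and counted; more than 1% dropped
    is an error.
    """
    if len(samples) < 100:
        raise ValueError("need at least 100 posterior samples")
    if start is None:
        start = np.zeros(network.n)
        start[network.b_index] = 1.0
    betas, taus, kons, dGs = [], [], [], []
    dropped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in samples:
            try:
                b, tau, kon, dG = _estimate_from_sample(
                    s, network, start, k_b, k_q, T)
            except (np.linalg.LinAlgError, ValueError):
                dropped += 1
                continue
            betas.append(b)
            taus.append(tau)
            kons.append(kon)
            dGs.append(dG)
    if dropped > 0.01 * len(samples):
        raise RuntimeError(f"{dropped}/{len(samples)} posterior samples failed")
    lo, hi = 50.0 * (1.0 - level), 50.0 * (1.0 + level)
    betas = np.array(betas)
    taus = np.array(taus)
    kons = np.array(kons)
    dGs = np.array(dGs)
    est = RateEstimate(
        beta=float(np.median(betas)),
        kon=float(np.median(kons)) if np.isfinite(kons).any() else None,
        mfpt=float(np.median(taus)),
        dG=np.median(dGs, axis=0),
        level=level,
    )
    est.intervals = {
        "beta": (float(np.percentile(betas, lo)), float(np.percentile(betas, hi))),
        "mfpt": (float(np.percentile(taus, lo)), float(np.percentile(taus, hi))),
    }
    if np.isfinite(kons).any():
        est.intervals["kon"] = (float(np.percentile(kons, lo)),
                                float(np.percentile(kons, hi)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est.intervals["dG"] = (np.nanpercentile(dGs, lo, axis=0),
                               np.nanpercentile(dGs, hi, axis=0))
    return est


def convergence_series(events: pd.DataFrame, network: MilestoneNetwork,
                       checkpoints=None,
                       k_b: float | None = None,
                       k_q: float | None = None) -> pd.DataFrame:
    """Running beta / MFPT / k_on over growing prefixes of the event stream.

    ``checkpoints`` are fractions of the stream (default 10 evenly spaced,
    ending at 1.0 so the last row equals the full-data estimate).
    Checkpoints at which some milestone has not yet completed a transition
    are skipped.
    """
    if checkpoints is None:
        checkpoints = np.linspace(0.1, 1.0, 10)
    n_events = len(events)
    start = np.zeros(network.n)
    start[network.b_index] = 1.0
    non_sink = [i for i in range(network.n) if i not in network.sink_indices]
    rows = []
    for f in checkpoints:
        m = int(round(f * n_events))
        sub = events.iloc[:m]
        seen = set(sub["src_milestone"].unique())
        if not set(non_sink).issubset(seen):
            continue
        stats = TransitionStatistics.from_events(
            network.n, sub["src_milestone"], sub["dst_milestone"],
            sub["transit_time_ps"])
        kernel = estimate_kernel(stats, network)
        beta = beta_from_flux(kernel, network)
        tau = mfpt(kernel, start)
        kon = kon_two_regime(k_b, k_q, beta) \
            if k_b is not None and k_q is not None else np.nan
        rows.append({"fraction": f, "n_events": m, "beta": beta,
                     "mfpt_ps": tau, "kon_M1s1": kon})
    return pd.DataFrame(rows)
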