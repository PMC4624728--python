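"""Milestoning estimator: kernel, stationary flux, beta, MFPT, free energy.

The milestoning model of an association process keeps, per milestone i, the
observed transition counts N_ij to other milestones and the summed transit
(incubation) times R_i.  From these it forms a row-stochastic transition
kernel K_ij = N_ij / sum_k N_ik and the mean incubation-time vector
t_i = R_i / sum_k N_ik, and derives:

* the stationary flux q solving q (I - K) = 0,
* the stationary probability p_i proportional to q_i t_i,
* the mean first passage time  <tau> = start . (I - K~)^-1 . t  where K~
  zeroes the rows of the absorbing (sink) milestones,
* the binding probability beta: the chance that a ligand entering at the
  b-surface milestone reaches a bound milestone before the escape surface,
* the free-energy profile dG_i = -k_B T ln(p_i / p_ref),
* the composed association constants k_on = k_b beta and its two-regime
  refinement k_on = k_b beta / (1 - (1 - beta) k_b / k_q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import constants as C
from .network import MilestoneNetwork

_STATIONARY_RTOL = 1e-10
_BETA_AGREEMENT = 1e-10


@dataclass
class TransitionStatistics:
    """Raw crossing statistics: integer count matrix N and the cumulative
    incubation-time accumulator R (ps) for transitions leaving each row."""

    counts: np.ndarray
    incubation_total: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.incubation_total = np.asarray(self.incubation_total, dtype=float)
        n, m = self.counts.shape
        if n != m:
            raise ValueError("count matrix must be square")
        if self.incubation_total.shape != (n,):
            raise ValueError("incubation vector length must match counts")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if np.diag(self.counts).any():
            raise ValueError("self-transitions N_ii must be zero")
        if (self.incubation_total < 0).any():
            raise ValueError("incubation totals must be non-negative")
        row = self.counts.sum(axis=1)
        if ((row == 0) & (self.incubation_total > 0)).any():
            raise ValueError("incubation time recorded for a row with no counts")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __add__(self, other: "TransitionStatistics") -> "TransitionStatistics":
        return TransitionStatistics(self.counts + other.counts,
                                    self.incubation_total + other.incubation_total)

    @classmethod
    def empty(cls, n: int) -> "TransitionStatistics":
        return cls(np.zeros((n, n), dtype=np.int64), np.zeros(n))

    @classmethod
    def from_events(cls, n: int, src, dst, transit_ps) -> "TransitionStatistics":
        """Accumulate an event stream (arrays of source index, destination
        index, transit time in ps) into count/time statistics."""
        src = np.asarray(src, dtype=np.int64)
        dst = np.asarray(dst, dtype=np.int64)
        transit = np.asarray(transit_ps, dtype=float)
        if (src == dst).any():
            raise ValueError("event stream contains a self-transition")
        if (transit < 0).any():
            raise ValueError("negative transit time in event stream")
        if src.size and (src.min() < 0 or src.max() >= n or dst.min() < 0 or dst.max() >= n):
            raise ValueError("milestone index outside the configured network")
        counts = np.zeros((n, n), dtype=np.int64)
        np.add.at(counts, (src, dst), 1)
        R = np.zeros(n)
        np.add.at(R, src, transit)
        return cls(counts, R)


@dataclass
class TransitionKernel:
    """Row-stochastic milestone transition kernel with incubation times.

    ``observed`` flags rows backed by at least one transition; rows never
    exited are kept but flagged (their K row is zero and t is NaN) rather
    than silently imputed.  ``sink_set`` lists the absorbing milestones
    whose outgoing rows are zeroed to form K~.
    """

    K: np.ndarray
    t: np.ndarray
    sink_set: tuple[int, ...] = ()
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n) or self.t.shape != (n,):
            raise ValueError("inconsistent kernel dimensions")
        if self.observed is None:
            self.observed = self.K.sum(axis=1) > 0
        if (self.K < -1e-15).any() or (self.K > 1 + 1e-15).any():
            raise ValueError("kernel entries outside [0, 1]")
        if np.abs(np.diag(self.K)).max(initial=0.0) > 0:
            raise ValueError("kernel diagonal must be zero")
        rows = self.K.sum(axis=1)
        live = self.observed & ~np.isin(np.arange(n), self.sink_set)
        if live.any() and np.abs(rows[live] - 1.0).max() > 1e-12:
            raise ValueError("non-sink rows must sum to 1 within 1e-12")

    @property
    def n(self) -> int:
        return self.K.shape[0]

    @property
    def K_tilde(self) -> np.ndarray:
        """Kernel with sink rows zeroed (absorbing chain)."""
        Kt = self.K.copy()
        for s in self.sink_set:
            Kt[s, :] = 0.0
        return Kt

    def with_sinks(self, sinks) -> "TransitionKernel":
        return TransitionKernel(self.K.copy(), self.t.copy(),
                                sink_set=tuple(sorted(sinks)),
                                observed=self.observed.copy())


@dataclass(frozen=True)
class StationaryResult:
    """Stationary flux q and stationary probability p (both sum to 1)."""

    q: np.ndarray
    p: np.ndarray


@dataclass
class RateEstimate:
    """Headline kinetic quantities with optional confidence intervals.

    beta is dimensionless, kon in M^-1 s^-1, mfpt in ps, dG per milestone
    in kcal/mol relative to the reference milestone.  ``intervals`` maps a
    quantity name to (lower, upper) at ``level`` confidence.
    """

    beta: float
    kon: float | None = None
    mfpt: float | None = None
    dG: np.ndarray | None = None
    intervals: dict = field(default_factory=dict)
    level: float = 0.95


def estimate_kernel(stats: TransitionStatistics,
                    network: MilestoneNetwork | None = None,
                    sinks=()) -> TransitionKernel:
    """Maximum-likelihood kernel and incubation times from raw statistics.

    K_ij = N_ij / sum_k N_ik and t_i = R_i / sum_k N_ik on rows with
    observed transitions; empty rows are flagged via ``observed``.
    """
    if network is not None and stats.n != network.n:
        raise ValueError(
            f"statistics dimension {stats.n} does not match network {network.n}")
    row = stats.row_totals
    if not row.any():
        raise ValueError("no transitions observed")
    observed = row > 0
    if ((row > 0) & (stats.incubation_total <= 0)).any():
        raise ValueError("row with counts but zero incubation total")
    K = np.zeros_like(stats.counts, dtype=float)
    K[observed] = stats.counts[observed] / row[observed, None]
    t = np.full(stats.n, np.nan)
    t[observed] = stats.incubation_total[observed] / row[observed]
    if network is not None and not sinks:
        sinks = network.sink_indices
    return TransitionKernel(K, t, sink_set=tuple(sorted(sinks)), observed=observed)


def stationary_flux(kernel: TransitionKernel) -> StationaryResult:
    """Stationary flux q with q (I - K) = 0 and probability p_i ~ q_i t_i.

    Solved as the left Perron eigenvector of K by a dense eigendecomposition
    (milestone counts are at most dozens); the residual ||q(I-K)||_inf must
    be below 1e-10.
    """
    K = kernel.K
    w, V = scipy.linalg.eig(K.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    if abs(w[idx] - 1.0) > 1e-8:
        raise np.linalg.LinAlgError("no unit eigenvalue: chain has no stationary flux")
    q = np.real(V[:, idx])
    q = q / q.sum()
    if (q < -_STATIONARY_RTOL).any():
        raise np.linalg.LinAlgError("stationary vector has negative entries")
    q = np.clip(q, 0.0, None)
    q = q / q.sum()
    resid = np.abs(q @ (np.eye(kernel.n) - K)).max()
    if resid > _STATIONARY_RTOL:
        raise np.linalg.LinAlgError(f"stationary residual {resid:.2e} exceeds tolerance")
    t_safe = np.where(np.isnan(kernel.t), 0.0, kernel.t)
    p = q * t_safe
    total = p.sum()
    if total > 0:
        p = p / total
    return StationaryResult(q=q, p=p)


def mfpt(kernel: TransitionKernel, start: np.ndarray) -> float:
    """Mean first passage time start . (I - K~)^-1 . t, in ps.

    ``start`` is a probability vector over milestones.  Mass placed on a
    sink contributes zero time (with a warning).  Rows never observed are
    excluded from the transient set; if a sink is unreachable the linear
    solve is singular and an error is raised.
    """
    start = np.asarray(start, dtype=float)
    if start.shape != (kernel.n,):
        raise ValueError("start vector length must match kernel")
    if abs(start.sum() - 1.0) > 1e-9:
        raise ValueError("start vector must sum to 1")
    if not kernel.sink_set:
        raise ValueError("kernel has no sink set; MFPT undefined")
    sinks = np.isin(np.arange(kernel.n), kernel.sink_set)
    if start[sinks].sum() > 0:
        warnings.warn("start distribution has mass on a sink; it contributes 0",
                      stacklevel=2)
    transient = kernel.observed & ~sinks
    idx = np.flatnonzero(transient)
    if idx.size == 0:
        return 0.0
    Kt = kernel.K_tilde[np.ix_(idx, idx)]
    t = kernel.t[idx]
    A = np.eye(idx.size) - Kt
    try:
        tau_vec = scipy.linalg.solve(A, t)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "(I - K~) is singular: no sink reachable from the transient set") from exc
    value = float(start[idx] @ tau_vec)
    if value < 0:
        raise np.linalg.LinAlgError("negative MFPT: inconsistent kernel")
    return value


def absorption_probabilities(kernel: TransitionKernel, targets) -> np.ndarray:
    """Per-milestone probability of absorbing in ``targets`` (a subset of
    the sink set) before any other sink, via the fundamental matrix."""
    targets = set(targets)
    if not targets.issubset(kernel.sink_set):
        raise ValueError("targets must be sink milestones")
    n = kernel.n
    sinks = np.isin(np.arange(n), kernel.sink_set)
    transient = kernel.observed & ~sinks
    idx = np.flatnonzero(transient)
    h = np.zeros(n)
    for s in targets:
        h[s] = 1.0
    if idx.size:
        Kt = kernel.K[np.ix_(idx, idx)]
        # one-step absorption vector into the target set
        b = kernel.K[idx, :] @ h
        h_tr = scipy.linalg.solve(np.eye(idx.size) - Kt, b)
        h[idx] = h_tr
    return h


def recycled_kernel(kernel: TransitionKernel, b_index: int) -> TransitionKernel:
    """Close the absorbing chain cyclically: all sink outflow is re-injected
    at the b-surface milestone, defining the stationary-flux problem."""
    K = kernel.K.copy()
    for s in kernel.sink_set:
        K[s, :] = 0.0
        K[s, b_index] = 1.0
    obs = kernel.observed.copy()
    obs[list(kernel.sink_set)] = True
    return TransitionKernel(K, kernel.t, sink_set=(), observed=obs)


def beta_from_flux(kernel: TransitionKernel, network: MilestoneNetwork) -> float:
    """Binding probability beta from the b-surface.

    Computed two ways and cross-checked to 1e-10: (i) the stationary flux of
    the recycled chain, beta = sum_z q_z over bound milestones normalised by
    the total sink flux (i.e. q scaled to unit absorbed current); (ii) the
    absorption probability from the b-surface into the bound set via the
    fundamental matrix.
    """
    if not kernel.sink_set:
        raise ValueError("kernel must be estimated with bound/escape sinks")
    bound = set(network.bound_indices) & set(kernel.sink_set)
    escape = network.q_index
    if not bound:
        raise ValueError("no bound milestone in the sink set")

    h = absorption_probabilities(kernel, bound)
    beta_absorb = float(h[network.b_index])

    h_esc = absorption_probabilities(kernel, {escape})
    if beta_absorb == 0.0 and h_esc[network.b_index] == 0.0:
        raise np.linalg.LinAlgError("neither bound nor escape reachable from b-surface")
    if beta_absorb == 0.0:
        warnings.warn("bound state unreachable from the b-surface: beta = 0",
                      stacklevel=2)
        return 0.0

    rec = recycled_kernel(kernel, network.b_index)
    q = stationary_flux(rec).q
    sink_flux = q[list(kernel.sink_set)].sum()
    beta_rec = float(q[sorted(bound)].sum() / sink_flux)

    if abs(beta_rec - beta_absorb) > _BETA_AGREEMENT:
        raise AssertionError(
            f"beta formulations disagree: recycled {beta_rec!r} vs "
            f"absorption {beta_absorb!r}")
    return beta_absorb


def kon_from_kb_beta(k_b: float, beta: float) -> float:
    """Compose k_on = k_b * beta (units follow k_b)."""
    if k_b < 0:
        raise ValueError("k_b must be non-negative")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    return k_b * beta


def kon_two_regime(k_b: float, k_q: float, beta: float) -> float:
    """Two-regime composition k_on = k_b beta / (1 - (1-beta) k_b/k_q).

    Corrects k_b * beta for ligands that recross the b-surface outward but
    return from the q-surface region instead of escaping.  For free
    diffusion with k(r) = 4 pi r D and beta the analytic committor this
    reduces exactly to the Smoluchowski rate at the reaction radius.
    """
    if k_b < 0 or k_q <= 0:
        raise ValueError("rates must be positive")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    denom = 1.0 - (1.0 - beta) * (k_b / k_q)
    if denom <= 0:
        raise ValueError(
            f"non-positive denominator: k_b={k_b!r}, k_q={k_q!r}, beta={beta!r} "
            "are mutually inconsistent")
    return k_b * beta / denom


def free_energy_profile(stationary: StationaryResult, ref_index: int,
                        T: float) -> np.ndarray:
    """Free energies dG_i = -k_B T ln(p_i / p_ref) in kcal/mol.

    The reference milestone is exactly 0; milestones with zero stationary
    probability are reported as NaN (undefined), not infinite.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    p = stationary.p
    p_ref = p[ref_index]
    if p_ref <= 0:
        raise ValueError("reference milestone has non-positive probability")
    dG = np.full(p.shape, np.nan)
    pos = p > 0
    dG[pos] = -C.KB_KCAL_PER_MOL_K * T * np.log(p[pos] / p_ref)
    dG[ref_index] = 0.0
    return dG
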