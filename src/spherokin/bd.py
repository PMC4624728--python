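"""Overdamped Brownian dynamics of a point ligand in a central potential.

The propagator is the position-only reduction of the general Brownian
equation of motion for a single isotropic particle with constant scalar
diffusion coefficient D (rigid-body rotation, hydrodynamic coupling and
the divergence term vanish in this limit):

    dx = (D / k_B T) F dt + sqrt(2 D dt) w,

with F = -dU/dr r_hat the central force and w a vector of independent
standard Gaussians.  Concentric spherical milestones are detected as radii
crossed between consecutive steps, with the crossing time and position
linearly interpolated in radius.

The module is the synthetic-data engine of the package: it produces
brute-force binding probabilities and first passage times, first-hitting
point distributions (FHPDs) on the milestones, and the milestone-crossing
event streams consumed by the milestoning estimator.

Reproducibility: every trajectory draws from its own counter-based stream
(Philox keyed by the master seed and the trajectory id), so results are
independent of batching or execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .milestoning import TransitionStatistics
from .network import MilestoneNetwork, benchmark_network
from .physics import CentralPotential

_BLOCK = 256  # steps drawn per trajectory per batch round (fixed: part of the stream contract)

EVENT_COLUMNS = ("traj_id", "src_milestone", "dst_milestone", "transit_time_ps")


@dataclass(frozen=True)
class BDSystemSpec:
    """Simulation specification: physics + milestone geometry + integrator.

    The default timestep 0.01 ps gives a per-step displacement scale
    sqrt(2 D dt) of about 0.05 A for D = 0.133 A^2/ps, comfortably below a
    quarter of the 1 A milestone spacing, which is enforced as an invariant
    so that no step can silently skip a milestone.
    """

    physics: CentralPotential
    network: MilestoneNetwork = field(default_factory=benchmark_network)
    dt: float = 0.01
    seed: int = 0
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        radii = self.network.radii
        gap = min(r2 - r1 for r1, r2 in zip(radii, radii[1:]))
        sigma = math.sqrt(2.0 * self.physics.D * self.dt)
        if sigma >= gap / 4.0:
            raise ValueError(
                f"dt too large: step scale {sigma:.3g} A >= quarter of the "
                f"minimum milestone gap {gap:.3g} A")

    @property
    def sigma(self) -> float:
        """Per-coordinate step scale sqrt(2 D dt), angstrom."""
        return math.sqrt(2.0 * self.physics.D * self.dt)


@dataclass
class PhasePoint:
    """State of a ligand: position (A), last milestone crossed, elapsed ps."""

    position: np.ndarray
    last_milestone: int | None = None
    elapsed: float = 0.0

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.position))


def trajectory_rng(master_seed: int, traj_id: int) -> np.random.Generator:
    """Counter-based per-trajectory stream keyed by (master seed, id)."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence([master_seed, traj_id])))


def uniform_sphere_points(n: int, radius: float,
                          rng: np.random.Generator) -> np.ndarray:
    """n points uniformly distributed on the sphere of given radius."""
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius


def _drift_coefficient(spec: BDSystemSpec, r2: np.ndarray) -> np.ndarray:
    """Radial drift displacement per unit position vector for one step.

    The drift term (D/k_B T) F dt with F/k_B T = -rc/r^2 r_hat gives a
    displacement (D dt rc / r^3) x, signed by the Onsager length (negative
    rc pulls inward).
    """
    rc = spec.physics.onsager_length
    if rc == 0.0:
        return np.zeros_like(r2)
    return spec.physics.D * spec.dt * rc / (r2 * np.sqrt(r2))


def propagate_step(point: PhasePoint, spec: BDSystemSpec,
                   rng: np.random.Generator) -> PhasePoint:
    """Advance one Brownian step (boundary handling is the caller's)."""
    pos = np.asarray(point.position, dtype=float)
    r2 = np.array([pos @ pos])
    drift = _drift_coefficient(spec, r2)[0] * pos
    new = pos + drift + spec.sigma * rng.standard_normal(3)
    return PhasePoint(position=new, last_milestone=point.last_milestone,
                      elapsed=point.elapsed + spec.dt)


def detect_crossings(prev: PhasePoint, next_: PhasePoint,
                     spec: BDSystemSpec) -> list[tuple[int, float]]:
    """Milestone radii strictly between |prev| and |next|, in traversal
    order, with crossing times linearly interpolated in radius.

    Crossing more than one milestone in a single step violates the
    timestep invariant and raises.
    """
    r0, r1 = prev.radius, next_.radius
    lo, hi = min(r0, r1), max(r0, r1)
    hits = [m for m in spec.network.milestones if lo < m.radius < hi]
    if len(hits) > 1:
        raise RuntimeError(
            f"step from r={r0:.3f} to r={r1:.3f} A skipped "
            f"{len(hits)} milestones: timestep too large")
    out = []
    for m in (hits if r1 > r0 else hits[::-1]):
        frac = (m.radius - r0) / (r1 - r0)
        out.append((m.index, prev.elapsed + frac * spec.dt))
    return out


class _BatchResult:
    """Per-trajectory outcome of a batch propagation."""

    __slots__ = ("stop_radius_idx", "time", "position", "censored")

    def __init__(self, n: int):
        self.stop_radius_idx = np.full(n, -1, dtype=np.int64)
        self.time = np.full(n, np.nan)
        self.position = np.full((n, 3), np.nan)
        self.censored = np.zeros(n, dtype=bool)


def _propagate_batch(spec: BDSystemSpec, traj_ids: np.ndarray,
                     start_positions: np.ndarray,
                     stop_radii: np.ndarray,
                     rngs: list[np.random.Generator] | None = None) -> _BatchResult:
    """Propagate a batch of trajectories until each first crosses one of
    ``stop_radii`` (or exceeds max_steps).

    Vectorised across trajectories; randomness is drawn per trajectory
    from its counter-based stream in fixed-size blocks so the outcome of
    any single trajectory is independent of the batch composition.

    Start points lying exactly on a stop radius are displaced by 1e-9 A
    into the domain so that the immediate re-cross counts as a genuine
    crossing.
    """
    stop_radii = np.asarray(sorted(stop_radii), dtype=float)
    n = len(traj_ids)
    res = _BatchResult(n)
    if rngs is None:
        rngs = [trajectory_rng(spec.seed, int(t)) for t in traj_ids]
    elif len(rngs) != n:
        raise ValueError("one generator per trajectory required")

    pos = np.array(start_positions, dtype=float)
    r = np.linalg.norm(pos, axis=1)
    on_stop = np.isclose(r[:, None], stop_radii[None, :], rtol=0, atol=1e-12).any(axis=1)
    if on_stop.any():
        # nudge toward the interior of the stop interval
        mid = 0.5 * (stop_radii[0] + stop_radii[-1])
        shift = np.where(r[on_stop] < mid, 1e-9, -1e-9)
        pos[on_stop] *= ((r[on_stop] + shift) / r[on_stop])[:, None]
        r = np.linalg.norm(pos, axis=1)

    active = np.arange(n)
    steps_done = 0
    dt, sigma = spec.dt, spec.sigma
    sigma2 = sigma * sigma
    n_stop = stop_radii.size
    while active.size and steps_done < spec.max_steps:
        block = min(_BLOCK, spec.max_steps - steps_done)
        noise = np.empty((active.size, block, 3))
        unif = np.empty((active.size, block, n_stop))
        for j, i in enumerate(active):
            noise[j] = rngs[i].standard_normal((block, 3))
            unif[j] = rngs[i].random((block, n_stop))
        p = pos[active]
        rr = r[active]
        live = np.ones(active.size, dtype=bool)
        for k in range(block):
            idx = np.flatnonzero(live)
            if idx.size == 0:
                break
            p_old = p[idx]
            r_old = rr[idx]
            r2 = r_old * r_old
            p_new = p_old + _drift_coefficient(spec, r2)[:, None] * p_old \
                + sigma * noise[idx, k, :]
            r_new = np.linalg.norm(p_new, axis=1)
            d_old = r_old[:, None] - stop_radii[None, :]
            d_new = r_new[:, None] - stop_radii[None, :]
            crossed = (d_old > 0) != (d_new > 0)
            ncross = crossed.sum(axis=1)
            if (ncross > 1).any():
                raise RuntimeError("a step crossed more than one stop radius: "
                                   "timestep too large")
            # unresolved within-step excursions: a Brownian bridge between
            # endpoints on the same side of a stop radius crossed it with
            # probability exp(-2 d_old d_new / sigma^2) (radial 1D bridge;
            # curvature is negligible at the enforced step scale)
            prod = d_old * d_new
            with np.errstate(over="ignore"):
                p_bridge = np.where(prod > 0.0, np.exp(-2.0 * prod / sigma2), 0.0)
            p_bridge[crossed] = 0.0
            bridged = unif[idx, k, :] < p_bridge
            for h in np.flatnonzero((ncross == 1) | bridged.any(axis=1)):
                i_local = idx[h]
                i_global = active[i_local]
                if ncross[h] == 1:
                    s_idx = int(np.flatnonzero(crossed[h])[0])
                    s = stop_radii[s_idx]
                    frac = (s - r_old[h]) / (r_new[h] - r_old[h])
                else:
                    cand = np.flatnonzero(bridged[h])
                    s_idx = int(cand[np.argmax(p_bridge[h, cand])])
                    s = stop_radii[s_idx]
                    frac = 0.5  # excursion apex: time resolved to mid-step
                res.stop_radius_idx[i_global] = s_idx
                res.time[i_global] = (steps_done + k + frac) * dt
                cp = p_old[h] + frac * (p_new[h] - p_old[h])
                # place exactly on the stop sphere (the chord point nearest
                # the crossing, radially renormalised)
                res.position[i_global] = cp * (s / np.linalg.norm(cp))
                live[i_local] = False
            p[idx] = p_new
            rr[idx] = r_new
        pos[active] = p
        r[active] = rr
        active = active[live]
        steps_done += block
    if active.size:
        res.censored[active] = True
    return res


@dataclass(frozen=True)
class BruteForceResult:
    """Binding probability and MFPT from direct absorbing-boundary runs."""

    beta: float
    mfpt: float
    se_beta: float
    se_mfpt: float
    n: int
    n_censored: int


def run_brute_force(spec: BDSystemSpec, n_traj: int,
                    start_radius: float | None = None,
                    traj_id_offset: int = 0) -> BruteForceResult:
    """Direct estimate of beta and the MFPT.

    ``n_traj`` independent trajectories start from uniformly random points
    on the sphere of ``start_radius`` (default: the b-surface) and run to
    absorption at the reaction surface or the escape surface.  beta is the
    fraction absorbed at the reaction surface; the MFPT is the mean
    absorption time.  Binomial and empirical standard errors are attached.
    The run fails if more than 0.1% of trajectories hit the step cap.
    """
    net = spec.network
    if start_radius is None:
        start_radius = net.b_radius
    a, q = net.reaction_radius, net.q_radius
    if not (a < start_radius < q):
        raise ValueError("start radius must lie strictly between the bound "
                         "and escape radii")
    traj_ids = np.arange(n_traj) + traj_id_offset
    starts = np.empty((n_traj, 3))
    rngs = [trajectory_rng(spec.seed, int(t)) for t in traj_ids]
    for j, rng in enumerate(rngs):
        starts[j] = uniform_sphere_points(1, start_radius, rng)[0]
    res = _propagate_batch(spec, traj_ids, starts, np.array([a, q]), rngs=rngs)
    n_cens = int(res.censored.sum())
    if n_cens > 0.001 * n_traj:
        raise RuntimeError(f"{n_cens} of {n_traj} trajectories censored at "
                           f"max_steps={spec.max_steps}")
    done = ~res.censored
    n_done = int(done.sum())
    bound_hits = int((res.stop_radius_idx[done] == 0).sum())
    beta = bound_hits / n_done
    times = res.time[done]
    mfpt = float(times.mean())
    se_beta = math.sqrt(beta * (1.0 - beta) / n_done)
    se_mfpt = float(times.std(ddof=1) / math.sqrt(n_done))
    return BruteForceResult(beta=beta, mfpt=mfpt, se_beta=se_beta,
                            se_mfpt=se_mfpt, n=n_done, n_censored=n_cens)


def sample_fhpd(spec: BDSystemSpec, milestone: int, n: int,
                traj_id_offset: int = 10_000_000) -> pd.DataFrame:
    """Sample n first-hitting points on a milestone (the positional FHPD).

    Trajectories are launched from uniformly random points on each adjacent
    *non-sink* milestone (nothing ever returns from a bound or escape
    surface, so sinks feed no first hits) and the phase point of first
    arrival on the target milestone is recorded, tagged with the side of
    approach ('inner'/'outer').  Launches absorbed at the reaction or
    escape surface before reaching the target are discarded.  For an
    isotropic central potential the resulting distribution is uniform over
    the target sphere.

    Returns a DataFrame with columns x, y, z, time_ps, side.
    """
    net = spec.network
    radii = net.radii
    m = milestone
    if not 0 <= m < net.n:
        raise ValueError("milestone index out of range")
    sinks = set(net.sink_indices)
    neighbours = [i for i in (m - 1, m + 1)
                  if 0 <= i < net.n and i not in sinks]
    if not neighbours:
        raise ValueError("milestone has no non-sink neighbour to feed its FHPD")
    a, q = net.reaction_radius, net.q_radius
    target_r = radii[m]

    rows: list[tuple[float, float, float, float, str]] = []
    next_id = traj_id_offset + m * 1_000_000
    batch = max(64, n // 2)
    attempts = 0
    max_attempts = 1000 * n
    while len(rows) < n and attempts < max_attempts:
        # launch an equal batch from every neighbour each round so the
        # side composition of the collected hits is launch-fair
        for nb in neighbours:
            launch_r = radii[nb]
            side = "inner" if launch_r < target_r else "outer"
            # absorbing set for the sampling problem: the target plus the
            # terminal surface bounding the launch side
            if launch_r < target_r:
                stops = np.array([a, target_r])
                target_idx = 1
            else:
                stops = np.array([target_r, q])
                target_idx = 0
            ids = np.arange(next_id, next_id + batch)
            next_id += batch
            starts = np.empty((batch, 3))
            rngs = [trajectory_rng(spec.seed, int(t)) for t in ids]
            for j, rng in enumerate(rngs):
                starts[j] = uniform_sphere_points(1, launch_r, rng)[0]
            res = _propagate_batch(spec, ids, starts, stops, rngs=rngs)
            attempts += batch
            hit = (res.stop_radius_idx == target_idx) & ~res.censored
            for i in np.flatnonzero(hit):
                rows.append((*res.position[i], res.time[i], side))
    if len(rows) < n:
        raise RuntimeError(
            f"FHPD sampling starved: {len(rows)}/{n} hits on milestone {m} "
            f"after {attempts} launches")
    # subsample uniformly from everything collected: a head-truncation would
    # over-represent whichever neighbour's batch ran first in the last round
    sub_rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence([spec.seed, m, 2**31])))
    keep = np.sort(sub_rng.choice(len(rows), size=n, replace=False))
    df = pd.DataFrame([rows[i] for i in keep],
                      columns=["x", "y", "z", "time_ps", "side"])
    return df


def run_milestoning_trajectories(
        spec: BDSystemSpec,
        fhpd: dict[int, pd.DataFrame | np.ndarray],
        n_per_milestone: int,
        traj_id_offset: int = 20_000_000,
) -> tuple[TransitionStatistics, pd.DataFrame]:
    """Harvest milestone-to-milestone transition statistics.

    From each non-sink milestone, ``n_per_milestone`` trajectories start at
    its FHPD points and run until they first cross an adjacent milestone
    (between concentric spheres a trajectory cannot reach a farther
    milestone without crossing the neighbour, so the adjacent pair is the
    complete stopping set).  Source -> destination counts and transit times
    are accumulated; the raw event stream is returned alongside.
    """
    net = spec.network
    radii = np.asarray(net.radii)
    sinks = set(net.sink_indices)
    src_list, dst_list, t_list, id_list = [], [], [], []
    next_id = traj_id_offset
    n_censored = 0
    for m in range(net.n):
        if m in sinks:
            continue
        pts = fhpd[m]
        if isinstance(pts, pd.DataFrame):
            pts = pts[["x", "y", "z"]].to_numpy()
        pts = np.asarray(pts, dtype=float)
        if len(pts) == 0:
            raise ValueError(f"no FHPD samples for milestone {m}")
        take = np.resize(np.arange(len(pts)), n_per_milestone)
        starts = pts[take]
        stops = np.array([radii[m - 1], radii[m + 1]])
        ids = np.arange(next_id, next_id + n_per_milestone)
        next_id += n_per_milestone
        res = _propagate_batch(spec, ids, starts, stops)
        cens = res.censored
        n_censored += int(cens.sum())
        dst = np.where(res.stop_radius_idx == 0, m - 1, m + 1)
        for j in np.flatnonzero(~cens):
            src_list.append(m)
            dst_list.append(int(dst[j]))
            t_list.append(float(res.time[j]))
            id_list.append(int(ids[j]))
    total = next_id - traj_id_offset
    if n_censored > 0.001 * total:
        raise RuntimeError(f"{n_censored} of {total} milestone trajectories censored")
    events = pd.DataFrame({
        "traj_id": id_list,
        "src_milestone": src_list,
        "dst_milestone": dst_list,
        "transit_time_ps": t_list,
    })
    stats = TransitionStatistics.from_events(net.n, src_list, dst_list, t_list)
    return stats, events


def run_equilibrium_radii(spec: BDSystemSpec, n_steps: int,
                          r_lo: float, r_hi: float,
                          traj_id: int = 30_000_000,
                          burn_in: int = 1000) -> np.ndarray:
    """Radii of a long run between *reflecting* spheres (sanity check: the
    radial marginal should follow r^2 exp(-U/k_B T))."""
    rng = trajectory_rng(spec.seed, traj_id)
    pos = uniform_sphere_points(1, 0.5 * (r_lo + r_hi), rng)[0]
    out = np.empty(n_steps)
    sigma = spec.sigma
    for k in range(burn_in + n_steps):
        r2 = np.array([pos @ pos])
        pos = pos + _drift_coefficient(spec, r2)[0] * pos \
            + sigma * rng.standard_normal(3)
        r = float(np.linalg.norm(pos))
        if r < r_lo:
            pos *= (2.0 * r_lo - r) / r
            r = 2.0 * r_lo - r
        elif r > r_hi:
            pos *= (2.0 * r_hi - r) / r
            r = 2.0 * r_hi - r
        if k >= burn_in:
            out[k - burn_in] = r
    return out
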