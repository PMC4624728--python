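"""Brownian-dynamics engine: reproducibility, invariants, crossing logic,
and statistical agreement with the closed-form Smoluchowski oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import spherokin as sk
from spherokin.bd import (EVENT_COLUMNS, _propagate_batch, detect_crossings,
                          propagate_step, run_brute_force,
                          run_equilibrium_radii, trajectory_rng,
                          uniform_sphere_points)


class TestSpecInvariants:
    def test_timestep_cap_enforced(self, uncharged):
        with pytest.raises(ValueError, match="dt too large"):
            sk.BDSystemSpec(physics=uncharged, dt=1.0)

    def test_sigma_definition(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, dt=0.01)
        assert spec.sigma == pytest.approx(math.sqrt(2 * uncharged.D * 0.01))

    @pytest.mark.parametrize("kwargs", [dict(dt=-0.01), dict(max_steps=0)])
    def test_rejects_bad_integrator_settings(self, uncharged, kwargs):
        with pytest.raises(ValueError):
            sk.BDSystemSpec(physics=uncharged, **kwargs)


class TestRngStreams:
    def test_streams_are_reproducible_and_distinct(self):
        a1 = trajectory_rng(7, 3).standard_normal(8)
        a2 = trajectory_rng(7, 3).standard_normal(8)
        b = trajectory_rng(7, 4).standard_normal(8)
        c = trajectory_rng(8, 3).standard_normal(8)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, b)
        assert not np.array_equal(a1, c)

    def test_uniform_sphere_radius_and_isotropy(self, rng):
        pts = uniform_sphere_points(4000, 9.0, rng)
        assert np.linalg.norm(pts, axis=1) == pytest.approx(np.full(4000, 9.0))
        # each Cartesian coordinate of a uniform point has mean 0 and
        # variance r^2/3
        se = 9.0 / math.sqrt(3 * 4000)
        assert np.abs(pts.mean(axis=0)).max() < 4 * se * math.sqrt(4000) / math.sqrt(4000) + 4 * se
        assert pts.var(axis=0) == pytest.approx(np.full(3, 27.0), rel=0.15)


class TestSingleStep:
    def test_uncharged_step_is_pure_noise(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, dt=0.01, seed=5)
        start = sk.PhasePoint(position=np.array([8.0, 0.0, 0.0]))
        rng1 = trajectory_rng(5, 0)
        moved = propagate_step(start, spec, rng1)
        expected = start.position + spec.sigma * trajectory_rng(5, 0).standard_normal(3)
        assert moved.position == pytest.approx(expected)
        assert moved.elapsed == pytest.approx(spec.dt)

    def test_attractive_drift_points_inward(self, charged):
        # with Q_c Q_s < 0 the deterministic part of the step reduces r
        spec = sk.BDSystemSpec(physics=charged, dt=0.01, seed=5)
        pos = np.array([8.0, 0.0, 0.0])

        class _ZeroRng:
            def standard_normal(self, size):
                return np.zeros(size)

        moved = propagate_step(sk.PhasePoint(position=pos), spec, _ZeroRng())
        assert np.linalg.norm(moved.position) < 8.0
        rc = charged.onsager_length
        drift = charged.D * spec.dt * rc / 8.0**2
        assert moved.position[0] == pytest.approx(8.0 + drift)


class TestDetectCrossings:
    def test_interpolated_time(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, dt=0.01)
        prev = sk.PhasePoint(position=np.array([7.9, 0, 0.0]), elapsed=1.0)
        nxt = sk.PhasePoint(position=np.array([8.1, 0, 0.0]), elapsed=1.01)
        hits = detect_crossings(prev, nxt, spec)
        assert hits == [(2, pytest.approx(1.0 + 0.5 * spec.dt))]

    def test_no_crossing(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, dt=0.01)
        prev = sk.PhasePoint(position=np.array([8.2, 0, 0.0]), elapsed=0.0)
        nxt = sk.PhasePoint(position=np.array([8.6, 0, 0.0]), elapsed=0.01)
        assert detect_crossings(prev, nxt, spec) == []

    def test_multi_skip_raises(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, dt=0.01)
        prev = sk.PhasePoint(position=np.array([6.5, 0, 0.0]), elapsed=0.0)
        nxt = sk.PhasePoint(position=np.array([9.5, 0, 0.0]), elapsed=0.01)
        with pytest.raises(RuntimeError, match="skipped"):
            detect_crossings(prev, nxt, spec)


class TestBatchEngine:
    def test_batch_composition_invariance(self, uncharged):
        # a trajectory's outcome must not depend on which batch it runs in
        spec = sk.BDSystemSpec(physics=uncharged, seed=11)
        ids = np.arange(6)
        starts = np.empty((6, 3))
        for j in range(6):
            starts[j] = uniform_sphere_points(1, 8.5, trajectory_rng(99, j))[0]
        stops = np.array([6.0, 11.0])
        full = _propagate_batch(spec, ids, starts, stops)
        solo = [_propagate_batch(spec, ids[j:j + 1], starts[j:j + 1], stops)
                for j in range(6)]
        for j, s in enumerate(solo):
            assert s.stop_radius_idx[0] == full.stop_radius_idx[j]
            assert s.time[0] == pytest.approx(full.time[j])
            assert s.position[0] == pytest.approx(full.position[j])

    def test_endpoints_on_stop_spheres(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, seed=3)
        ids = np.arange(64)
        starts = np.empty((64, 3))
        for j in range(64):
            starts[j] = uniform_sphere_points(1, 8.0, trajectory_rng(3, j))[0]
        res = _propagate_batch(spec, ids, starts, np.array([7.0, 9.0]),
                               rngs=[trajectory_rng(3, j) for j in range(64)])
        assert not res.censored.any()
        r_end = np.linalg.norm(res.position, axis=1)
        want = np.where(res.stop_radius_idx == 0, 7.0, 9.0)
        assert r_end == pytest.approx(want, abs=1e-9)
        assert (res.time > 0).all()

    def test_start_on_stop_radius_is_nudged(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, seed=4)
        starts = np.array([[9.0, 0.0, 0.0]])
        res = _propagate_batch(spec, np.array([0]), starts, np.array([7.0, 9.0]))
        assert not res.censored[0]
        assert res.stop_radius_idx[0] in (0, 1)

    def test_censoring_flagged(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, seed=4, max_steps=3)
        starts = np.array([[8.0, 0.0, 0.0]])
        res = _propagate_batch(spec, np.array([0]), starts, np.array([6.0, 11.0]))
        assert res.censored[0]
        assert np.isnan(res.time[0])


class TestBruteForce:
    def test_committor_recovery_uncharged(self, uncharged):
        # start from 9 A between absorbers at 8 and 10 A; the analytic
        # committor gives the hit probability, checked at 3 binomial SE
        net = sk.concentric_network([8.0, 9.0, 10.0], bound=8.0, escape=10.0,
                                    b_radius=9.0)
        spec = sk.BDSystemSpec(physics=uncharged, network=net, seed=17)
        res = run_brute_force(spec, 3000)
        expect = sk.splitting_probability(8.0, 9.0, 10.0, uncharged)
        assert abs(res.beta - expect) < 3 * res.se_beta
        expect_tau = sk.mfpt_theory(8.0, 9.0, 10.0, uncharged)
        assert abs(res.mfpt - expect_tau) < max(3 * res.se_mfpt, 0.02 * expect_tau)

    def test_committor_recovery_charged(self, charged):
        net = sk.concentric_network([8.0, 9.0, 10.0], bound=8.0, escape=10.0,
                                    b_radius=9.0)
        spec = sk.BDSystemSpec(physics=charged, network=net, seed=23)
        res = run_brute_force(spec, 3000)
        expect = sk.splitting_probability(8.0, 9.0, 10.0, charged)
        assert abs(res.beta - expect) < 3 * res.se_beta

    def test_dt_halving_statistical_equality(self, uncharged):
        # discretisation check: halving dt must not shift beta or the MFPT
        # by more than the combined 3-sigma Monte Carlo error
        net = sk.concentric_network([8.0, 9.0, 10.0], bound=8.0, escape=10.0,
                                    b_radius=9.0)
        coarse = sk.BDSystemSpec(physics=uncharged, network=net, seed=31, dt=0.01)
        fine = sk.BDSystemSpec(physics=uncharged, network=net, seed=37, dt=0.005)
        r1 = run_brute_force(coarse, 2500)
        r2 = run_brute_force(fine, 2500)
        assert abs(r1.beta - r2.beta) < 3 * math.hypot(r1.se_beta, r2.se_beta)
        assert abs(r1.mfpt - r2.mfpt) < 3 * math.hypot(r1.se_mfpt, r2.se_mfpt)

    def test_invalid_start_radius(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, seed=1)
        with pytest.raises(ValueError, match="start radius"):
            run_brute_force(spec, 10, start_radius=11.0)


class TestFhpd:
    def test_schema_and_radius(self, uncharged_dataset):
        spec, fhpd, _, _ = uncharged_dataset
        for m, df in fhpd.items():
            assert list(df.columns) == ["x", "y", "z", "time_ps", "side"]
            r = np.linalg.norm(df[["x", "y", "z"]].to_numpy(), axis=1)
            assert r == pytest.approx(np.full(len(df), spec.network.radii[m]),
                                      abs=1e-9)
            assert (df["time_ps"] > 0).all()
            assert set(df["side"]) <= {"inner", "outer"}

    def test_isotropy_of_hitting_points(self, uncharged_dataset):
        # for a central potential the FHPD must be uniform on the sphere:
        # each direction cosine is Uniform(-1, 1)
        _, fhpd, _, _ = uncharged_dataset
        pts = fhpd[2][["x", "y", "z"]].to_numpy()
        cosines = pts[:, 2] / np.linalg.norm(pts, axis=1)
        assert sps.kstest(cosines, "uniform", args=(-1.0, 2.0)).pvalue > 1e-3

    def test_side_split_matches_committor(self, uncharged):
        # of launch-fair arrivals on milestone 8 A, the fraction arriving
        # from inside equals p_in / (p_in + p_out) of the two committor
        # success probabilities for launches at 7 A and 9 A
        spec = sk.BDSystemSpec(physics=uncharged, seed=41)
        df = sk.sample_fhpd(spec, 2, 1200)
        p_in = 1.0 - sk.splitting_probability(6.0, 7.0, 8.0, uncharged)
        p_out = sk.splitting_probability(8.0, 9.0, 11.0, uncharged)
        expect = p_in / (p_in + p_out)
        frac = (df["side"] == "inner").mean()
        se = math.sqrt(expect * (1 - expect) / len(df))
        assert abs(frac - expect) < 4 * se

    def test_sink_milestone_has_no_feed(self, uncharged):
        # in a 3-sphere network the lone intermediate sits between two
        # sinks, so no surface can feed its FHPD
        net = sk.concentric_network([6.0, 7.0, 8.0], bound=6.0, escape=8.0)
        spec = sk.BDSystemSpec(physics=uncharged, network=net, seed=1)
        with pytest.raises(ValueError, match="non-sink neighbour"):
            sk.sample_fhpd(spec, 1, 10)


class TestMilestoningTrajectories:
    def test_event_stream_wellformed(self, uncharged_dataset):
        spec, _, stats, events = uncharged_dataset
        net = spec.network
        assert list(events.columns) == list(EVENT_COLUMNS)
        src = events["src_milestone"].to_numpy()
        dst = events["dst_milestone"].to_numpy()
        assert np.isin(src, [1, 2, 3, 4]).all()  # non-sink sources only
        assert (np.abs(src - dst) == 1).all()    # nearest neighbours only
        assert (events["transit_time_ps"] > 0).all()
        # statistics object agrees with the raw stream
        rebuilt = sk.TransitionStatistics.from_events(
            net.n, src, dst, events["transit_time_ps"].to_numpy())
        assert np.array_equal(rebuilt.counts, stats.counts)
        assert rebuilt.incubation_total == pytest.approx(stats.incubation_total)

    def test_kernel_rows_match_committor(self, uncharged_dataset, uncharged):
        spec, _, stats, _ = uncharged_dataset
        net = spec.network
        kernel = sk.estimate_kernel(stats, net)
        radii = net.radii
        for i in range(1, net.n - 1):
            p_in = sk.splitting_probability(radii[i - 1], radii[i],
                                            radii[i + 1], uncharged)
            n_i = stats.row_totals[i]
            se = math.sqrt(p_in * (1 - p_in) / n_i)
            assert abs(kernel.K[i, i - 1] - p_in) < 4 * se

    def test_incubation_times_match_continuum(self, uncharged_dataset, uncharged):
        spec, _, stats, _ = uncharged_dataset
        net = spec.network
        kernel = sk.estimate_kernel(stats, net)
        radii = net.radii
        for i in range(1, net.n - 1):
            expect = sk.mfpt_theory(radii[i - 1], radii[i], radii[i + 1],
                                    uncharged)
            assert kernel.t[i] == pytest.approx(expect, rel=0.15)

    def test_charged_dataset_is_biased_inward(self, charged_dataset, charged):
        # attraction raises every inward transition probability relative to
        # the committor expectation of the free system
        spec, _, stats, _ = charged_dataset
        net = spec.network
        kernel = sk.estimate_kernel(stats, net)
        radii = net.radii
        for i in range(1, net.n - 1):
            p_free = sk.splitting_probability(radii[i - 1], radii[i],
                                              radii[i + 1],
                                              sk.uncharged_reference())
            p_chg = sk.splitting_probability(radii[i - 1], radii[i],
                                             radii[i + 1], charged)
            assert p_chg > p_free
            n_i = stats.row_totals[i]
            se = math.sqrt(p_chg * (1 - p_chg) / n_i)
            assert abs(kernel.K[i, i - 1] - p_chg) < 4 * se

    def test_missing_fhpd_rejected(self, uncharged):
        spec = sk.BDSystemSpec(physics=uncharged, seed=1)
        with pytest.raises((KeyError, ValueError)):
            sk.run_milestoning_trajectories(
                spec, {1: np.empty((0, 3))}, 10)


class TestEquilibrium:
    def test_boltzmann_radial_marginal(self, charged):
        # long reflecting-boundary run: mean radius matches the Boltzmann
        # average of r over r^2 exp(-rc/r) on [7, 10]
        spec = sk.BDSystemSpec(physics=charged, seed=53)
        radii = run_equilibrium_radii(spec, 200_000, 7.0, 10.0)
        assert radii.min() >= 7.0 - 1e-9 and radii.max() <= 10.0 + 1e-9
        from scipy.integrate import quad
        rc = charged.onsager_length
        w = lambda r: r * r * math.exp(-rc / r)  # noqa: E731
        Z, _ = quad(w, 7.0, 10.0)
        mean_r, _ = quad(lambda r: r * w(r), 7.0, 10.0)
        assert radii.mean() == pytest.approx(mean_r / Z, rel=0.01)
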