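from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from reacharc import (
    DurationModel,
    EndpointModel,
    ProtocolConfig,
    ReacherParams,
    build_schedule,
    default_reacher,
    default_surface,
    exp1_population,
    minimum_jerk,
    sample_endpoint,
    sample_target,
    simulate_cohort,
    simulate_session,
    simulate_trial,
    Vec3,
)
from reacharc.simulate import RAYLEIGH_MEAN_FACTOR, draw_reacher


def _reacher(vis_sd=0.0, inv_sd=0.0, vis_bias=(0.0, 0.0), **kw) -> ReacherParams:
    return ReacherParams(
        endpoint={
            "visible": EndpointModel(
                azimuth_bias=vis_bias[0],
                elevation_bias=vis_bias[1],
                azimuth_sd=vis_sd,
                elevation_sd=vis_sd,
            ),
            "invisible": EndpointModel(azimuth_sd=inv_sd, elevation_sd=inv_sd),
        },
        **kw,
    )


class TestBuildSchedule:
    def test_balanced_counts(self):
        sched = build_schedule(ProtocolConfig(rng_seed=0))
        assert len(sched) == 200
        assert sched.count("visible") == 100
        assert sched.count("invisible") == 100

    def test_seed_reproducibility(self):
        a = build_schedule(ProtocolConfig(rng_seed=5))
        b = build_schedule(ProtocolConfig(rng_seed=5))
        c = build_schedule(ProtocolConfig(rng_seed=6))
        assert a == b
        assert a != c  # 200!/(100!100!) orderings; collision essentially impossible

    def test_n1_both_orders_occur_evenly(self):
        firsts = [
            build_schedule(ProtocolConfig(n_trials_per_condition=1, rng_seed=s))[0]
            for s in range(400)
        ]
        frac = firsts.count("visible") / 400
        assert 0.4 < frac < 0.6  # binomial(400, .5): 3 SE ~ 0.075


class TestSampleEndpoint:
    def test_noiseless_hits_target(self, surface, rng):
        t = sample_target(surface, 0.0, rng)
        model = EndpointModel()
        az, el, p = sample_endpoint(t, model, rng, surface)
        assert az == pytest.approx(t.azimuth)
        assert el == pytest.approx(t.elevation)
        assert p == t.cartesian

    def test_pure_bias_gives_exact_error(self, surface, rng):
        from reacharc import Crossing, angular_error

        t = sample_target(surface, 0.0, rng)
        model = EndpointModel(azimuth_bias=3.0)
        az, el, p = sample_endpoint(t, model, rng, surface)
        err = angular_error(surface, t, Crossing(point=p, time_ms=1.0))
        assert err.total_deg == pytest.approx(3.0, abs=1e-9)

    def test_mean_error_matches_folded_normal_oracle(self, surface):
        # independent Monte-Carlo oracle for E[sqrt(X^2+Y^2)], X,Y ~ N(0,2^2)
        oracle_rng = np.random.default_rng(99)
        xy = oracle_rng.normal(0.0, 2.0, size=(200_000, 2))
        oracle_mean = float(np.hypot(xy[:, 0], xy[:, 1]).mean())
        assert oracle_mean == pytest.approx(2.0 * RAYLEIGH_MEAN_FACTOR, rel=0.01)

        gen = np.random.default_rng(7)
        t = sample_target(surface, 0.0, gen)
        model = EndpointModel(azimuth_sd=2.0, elevation_sd=2.0)
        from reacharc.geometry import cone_angle_deg

        errs = []
        for _ in range(10_000):
            az, el, _ = sample_endpoint(t, model, gen, surface)
            errs.append(cone_angle_deg(t.azimuth, t.elevation, az, el))
        # MC SE ~ 2*sqrt(2-pi/2)/sqrt(1e4) ~ 0.013
        assert np.mean(errs) == pytest.approx(oracle_mean, abs=0.06)


class TestMinimumJerk:
    def test_midpoint_and_end_velocity(self):
        start, end = Vec3(0, 0, 0), Vec3(0.2, 0.1, 0.6)
        traj = minimum_jerk(start, end, duration_ms=500.0, frame_rate=1000.0)
        # midpoint of the path = 50% displacement at tau = 1/2
        i_mid = int(np.argmin(np.abs(traj.t_ms - 250.0)))
        frac = np.linalg.norm(traj.xyz[i_mid] - start.as_array()) / np.linalg.norm(
            end.as_array() - start.as_array()
        )
        assert frac == pytest.approx(0.5, abs=0.01)
        # finite-difference velocity ~ 0 at both ends
        v0 = np.linalg.norm(traj.xyz[1] - traj.xyz[0]) / 1.0
        v_end = np.linalg.norm(traj.xyz[-1] - traj.xyz[-2]) / 1.0
        v_peak = np.abs(np.diff(traj.xyz, axis=0)).max()
        assert v0 < 0.01 * v_peak
        assert v_end < 0.01 * v_peak

    def test_displacement_monotone(self):
        traj = minimum_jerk(Vec3(0, 0, 0), Vec3(0, 0, 0.7), 400.0, 72.0)
        z = traj.xyz[:, 2]
        assert np.all(np.diff(z) >= 0)


class TestSimulateTrial:
    def test_noiseless_error_within_interpolation_tolerance(self, surface, rng):
        t = sample_target(surface, 0.0, rng)
        rec, traj = simulate_trial(surface, t, _reacher(), "visible", rng)
        assert rec.valid
        assert traj is not None
        assert rec.error_deg < 0.05

    def test_fast_path_agrees_with_trajectory_path(self, surface):
        t = sample_target(surface, 0.0, np.random.default_rng(0))
        reacher = _reacher(vis_sd=2.0)
        rec_t, _ = simulate_trial(
            surface, t, reacher, "visible", np.random.default_rng(11)
        )
        rec_f, _ = simulate_trial(
            surface, t, reacher, "visible", np.random.default_rng(11),
            with_trajectory=False,
        )
        assert rec_f.error_deg == pytest.approx(rec_t.error_deg, abs=0.05)
        assert rec_f.reach_time_ms == pytest.approx(rec_t.reach_time_ms, rel=0.05)

    def test_duration_median_recovery(self, surface):
        gen = np.random.default_rng(21)
        t = sample_target(surface, 0.0, gen)
        reacher = _reacher(duration=DurationModel(median_ms=618.0, sigma=0.15),
                           lapse_rate=0.0)
        times = [
            simulate_trial(surface, t, reacher, "visible", gen, with_trajectory=False)[
                0
            ].reach_time_ms
            for _ in range(10_000)
        ]
        assert np.median(times) == pytest.approx(618.0, rel=0.02)

    def test_memory_delay_clock_includes_tone_delay(self, surface, rng):
        t = sample_target(surface, 0.0, rng)
        reacher = ReacherParams(
            endpoint={"standard": EndpointModel(), "delayed": EndpointModel()},
            duration=DurationModel(median_ms=600.0, sigma=0.0),
            lapse_rate=0.0,
        )
        rec, _ = simulate_trial(
            surface, t, reacher, "delayed", rng, clock_offset_ms=1200.0,
            with_trajectory=False,
        )
        assert rec.reach_time_ms == pytest.approx(1800.0)


class TestSimulateSession:
    def test_standard_structure(self):
        log = simulate_session(
            ProtocolConfig(rng_seed=1), default_surface(), default_reacher()
        )
        assert len(log.trials) == 210
        assert len(log.practice_trials) == 10
        assert len(log.experimental_trials) == 200
        log.validate()  # exact condition balance
        assert all(t.phase == "practice" for t in log.trials[:10])

    def test_practice_excluded_from_condition_trials(self):
        log = simulate_session(
            ProtocolConfig(rng_seed=2), default_surface(), default_reacher()
        )
        vis = log.condition_trials("visible")
        assert len(vis) == 100
        assert all(t.phase == "experimental" for t in vis)

    def test_condition_noise_ordering(self):
        # visible SD < invisible SD must show in session-level mean errors
        proto = ProtocolConfig(n_trials_per_condition=500, rng_seed=3)
        log = simulate_session(proto, default_surface(), _reacher(1.0, 3.0))
        mean = lambda c: np.mean([t.error_deg for t in log.condition_trials(c)])
        assert mean("visible") < mean("invisible")

    def test_seed_determinism_roundtrip(self, tmp_path):
        from reacharc.io import write_trial_log

        proto = ProtocolConfig(rng_seed=44)
        a = simulate_session(proto, default_surface(), default_reacher(), "P1")
        b = simulate_session(proto, default_surface(), default_reacher(), "P1")
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_trial_log(a, pa)
        write_trial_log(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_parameter_recovery_at_large_n(self):
        # pipeline mean error converges to the folded-noise expectation
        sd = 2.5
        proto = ProtocolConfig(n_trials_per_condition=5000, rng_seed=9)
        log = simulate_session(proto, default_surface(), _reacher(sd, sd))
        expected = sd * RAYLEIGH_MEAN_FACTOR
        got = np.mean([t.error_deg for t in log.condition_trials("visible")])
        assert got == pytest.approx(expected, rel=0.02)


class TestSimulateCohort:
    def test_single_participant(self):
        logs = simulate_cohort(1, ProtocolConfig(), exp1_population(), seed=0)
        assert len(logs) == 1
        logs[0].validate()

    def test_distinct_seeds_distinct_cohorts(self):
        a = simulate_cohort(2, ProtocolConfig(), exp1_population(), seed=1)
        b = simulate_cohort(2, ProtocolConfig(), exp1_population(), seed=2)
        ea = [t.error_deg for t in a[0].experimental_trials[:10]]
        eb = [t.error_deg for t in b[0].experimental_trials[:10]]
        assert ea != eb

    def test_draw_reacher_symmetric_clipping_keeps_population_mean(self):
        pop = exp1_population()
        gen = np.random.default_rng(5)
        sds = [
            draw_reacher(pop, gen).endpoint["visible"].azimuth_sd
            for _ in range(4000)
        ]
        target = pop.conditions["visible"].azimuth_sd_mean
        # clipped-normal draws are mean-exact; SE ~ sd/sqrt(4000) ~ 0.013
        assert np.mean(sds) == pytest.approx(target, abs=0.05)
        assert min(sds) > 0

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(0, ProtocolConfig(), exp1_population(), seed=0)
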