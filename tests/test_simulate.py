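"""Trajectory simulator, monitoring schedule, and reference cohort."""

import numpy as np
import pytest

from neutrokit import (
    ArmSpec,
    CONTROL_ARM,
    DenseTrajectory,
    REFERENCE_DSN_COUNTS,
    SimConfig,
    apply_monitoring_schedule,
    cohort_endpoints,
    default_trial_config,
    derive_dsn,
    simulate_cohort,
    simulate_dense_trajectory,
    trajectory_curve,
)
from neutrokit.simulate import TWICE_WEEKLY_GRID


class TestDenseTrajectory:
    def test_full_potency_cancels_suppression(self, rng):
        cfg = SimConfig(obs_noise_cv=0.0)
        traj = simulate_dense_trajectory(cfg, 1.0, rng, baseline=4.0)
        # with suppression gone the curve never drops below baseline
        assert traj.anc_by_day.min() >= 4.0

    @pytest.mark.parametrize("potency", [0.45, 0.63, 0.68, 0.88])
    def test_nadir_in_reported_window(self, potency):
        cfg = SimConfig(obs_noise_cv=0.0)
        curve = trajectory_curve(cfg, potency, 4.5)
        nadir_day = int(np.argmin(curve)) + 1
        assert 5 <= nadir_day <= 10

    def test_biphasic_shape_at_control_potency(self):
        # early Day-3 peak and Day 10-13 rebound both exceed baseline
        curve = trajectory_curve(SimConfig(), 0.63, 1.0)
        assert curve[2] > 1.0
        assert max(curve[9:13]) > 1.0
        assert curve.min() < 1.0

    def test_nadir_depth_monotone_in_potency(self):
        cfg = SimConfig(obs_noise_cv=0.0)
        depths = [trajectory_curve(cfg, p, 4.5).min() for p in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(depths, depths[1:]))

    def test_invalid_potency_rejected(self, rng):
        with pytest.raises(ValueError, match="dose_potency"):
            simulate_dense_trajectory(SimConfig(), 1.5, rng)

    def test_noise_preserves_nonnegativity(self, rng):
        cfg = SimConfig(obs_noise_cv=0.6)
        traj = simulate_dense_trajectory(cfg, 0.2, rng, baseline=4.0)
        assert np.all(traj.anc_by_day >= 0)
        assert len(traj) == cfg.cycle_length_days

    def test_kernel_day_ordering_enforced(self):
        with pytest.raises(ValueError, match="kernel days"):
            SimConfig(stim_day=8.0, suppression_day=7.0)


class TestMonitoringSchedule:
    def dense(self, values):
        return DenseTrajectory("p", 1, np.asarray(values, dtype=float))

    def test_never_triggered_gives_fixed_grid(self):
        s = apply_monitoring_schedule(self.dense([5.0] * 21))
        assert s.days == (1, 2, 3, *TWICE_WEEKLY_GRID)

    def test_trigger_at_day7_daily_until_recovery_day11(self):
        vals = [5.0] * 21
        for d in range(7, 11):
            vals[d - 1] = 1.0
        s = apply_monitoring_schedule(self.dense(vals))
        assert s.days == (1, 2, 3, 7, 8, 9, 10, 11, 14, 17, 21)

    def test_trigger_on_day3_goes_daily_immediately(self):
        vals = [5.0, 5.0] + [1.0] * 6 + [2.0] * 13  # below 1.5 on days 3-8
        s = apply_monitoring_schedule(self.dense(vals))
        assert s.days[:8] == (1, 2, 3, 4, 5, 6, 7, 8)
        assert s.days[8:] == (9, 10, 14, 17, 21)

    def test_observed_days_sorted_unique(self, rng):
        for _ in range(50):
            traj = simulate_dense_trajectory(SimConfig(), rng.uniform(0, 1), rng)
            days = apply_monitoring_schedule(traj).days
            assert list(days) == sorted(set(days))
            assert days[:3] == (1, 2, 3)

    def test_thinning_preserves_dsn_for_gradual_declines(self, rng):
        # monotone-ish curves that spend >=4 days in the daily-trigger band
        # [0.5, 1.5) before grade 4, then jump to >=2.0 at recovery: the
        # schedule observes the true onset and recovery days exactly
        for _ in range(200):
            start = rng.integers(4, 9)
            width = rng.integers(4, 6)
            severe = rng.integers(1, min(5, 21 - (start + width)) + 1)
            vals = np.empty(21)
            vals[: start - 1] = rng.uniform(1.5, 8.0, start - 1)
            vals[start - 1 : start - 1 + width] = np.sort(rng.uniform(0.5, 1.5, width))[::-1]
            s0 = start - 1 + width
            vals[s0 : s0 + severe] = rng.uniform(0.0, 0.5, severe)
            vals[s0 + severe :] = rng.uniform(2.0, 8.0, 21 - s0 - severe)
            dense = self.dense(vals)
            daily = AncSeriesFromDense(dense)
            thinned = apply_monitoring_schedule(dense)
            assert derive_dsn(thinned) == derive_dsn(daily)


def AncSeriesFromDense(dense):
    from neutrokit import AncSeries

    return AncSeries(dense.patient_id, dense.cycle, list(enumerate(dense.anc_by_day, start=1)))


class TestSimulateCohort:
    def test_same_seed_identical_cohorts(self):
        cfg = default_trial_config(seed=11)
        assert simulate_cohort(cfg) == simulate_cohort(cfg)

    def test_different_seed_differs(self):
        a = simulate_cohort(default_trial_config(seed=1))
        b = simulate_cohort(default_trial_config(seed=2))
        assert a != b

    def test_weight_cutpoints(self):
        cfg = SimConfig(arms=(ArmSpec("a", 0.5, 20),), weight_log_sd=1e-12,
                        weight_log_mean=np.log(70.0), seed=0)
        cohort = simulate_cohort(cfg)
        assert {p.stratum for p in cohort} == {"65-75"}

    def test_mean_dsn_strictly_decreasing_in_potency(self):
        cfg = SimConfig(
            arms=(ArmSpec("lo", 0.1, 200), ArmSpec("mid", 0.5, 200), ArmSpec("hi", 0.9, 200)),
            seed=7,
        )
        by_arm = cohort_endpoints(simulate_cohort(cfg), 1)
        means = [np.mean([r.dsn_days for r in by_arm[a]]) for a in ("lo", "mid", "hi")]
        assert means[0] > means[1] > means[2]
        depths = [np.mean([r.nadir_depth for r in by_arm[a]]) for a in ("lo", "mid", "hi")]
        assert depths[0] < depths[1] < depths[2]

    def test_bad_arm_sizes_rejected(self):
        with pytest.raises(ValueError, match="n_patients"):
            SimConfig(arms=(ArmSpec("a", 0.5, 0),))

    def test_cycles_per_patient(self):
        cfg = SimConfig(arms=(ArmSpec("a", 0.5, 3),), n_cycles=3, seed=0)
        cohort = simulate_cohort(cfg)
        assert all(len(p.cycles) == 3 for p in cohort)
        assert all([s.cycle for s in p.cycles] == [1, 2, 3] for p in cohort)


class TestReferenceCohort:
    def test_arm_sizes(self, reference_cohort):
        sizes = {}
        for p in reference_cohort:
            sizes[p.arm] = sizes.get(p.arm, 0) + 1
        assert sizes == {
            "eflapegrastim_45": 39,
            "eflapegrastim_135": 36,
            "eflapegrastim_270": 36,
            CONTROL_ARM: 36,
        }

    def test_dsn_multisets_round_trip(self, reference_cohort):
        by_arm = cohort_endpoints(reference_cohort, 1)
        for arm, expected in REFERENCE_DSN_COUNTS.items():
            derived = {}
            for r in by_arm[arm]:
                derived[r.dsn_days] = derived.get(r.dsn_days, 0) + 1
            assert derived == expected

    def test_series_are_schedule_consistent(self, reference_cohort):
        # each stored series equals itself re-thinned through the schedule,
        # i.e. the observation days follow the protocol's sampling rules
        for p in reference_cohort:
            s = p.cycles[0]
            dense_vals = np.full(21, 5.0)
            for d, a in s.observations:
                dense_vals[d - 1] = a
            rethinned = apply_monitoring_schedule(DenseTrajectory(p.patient_id, 1, dense_vals))
            assert rethinned.days == s.days

    def test_deterministic(self):
        from neutrokit import generate_reference_cohort

        assert generate_reference_cohort() == generate_reference_cohort()
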