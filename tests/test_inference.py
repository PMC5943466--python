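"""Stratified bootstrap comparison: CIs, P-values, determinism."""

import numpy as np
import pytest

from neutrokit import (
    BootstrapSpec,
    CONTROL_ARM,
    compare_arms,
    compare_dsn_samples,
    noninferiority_pvalue,
    percentile_ci,
    stratified_resample_diffs,
    superiority_pvalue,
)


def plain_bootstrap_diffs(exp, ctrl, n, rng):
    """Independently coded unstratified bootstrap of the mean difference."""
    exp = np.asarray(exp, float)
    ctrl = np.asarray(ctrl, float)
    out = np.empty(n)
    for i in range(n):
        out[i] = rng.choice(exp, exp.size).mean() - rng.choice(ctrl, ctrl.size).mean()
    return out


class TestPercentileCi:
    def test_linear_interpolation_quantiles(self):
        diffs = np.arange(1, 101, dtype=float)
        assert percentile_ci(diffs, 0.90) == pytest.approx((5.95, 95.05))

    def test_degenerate_constant(self):
        assert percentile_ci([2.0] * 50, 0.95) == (2.0, 2.0)

    def test_level_to_zero_shrinks_to_median(self):
        diffs = np.arange(1, 102, dtype=float)
        lo, hi = percentile_ci(diffs, 1e-9)
        assert lo == pytest.approx(np.median(diffs), abs=1e-6)
        assert hi == pytest.approx(np.median(diffs), abs=1e-6)


class TestPvalues:
    def test_noninferiority_counts_exceedances(self):
        assert noninferiority_pvalue([0.5, 1.2, 0.8, 1.5], 1.0) == 1.0
        assert noninferiority_pvalue([0.5, 0.7], 1.0) == 0.0

    def test_ties_with_margin_do_not_exceed(self):
        assert noninferiority_pvalue([1.0, 1.0, 0.5, 1.5], 1.0) == pytest.approx(0.5)

    def test_cap_at_one(self):
        assert noninferiority_pvalue([2.0, 3.0, 4.0], 1.0) == 1.0
        assert superiority_pvalue([1.0, 2.0, 3.0]) == 1.0

    def test_superiority_counts_positives(self):
        assert superiority_pvalue([-0.3, -0.1, 0.2, -0.4]) == pytest.approx(0.5)
        assert superiority_pvalue([-1.0, -2.0]) == 0.0
        assert superiority_pvalue([0.0, -1.0, 1.0, 2.0]) == 1.0  # zero not counted

    def test_symmetric_diffs_give_pvalue_near_one(self, rng):
        diffs = rng.normal(0, 1, 10_000)
        assert superiority_pvalue(diffs) > 0.9


class TestStratifiedResampling:
    def test_degenerate_all_zero_arms(self):
        exp = [(0.0, "a")] * 10
        ctrl = [(0.0, "a")] * 10
        res = compare_dsn_samples(exp, ctrl, BootstrapSpec(n_resamples=500, seed=1))
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert res.p_noninferiority == 0.0 and res.p_superiority == 0.0
        assert res.noninferior

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            stratified_resample_diffs([], [(1.0, "a")], BootstrapSpec(n_resamples=10))

    def test_seed_determinism(self):
        exp = [(float(k), s) for k, s in zip(range(8), "aabbccdd")]
        ctrl = [(float(k), s) for k, s in zip(range(6), "aabbcc")]
        spec = BootstrapSpec(n_resamples=2_000, seed=42)
        d1 = stratified_resample_diffs(exp, ctrl, spec)
        d2 = stratified_resample_diffs(exp, ctrl, spec)
        np.testing.assert_array_equal(d1, d2)

    def test_single_stratum_matches_plain_bootstrap(self, rng):
        exp_vals = [0.0] * 25 + [1.0, 2.0, 2.0, 3.0, 5.0]
        ctrl_vals = [0.0] * 20 + [1.0, 1.0, 3.0]
        exp = [(v, "all") for v in exp_vals]
        ctrl = [(v, "all") for v in ctrl_vals]
        ours = stratified_resample_diffs(exp, ctrl, BootstrapSpec(n_resamples=10_000, seed=5))
        plain = plain_bootstrap_diffs(exp_vals, ctrl_vals, 10_000, rng)
        assert ours.mean() == pytest.approx(plain.mean(), abs=0.02)
        assert np.quantile(ours, 0.025) == pytest.approx(np.quantile(plain, 0.025), abs=0.04)
        assert np.quantile(ours, 0.975) == pytest.approx(np.quantile(plain, 0.975), abs=0.04)

    def test_stratification_preserves_stratum_sizes(self):
        # a stratum whose members all share one value contributes zero
        # resampling variance: with every stratum constant the diff is exact
        exp = [(2.0, "a")] * 4 + [(4.0, "b")] * 4
        ctrl = [(1.0, "a")] * 4 + [(3.0, "b")] * 4
        diffs = stratified_resample_diffs(exp, ctrl, BootstrapSpec(n_resamples=200, seed=0))
        np.testing.assert_allclose(diffs, 1.0)


class TestCompareArms:
    def test_point_estimates_match_published_differences(self, reference_cohort):
        spec = BootstrapSpec(n_resamples=200, seed=0)
        expected = {
            "eflapegrastim_45": 0.72,
            "eflapegrastim_135": 0.14,
            "eflapegrastim_270": -0.28,
        }
        for arm, diff in expected.items():
            res = compare_arms(reference_cohort, arm, CONTROL_ARM, 1, spec)
            assert res.point_diff == pytest.approx(diff, abs=0.005)

    def test_self_comparison_is_noninferior(self, reference_cohort):
        spec = BootstrapSpec(n_resamples=2_000, seed=3)
        res = compare_arms(reference_cohort, CONTROL_ARM, CONTROL_ARM, 1, spec)
        assert res.point_diff == 0.0
        assert res.noninferior

    def test_point_diff_inside_ci(self, reference_cohort):
        for seed in (0, 1, 2):
            spec = BootstrapSpec(n_resamples=1_000, seed=seed)
            res = compare_arms(reference_cohort, "eflapegrastim_45", CONTROL_ARM, 1, spec)
            assert res.ci_low <= res.point_diff <= res.ci_high

    def test_ci_converged_at_10k_resamples(self, reference_cohort):
        results = [
            compare_arms(
                reference_cohort, "eflapegrastim_45", CONTROL_ARM, 1,
                BootstrapSpec(n_resamples=10_000, seed=seed),
            )
            for seed in (101, 202)
        ]
        assert abs(results[0].ci_low - results[1].ci_low) < 0.05
        assert abs(results[0].ci_high - results[1].ci_high) < 0.05

    def test_unknown_arm_label_rejected(self, reference_cohort):
        with pytest.raises(KeyError):
            compare_arms(reference_cohort, "nope", CONTROL_ARM, 1)

    def test_decision_flag_is_ci_upper_below_margin(self, reference_cohort):
        spec = BootstrapSpec(n_resamples=1_000, seed=9)
        res = compare_arms(reference_cohort, "eflapegrastim_135", CONTROL_ARM, 1, spec)
        assert res.noninferior == (res.ci_high < spec.margin_days)
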