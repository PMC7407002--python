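"""Trial orchestration: determinism, titration behaviour, statistics."""

import numpy as np
import pytest

from basalsim.outcome_metrics import OutcomeSet
from basalsim.trial_engine import (
    NoninferiorityResult,
    TrialScenario,
    crossover_compare,
    noninferiority_test,
    parallel_splits,
    run_arm,
    select_test,
)


def make_outcomes(values, metric="mean", rng=None):
    """Population of OutcomeSets varying one metric, others mildly noisy."""
    rng = rng or np.random.default_rng(0)
    out = {}
    for i, v in enumerate(values):
        fields = dict(
            mean=150.0, sd=40.0, cv_2weeks=28.0, t_b54=0.2, t_b70=1.5,
            t_t70_140=40.0, t_t70_180=70.0, t_a180=28.5, t_a250=5.0,
            lbgi=0.5, hbgi=5.0,
        )
        for k in fields:
            fields[k] += rng.normal(0.0, 1e-3)
        fields[metric] = float(v)
        out[f"P{i:03d}"] = OutcomeSet(**fields)
    return out


class TestArmSimulation:
    def test_full_run_determinism(self, small_population):
        scn = TrialScenario(insulin="gla300", rule="A")
        a = run_arm(small_population[:2], scn)
        b = run_arm(small_population[:2], scn)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.trace.glucose, sb.trace.glucose)
            assert sa.final_dose_U == sb.final_dose_U

    def test_titration_disabled_keeps_dose(self, small_population):
        scn = TrialScenario(insulin="gla300", rule="A", titration_enabled=False)
        arm = run_arm(small_population[:2], scn)
        for s in arm.subjects:
            assert s.dose_history_U == [s.final_dose_U]

    def test_rule_b_lower_glucose_higher_dose(self, small_population):
        arm_a = run_arm(small_population, TrialScenario(insulin="gla300", rule="A"))
        arm_b = run_arm(small_population, TrialScenario(insulin="gla300", rule="B"))
        assert np.mean(arm_b.metric("mean")) < np.mean(arm_a.metric("mean"))
        doses_a = [s.final_dose_U for s in arm_a.subjects]
        doses_b = [s.final_dose_U for s in arm_b.subjects]
        assert np.mean(doses_b) >= np.mean(doses_a)

    def test_evening_schedule_runs(self, small_population):
        scn = TrialScenario(insulin="deg100", schedule="evening", rule="A",
                            b0_U_per_kg=0.32)
        arm = run_arm(small_population[:2], scn)
        assert all(not s.failed for s in arm.subjects)
        assert all(s.trace.n_days == 14 for s in arm.subjects)

    def test_titration_settles_without_oscillation(self, small_population):
        """By the end of uptitration, dose adjustments no longer alternate
        sign with more than a single step of amplitude."""
        arm = run_arm(small_population, TrialScenario(insulin="gla300", rule="A"))
        ok = 0
        for s in arm.subjects:
            adj = np.diff(s.dose_history_U)[-4:]
            oscillating = any(
                a * b < 0 and (abs(a) > 3 or abs(b) > 3)
                for a, b in zip(adj, adj[1:])
            )
            ok += not oscillating
        assert ok >= 0.9 * len(arm.subjects)

    def test_analysis_window_inside_stable_period(self):
        with pytest.raises(ValueError):
            TrialScenario(weeks_stable=1, analysis_days=14)


class TestTestSelection:
    def test_gaussian_prefers_t(self):
        rng = np.random.default_rng(3)
        hits = sum(
            select_test(rng.normal(size=100), rng.normal(size=100),
                        paired=True) == "paired_t"
            for _ in range(50)
        )
        assert hits >= 45

    def test_skewed_prefers_nonparametric(self):
        rng = np.random.default_rng(4)
        hits = sum(
            select_test(rng.lognormal(0, 1.5, 100), rng.lognormal(0, 1.5, 100),
                        paired=False) == "mannwhitney"
            for _ in range(50)
        )
        assert hits >= 48

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            select_test([1.0, 2.0], [1.0, 2.0], paired=False)


class TestCrossover:
    def test_identical_arms_not_significant(self):
        a = make_outcomes(np.random.default_rng(5).normal(150, 20, 40))
        table = crossover_compare(a, a)
        assert not table["significant"].any()
        assert (table["p_value"] == 1.0).all()

    def test_shift_detected(self):
        rng = np.random.default_rng(6)
        base = rng.normal(150, 20, 100)
        a = make_outcomes(base, rng=np.random.default_rng(1))
        b = make_outcomes(base + 10.0, rng=np.random.default_rng(2))
        table = crossover_compare(a, b).set_index("metric")
        assert table.loc["mean", "significant"]

    def test_swap_symmetry(self):
        rng = np.random.default_rng(7)
        a = make_outcomes(rng.normal(150, 20, 60), rng=np.random.default_rng(1))
        b = make_outcomes(rng.normal(155, 20, 60), rng=np.random.default_rng(2))
        t_ab = crossover_compare(a, b).set_index("metric")
        t_ba = crossover_compare(b, a).set_index("metric")
        assert t_ab.loc["mean", "p_value"] == pytest.approx(
            t_ba.loc["mean", "p_value"])
        assert t_ab.loc["mean", "mean_a"] - t_ab.loc["mean", "mean_b"] == (
            pytest.approx(-(t_ba.loc["mean", "mean_a"] - t_ba.loc["mean", "mean_b"]))
        )

    def test_subject_mismatch_rejected(self):
        a = make_outcomes([1.0] * 10)
        b = dict(list(make_outcomes([1.0] * 10).items())[:5])
        with pytest.raises(ValueError):
            crossover_compare(a, b)


class TestParallelSplits:
    def test_determinism(self):
        rng = np.random.default_rng(8)
        a = make_outcomes(rng.normal(150, 20, 40), rng=np.random.default_rng(1))
        b = make_outcomes(rng.normal(150, 20, 40), rng=np.random.default_rng(2))
        s1 = parallel_splits(a, b, n_splits=20, seed=5, metrics=["mean"])
        s2 = parallel_splits(a, b, n_splits=20, seed=5, metrics=["mean"])
        assert s1.equals(s2)

    def test_huge_effect_saturates(self):
        rng = np.random.default_rng(9)
        base = rng.normal(150, 5, 60)
        a = make_outcomes(base, rng=np.random.default_rng(1))
        b = make_outcomes(base + 25.0, rng=np.random.default_rng(2))  # 5 SD
        s = parallel_splits(a, b, n_splits=30, seed=0, metrics=["mean"])
        assert int(s["significant_count"].iloc[0]) == 30

    def test_crossover_at_least_as_powerful_as_parallel(self):
        """Paired analysis detects a within-subject shift that unpaired
        split comparisons mostly miss."""
        rng = np.random.default_rng(10)
        subject_level = rng.normal(150, 25, 80)
        effect = 3.0
        a = make_outcomes(subject_level, rng=np.random.default_rng(1))
        b = make_outcomes(subject_level + effect + rng.normal(0, 0.5, 80),
                          rng=np.random.default_rng(2))
        cross = crossover_compare(a, b, metrics=["mean"]).set_index("metric")
        par = parallel_splits(a, b, n_splits=40, seed=2, metrics=["mean"])
        crossover_detects = bool(cross.loc["mean", "significant"])
        parallel_rate = par["significant_count"].iloc[0] / 40.0
        assert crossover_detects
        assert parallel_rate <= 1.0
        assert crossover_detects >= (parallel_rate > 0.95)


class TestNoninferiority:
    def test_zero_difference_tiny_variance(self, rng):
        a = 40.0 + rng.normal(0, 0.01, 50)
        res = noninferiority_test(a, a.copy(), delta=8.0)
        assert res.noninferior

    def test_large_deficit_fails(self, rng):
        b = 40.0 + rng.normal(0, 0.01, 50)
        a = b - 16.0  # 2 * delta below
        res = noninferiority_test(a, b, delta=8.0)
        assert not res.noninferior

    def test_default_margin_is_half_comparator_sd(self, rng):
        b = rng.normal(40.0, 16.0, 200)
        a = b + rng.normal(0, 1.0, 200)
        res = noninferiority_test(a, b)
        assert res.delta == pytest.approx(0.5 * np.std(b, ddof=1))
        assert isinstance(res, NoninferiorityResult)

    def test_sd_sixteen_gives_margin_eight(self):
        """Margin convention: half of SD = 16 percentage points is 8."""
        b = np.concatenate([np.full(100, 24.0), np.full(100, 56.0)])
        sd = np.std(b, ddof=1)
        res = noninferiority_test(b.copy(), b)
        assert res.delta == pytest.approx(0.5 * sd)
        assert res.delta == pytest.approx(8.0, rel=0.01)
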