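import numpy as np
import pytest
from scipy import stats

from pulseaf import (ConfusionTable, evaluate_study, irregularity_index,
                     mcnemar_test, measurement_period, pearson_chi2_2x2,
                     sensitivity, specificity, simulate_afib, wilson_ci)
from pulseaf.evaluation import format_percent
from pulseaf.series import PulseIntervalSeries
from pulseaf.studydata import DEVICE_COUNTS, SUBGROUP_TABLES


class TestSensitivitySpecificity:
    def test_published_device_accuracies(self):
        fm = DEVICE_COUNTS["FM31"]
        fl = DEVICE_COUNTS["FL31"]
        assert sensitivity(fm) == pytest.approx(0.9747, abs=5e-5)
        assert format_percent(sensitivity(fm)) == "97.5"
        assert format_percent(specificity(fm)) == "98.9"
        assert format_percent(sensitivity(fl)) == "93.7"
        assert format_percent(specificity(fl)) == "100"

    def test_boundary_cases(self):
        assert sensitivity(ConfusionTable(tp=5, fn=0)) == 1.0
        assert specificity(ConfusionTable(tn=0, fp=1)) == 0.0

    def test_zero_denominators(self):
        with pytest.raises(ValueError):
            sensitivity(ConfusionTable(tn=3, fp=1))
        with pytest.raises(ValueError):
            specificity(ConfusionTable(tp=3, fn=1))


class TestWilson:
    # published validation CIs (percent, 1 decimal). The age<65 specificity
    # cell (34/34) prints its lower bound as 90.0 in the source table; the
    # Wilson value is 89.8 (no standard interval yields 90.0 at 1 decimal).
    CASES = [
        (77, 79, 91.2, 99.3), (91, 92, 94.1, 99.8),
        (74, 79, 86.0, 97.3), (92, 92, 96.0, 100.0),
        (15, 15, 79.6, 100.0), (62, 64, 89.3, 99.1),
        (34, 34, 89.8, 100.0), (57, 58, 90.9, 99.7),
        (30, 31, 83.8, 99.4), (47, 48, 89.1, 99.6),
        (42, 42, 91.6, 100.0), (49, 50, 89.5, 99.6),
    ]

    @pytest.mark.parametrize("s,n,low,high", CASES)
    def test_reproduces_validation_table_bounds(self, s, n, low, high):
        est = wilson_ci(s, n)
        assert round(est.ci_low * 100, 1) == pytest.approx(low, abs=0.051)
        assert round(est.ci_high * 100, 1) == pytest.approx(high, abs=0.051)

    def test_zero_successes_clipped_at_zero(self):
        est = wilson_ci(0, 10)
        assert est.ci_low == 0.0

    def test_ordering_invariant_small_n(self):
        for n in range(1, 31):
            for s in range(n + 1):
                est = wilson_ci(s, n)
                assert 0.0 <= est.ci_low <= est.point <= est.ci_high <= 1.0

    def test_coverage_near_nominal(self):
        # simulated coverage at n = 79, p = 0.97 within [0.90, 0.99]
        rng = np.random.default_rng(7)
        n, p, reps = 79, 0.97, 4000
        hits = 0
        draws = rng.binomial(n, p, reps)
        for s in draws:
            est = wilson_ci(int(s), n)
            hits += est.ci_low <= p <= est.ci_high
        assert 0.90 <= hits / reps <= 0.99

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            wilson_ci(5, 4)


class TestMcNemar:
    def test_symmetric_discordance_p_one(self):
        assert mcnemar_test(4, 4) == 1.0

    def test_exact_three_zero(self):
        assert mcnemar_test(3, 0) == pytest.approx(0.25)

    def test_chi2_cc_closed_form(self):
        statistic = (abs(5 - 1) - 1) ** 2 / 6
        expected = stats.chi2.sf(statistic, 1)
        assert mcnemar_test(5, 1, method="chi2_cc") == pytest.approx(expected)

    def test_swap_invariance(self):
        for b, c in [(3, 7), (0, 5), (10, 2)]:
            assert mcnemar_test(b, c) == mcnemar_test(c, b)
            assert mcnemar_test(b, c, "chi2_cc") == mcnemar_test(c, b, "chi2_cc")

    def test_no_discordance(self):
        assert mcnemar_test(0, 0) == 1.0


class TestChiSquare:
    EXPECTED_P = {"age_sensitivity": 0.49, "age_specificity": 0.44,
                  "arm_sensitivity": 0.75, "arm_specificity": 0.36}

    @pytest.mark.parametrize("name", sorted(EXPECTED_P))
    def test_published_subgroup_p_values(self, name):
        _, p = pearson_chi2_2x2(SUBGROUP_TABLES[name])
        assert round(p, 2) == self.EXPECTED_P[name]

    def test_independence_gives_zero_statistic(self):
        statistic, p = pearson_chi2_2x2([[10, 20], [5, 10]])  # ad == bc
        assert statistic == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_expected_counts_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            t = rng.integers(1, 50, size=(2, 2)).astype(float)
            statistic, _ = pearson_chi2_2x2(t)
            total = t.sum()
            exp = np.outer(t.sum(1), t.sum(0)) / total
            brute = np.sum((t - exp) ** 2 / exp)
            assert statistic == pytest.approx(brute, rel=1e-10)

    def test_degenerate_margin_error(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2([[0, 0], [3, 4]])


class TestIrregularityIndex:
    def test_constant_series_zero(self):
        assert irregularity_index(PulseIntervalSeries([0.8] * 10)) == 0.0

    def test_afib_sd_arithmetic(self):
        # index 0.13 at a 0.75 s mean interval implies an SD of 97.5 ms
        assert 0.13 * 0.75 * 1000 == pytest.approx(97.5)
        s = simulate_afib(20000, 0.75, 0.13, seed=1)
        assert irregularity_index(s) == pytest.approx(0.13, abs=0.005)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.uniform(0.4, 1.5, int(rng.integers(2, 40)))
            s = PulseIntervalSeries(x)
            assert irregularity_index(s) == pytest.approx(
                float(np.std(x) / np.mean(x)), abs=1e-14)


def test_measurement_period_arithmetic():
    # 21.6 pulses at 80 bpm spans 16.2 s; 21.9 pulses spans 16.4 s
    assert measurement_period(21.6, 0.75) == pytest.approx(16.2)
    assert round(measurement_period(21.9, 0.75), 1) == 16.4


class TestEvaluateStudy:
    def test_perfect_predictions(self):
        truth = ["AFIB"] * 10 + ["SINUS"] * 10
        report = evaluate_study(
            ["AFIB"] * 10 + ["NON_AFIB"] * 10, truth,
            strata=["a"] * 10 + ["b"] * 10)
        for g in report.sensitivity:
            assert report.sensitivity[g].point == 1.0
        for g in report.specificity:
            assert report.specificity[g].point == 1.0

    def test_rendered_row_matches_published_format(self):
        ct = DEVICE_COUNTS["FM31"]
        report = evaluate_study(
            ["AFIB"] * ct.tp + ["NON_AFIB"] * ct.fn
            + ["NON_AFIB"] * ct.tn + ["AFIB"] * ct.fp,
            ["AFIB"] * (ct.tp + ct.fn) + ["SINUS"] * (ct.tn + ct.fp))
        assert report.sensitivity["all"].render() == "97.5 (91.2–99.3)"
        assert report.specificity["all"].render() == "98.9 (94.1–99.8)"

    def test_identical_strata_p_one(self):
        pred = (["AFIB"] * 9 + ["NON_AFIB"]) * 2
        truth = ["AFIB"] * 10 * 2
        report = evaluate_study(pred, truth, strata=["x"] * 10 + ["y"] * 10)
        for c in report.comparisons.values():
            assert c.p_value == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_study(["AFIB"], ["AFIB", "SINUS"])
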