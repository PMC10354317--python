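import itertools
import json

import numpy as np
import pytest
from scipy import optimize
from scipy.stats import binom

from ramantriage.dxstats import (
    ConfusionCounts,
    DxReport,
    MetricWithCi,
    SampleSizeSpec,
    StratumResult,
    buderer_sample_size,
    build_report,
    clopper_pearson,
    infer_counts_from_rate,
    pooled_from_counts,
    roc_auc,
    round_half_up,
    sens_spec,
    stage_sensitivity,
)


def cp_tail_oracle(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Independent Clopper–Pearson oracle: bisection on binomial tail sums
    (the defining property of the exact interval)."""
    a = (1 - level) / 2
    low = 0.0
    if x > 0:
        low = optimize.brentq(lambda p: binom.sf(x - 1, n, p) - a, 1e-12, 1 - 1e-12, xtol=1e-12)
    high = 1.0
    if x < n:
        high = optimize.brentq(lambda p: binom.cdf(x, n, p) - a, 1e-12, 1 - 1e-12, xtol=1e-12)
    return low, high


def brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance: (concordant + ½·ties) / (n1·n0)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, expect_low_pct, expect_high_pct",
        [
            (22, 23, 78.1, 99.9),   # colonoscopy-stratum sensitivity
            (26, 29, 72.6, 97.8),   # combined-stratum sensitivity (exact CP)
        ],
    )
    def test_reported_sensitivity_intervals(self, x, n, expect_low_pct, expect_high_pct):
        low, high = clopper_pearson(x, n)
        assert round_half_up(100 * low, 1) == expect_low_pct
        assert round_half_up(100 * high, 1) == expect_high_pct

    def test_boundaries_pin_to_zero_and_one(self):
        assert clopper_pearson(10, 10)[1] == 1.0
        assert clopper_pearson(0, 10)[0] == 0.0

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(3, 10), (22, 23), (0, 7), (7, 7), (150, 300)]:
            ours = clopper_pearson(x, n)
            theirs = proportion_confint(x, n, alpha=0.05, method="beta")
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_agrees_with_tail_sum_oracle_spot(self):
        for x, n in [(1, 5), (22, 23), (26, 29), (15, 30)]:
            assert clopper_pearson(x, n) == pytest.approx(cp_tail_oracle(x, n), abs=1e-6)

    def test_coverage_is_conservative(self, rng):
        """95% interval covers the truth in ≥95% of 10,000 binomial draws."""
        n, p = 23, 0.9
        bounds = [clopper_pearson(x, n) for x in range(n + 1)]
        draws = rng.binomial(n, p, size=10_000)
        covered = np.mean([bounds[x][0] <= p <= bounds[x][1] for x in draws])
        assert covered >= 0.95

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)

    def test_printed_rates_identify_unique_counts(self):
        # the printed point estimates pin down the underlying integer counts
        assert infer_counts_from_rate(23, 95.7) == [22]
        assert infer_counts_from_rate(29, 89.7) == [26]
        assert infer_counts_from_rate(225, 69.3) == [156]


class TestSensSpec:
    def test_colonoscopy_stratum_point_estimates(self):
        ss = sens_spec(ConfusionCounts(tp=22, fn=1, tn=156, fp=69))
        assert ss.sensitivity.as_percent()[0] == 95.7
        assert ss.specificity.as_percent()[0] == 69.3
        assert ss.sensitivity.as_percent()[1:] == (78.1, 99.9)

    def test_degenerate_all_negative_predictions(self):
        ss = sens_spec(ConfusionCounts(tp=0, fn=5, tn=5, fp=0))
        assert ss.sensitivity.estimate == 0.0
        assert ss.specificity.estimate == 1.0

    def test_zero_denominator_flagged_undefined(self):
        ss = sens_spec(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))
        assert ss.sensitivity is None
        assert ss.specificity is not None

    @pytest.mark.parametrize("tp, fn", [(0, 7), (3, 4), (7, 0)])
    def test_sensitivity_plus_fnr_is_one(self, tp, fn):
        ss = sens_spec(ConfusionCounts(tp=tp, fn=fn, tn=1, fp=1))
        fnr = fn / (tp + fn)
        assert ss.sensitivity.estimate + fnr == pytest.approx(1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0

    def test_null_band_for_shuffled_labels(self, rng):
        scores = rng.uniform(size=200)
        labels = rng.permutation([True] * 100 + [False] * 100)
        assert 0.40 <= roc_auc(scores, labels) <= 0.60

    def test_equals_brute_force_concordance_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 13))
            scores = rng.integers(0, 5, size=n) / 4.0  # coarse grid forces ties
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.uniform(size=100)
        labels = rng.uniform(size=100) > 0.6
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [True, True])


class FakePred:
    def __init__(self, pid, label, probability=None):
        self.patient_id = pid
        self.label = label
        self.probability = probability if probability is not None else (
            0.8 if label == "crc" else 0.2
        )


class FakeTruth:
    def __init__(self, pid, is_crc, stage):
        self.patient_id = pid
        self.is_crc = is_crc
        self.stage = stage


class TestStageSensitivity:
    def test_pooled_early_stage_from_study_counts(self):
        """2/4 + 9/10 detected in stages I–II pool to 11/14 = 78.6%."""
        b = pooled_from_counts({"I": (2, 4), "II": (9, 10), "III": (12, 12), "IV": (3, 3)})
        assert b.early.detected == 11 and b.early.total == 14
        assert round_half_up(100 * b.early.sensitivity, 1) == 78.6
        assert b.late.sensitivity == 1.0

    def test_pooling_uses_counts_not_mean_of_percentages(self):
        # asymmetric n: mean of 50% and 90% would be 70%, pooling gives 78.6%
        b = pooled_from_counts({"I": (2, 4), "II": (9, 10)})
        assert b.early.sensitivity != pytest.approx(0.7)
        assert b.early.sensitivity == pytest.approx(11 / 14)

    def test_all_missed_gives_zero(self):
        b = pooled_from_counts({"I": (0, 2), "II": (0, 3), "III": (0, 1), "IV": (0, 1)})
        assert b.early.sensitivity == 0.0 and b.late.sensitivity == 0.0

    def test_from_predictions_and_truths(self):
        preds = [FakePred("a", "crc"), FakePred("b", "non_cancer"), FakePred("c", "crc")]
        truths = [FakeTruth("a", True, "I"), FakeTruth("b", True, "II"),
                  FakeTruth("c", False, "none")]
        b = stage_sensitivity(preds, truths)
        assert b.per_stage["I"].detected == 1
        assert b.per_stage["II"].detected == 0
        assert b.early.total == 2

    def test_diseased_without_stage_is_error(self):
        preds = [FakePred("a", "crc")]
        truths = [FakeTruth("a", True, "none")]
        with pytest.raises(ValueError, match="stage"):
            stage_sensitivity(preds, truths)


class TestBudererSampleSize:
    def test_study_planning_number(self):
        """90% target, ±0.1 precision, 5% prevalence → 691 recruits."""
        assert buderer_sample_size(SampleSizeSpec(0.90, 0.10, 0.05)) == 691

    def test_unit_prevalence_reduces_to_single_proportion(self):
        assert buderer_sample_size(SampleSizeSpec(0.5, 0.5, 1.0)) == 3

    def test_prevalence_inflates_inversely(self):
        base = buderer_sample_size(SampleSizeSpec(0.8, 0.1, 1.0))
        half = buderer_sample_size(SampleSizeSpec(0.8, 0.1, 0.5))
        assert half in (2 * base, 2 * base + 1)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(0.9, 0.1, 0.0)


class TestBuildReport:
    def make_inputs(self):
        from ramantriage.spectra_io import PatientRecord

        cohort = [
            PatientRecord("a", 70, "M", "colonoscopy", "crc", "II"),
            PatientRecord("b", 66, "F", "colonoscopy", "non_crc", "none"),
            PatientRecord("c", 72, "M", "ct_colonography", "crc", "III"),
            PatientRecord("d", 60, "F", "ct_colonography", "non_crc", "none"),
        ]
        preds = [FakePred("a", "crc", 0.9), FakePred("b", "non_cancer", 0.1),
                 FakePred("c", "crc", 0.7), FakePred("d", "non_cancer", 0.3)]
        truths = [FakeTruth("a", True, "II"), FakeTruth("b", False, "none"),
                  FakeTruth("c", True, "III"), FakeTruth("d", False, "none")]
        strata = {"colonoscopy_only": ["a", "b"],
                  "colonoscopy_plus_ctc": ["a", "b", "c", "d"]}
        return preds, cohort, strata, truths

    def test_all_correct_predictions_perfect_metrics(self):
        preds, cohort, strata, truths = self.make_inputs()
        report = build_report(preds, cohort, strata, truths=truths)
        for s in report.strata:
            assert s.sensitivity.estimate == 1.0
            assert s.specificity.estimate == 1.0
            assert s.auc == 1.0

    def test_stratum_sizes_reported(self):
        preds, cohort, strata, truths = self.make_inputs()
        report = build_report(preds, cohort, strata, truths=truths)
        assert [s.n for s in report.strata] == [2, 4]

    def test_json_roundtrip_lossless(self):
        preds, cohort, strata, truths = self.make_inputs()
        report = build_report(preds, cohort, strata, truths=truths,
                              exclusion_report={"retained": 4})
        blob = json.dumps(report.to_dict())
        assert DxReport.from_dict(json.loads(blob)).to_dict() == report.to_dict()

    def test_prediction_for_unknown_patient_is_error(self):
        preds, cohort, strata, truths = self.make_inputs()
        preds.append(FakePred("zz", "crc"))
        with pytest.raises(ValueError, match="zz"):
            build_report(preds, cohort, strata)


def test_metric_ci_ordering_enforced():
    with pytest.raises(ValueError):
        MetricWithCi(0.5, 0.6, 0.9)
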