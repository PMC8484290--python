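"""Agreement and diagnostics tests: kappa arithmetic, stratified confusions,
entropy summaries and the paired t test, each against hand or library oracles."""

import math

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import cohen_kappa_score

import sleepuq as s
from sleepuq.stages import Hypnogram
from sleepuq.uncertainty import EntropyMeasureSpec, FlagSequence, UncertaintyTrace


class TestCohensKappa:
    def test_identical_sequences_have_kappa_one(self):
        hyp = Hypnogram([0, 1, 2, 3, 4, 2, 1])
        assert s.cohens_kappa(hyp, hyp).kappa == 1.0

    def test_disjoint_constants_have_kappa_zero(self):
        report = s.cohens_kappa(Hypnogram([0] * 10), Hypnogram([2] * 10))
        assert report.observed_agreement == 0.0
        assert report.expected_agreement == 0.0
        assert report.kappa == 0.0

    def test_printed_two_class_toy_table(self):
        # agreement table [[20, 5], [10, 15]] over T = 50 epochs
        a = Hypnogram([0] * 25 + [1] * 25)
        b = Hypnogram([0] * 20 + [1] * 5 + [0] * 10 + [1] * 15)
        report = s.cohens_kappa(a, b)
        assert report.observed_agreement == pytest.approx(0.7)
        assert report.expected_agreement == pytest.approx(0.5)
        assert report.kappa == pytest.approx(0.4)

    def test_symmetry_and_upper_bound_against_sklearn(self, rng):
        for _ in range(20):
            a = Hypnogram(rng.integers(0, 5, 80))
            b = Hypnogram(rng.integers(0, 5, 80))
            ours = s.cohens_kappa(a, b).kappa
            assert ours == pytest.approx(s.cohens_kappa(b, a).kappa)
            assert ours <= 1.0
            assert ours == pytest.approx(
                cohen_kappa_score(a.stages, b.stages), abs=1e-12
            )

    def test_degenerate_identical_constants_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            report = s.cohens_kappa(Hypnogram([3] * 5), Hypnogram([3] * 5))
        assert report.kappa == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(s.ValidationError):
            s.cohens_kappa(Hypnogram([0]), Hypnogram([0, 1]))


class TestCertaintyConfusion:
    def test_perfect_certain_estimate(self):
        truth = Hypnogram([0, 1, 2, 3, 4])
        flags = FlagSequence(flags=np.zeros(5, dtype=int), threshold=1.0)
        confusion = s.certainty_confusion(truth, truth, flags)
        assert np.allclose(np.diag(confusion.certain_matrix), 100.0)
        assert np.isnan(confusion.uncertain_matrix).all()

    def test_hand_tabulated_ten_epoch_instance(self):
        truth = Hypnogram([0, 0, 0, 1, 1, 3, 3, 3, 3, 4])
        estimate = Hypnogram([0, 0, 2, 1, 0, 3, 3, 3, 4, 4])
        flags = FlagSequence(flags=np.array([0, 0, 1, 0, 1, 0, 0, 0, 1, 0]), threshold=1.0)
        confusion = s.certainty_confusion(truth, estimate, flags)
        # certain stratum: W->{W:2}, REM->{REM:1}, N2->{N2:3}, N3->{N3:1}
        assert confusion.certain_matrix[0, 0] == pytest.approx(100.0)
        assert confusion.certain_matrix[3, 3] == pytest.approx(100.0)
        # uncertain stratum: W->N1 once, REM->W once, N2->N3 once
        assert confusion.uncertain_matrix[0, 2] == pytest.approx(100.0)
        assert confusion.uncertain_matrix[1, 0] == pytest.approx(100.0)
        assert confusion.uncertain_matrix[3, 4] == pytest.approx(100.0)
        assert np.isnan(confusion.uncertain_matrix[4]).all()  # no uncertain N3 epochs

    def test_counts_across_both_strata_total_t(self, rng):
        T = 60
        truth = Hypnogram(rng.integers(0, 5, T))
        estimate = Hypnogram(rng.integers(0, 5, T))
        flags = FlagSequence(flags=rng.integers(0, 2, T), threshold=1.0)
        confusion = s.certainty_confusion(truth, estimate, flags)
        assert confusion.certain_counts.sum() + confusion.uncertain_counts.sum() == T

    def test_invariant_to_epoch_permutation(self, rng):
        T = 40
        truth = rng.integers(0, 5, T)
        estimate = rng.integers(0, 5, T)
        flags = rng.integers(0, 2, T)
        perm = rng.permutation(T)
        a = s.certainty_confusion(
            Hypnogram(truth), Hypnogram(estimate), FlagSequence(flags, 1.0)
        )
        b = s.certainty_confusion(
            Hypnogram(truth[perm]), Hypnogram(estimate[perm]), FlagSequence(flags[perm], 1.0)
        )
        assert np.allclose(a.certain_counts, b.certain_counts)
        assert np.allclose(a.uncertain_counts, b.uncertain_counts)

    def test_defined_rows_sum_to_one_hundred(self, rng):
        T = 200
        truth = Hypnogram(rng.integers(0, 5, T))
        estimate = Hypnogram(rng.integers(0, 5, T))
        flags = FlagSequence(flags=rng.integers(0, 2, T), threshold=1.0)
        confusion = s.certainty_confusion(truth, estimate, flags)
        for matrix in (confusion.certain_matrix, confusion.uncertain_matrix):
            sums = np.nansum(matrix, axis=1)
            defined = ~np.isnan(matrix).all(axis=1)
            assert np.allclose(sums[defined], 100.0)


class TestEntropyDistributionSummary:
    def _trace(self, values):
        return UncertaintyTrace(np.array(values, dtype=float), EntropyMeasureSpec(1.0))

    def test_all_correct_zero_entropy(self):
        truth = Hypnogram([0, 1, 2])
        summary = s.entropy_distribution_summary(
            self._trace([0, 0, 0]), truth, truth, fit_kde=False
        )
        correct = summary.overall["correct"]
        assert (correct.count, correct.mean, correct.sd) == (3, 0.0, 0.0)
        assert summary.overall["incorrect"].count == 0
        assert math.isnan(summary.overall["incorrect"].mean)

    def test_population_moments_on_hand_set_values(self):
        truth = Hypnogram([0, 0, 0])
        estimate = Hypnogram([0, 0, 1])  # correctness [1, 1, 0]
        summary = s.entropy_distribution_summary(
            self._trace([0.1, 0.9, 1.5]), truth, estimate, fit_kde=False
        )
        correct = summary.overall["correct"]
        assert correct.mean == pytest.approx(0.5)
        assert correct.sd == pytest.approx(0.4)  # population convention
        assert summary.overall["incorrect"].mean == pytest.approx(1.5)

    def test_counts_partition_by_correctness_and_stage(self, rng):
        T = 120
        truth = Hypnogram(rng.integers(0, 5, T))
        estimate = Hypnogram(rng.integers(0, 5, T))
        trace = self._trace(rng.uniform(0, 2.3, T))
        summary = s.entropy_distribution_summary(trace, truth, estimate, fit_kde=False)
        overall = summary.overall
        assert overall["correct"].count + overall["incorrect"].count == overall["all"].count == T
        per_stage_total = sum(groups["all"].count for groups in summary.per_stage.values())
        assert per_stage_total == T

    def test_incorrect_epochs_carry_more_entropy_end_to_end(self, study):
        summary = study.pooled_entropy_summary()
        assert summary.overall["incorrect"].mean > summary.overall["correct"].mean


class TestPairedTTest:
    def test_hand_evaluated_differences(self):
        # differences [1, 2, 3]: mean 2, sample sd 1, t = 2 / (1/sqrt(3))
        t, p = s.paired_t_test([2, 4, 6], [1, 2, 3])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-4)
        assert p == pytest.approx(2 * stats.t.sf(2 * math.sqrt(3), df=2), abs=1e-10)

    def test_swapping_arguments_negates_t_keeps_p(self):
        a, b = [0.5, 0.7, 0.9, 0.6], [0.4, 0.8, 0.7, 0.5]
        t_ab, p_ab = s.paired_t_test(a, b)
        t_ba, p_ba = s.paired_t_test(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_identical_inputs_return_sentinel(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = s.paired_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert math.isnan(t) and math.isnan(p)

    def test_requires_at_least_two_pairs(self):
        with pytest.raises(s.ValidationError):
            s.paired_t_test([1.0], [2.0])


def test_substitution_dominates_automated_on_every_night(study):
    frame = study.kappa_frame()
    assert (frame["automated+substitution"] >= frame["automated"]).all()
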