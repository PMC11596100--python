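import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lvtdm import (
    ConfusionCounts,
    binary_auc,
    chi2_upper_tail,
    confusion,
    diagnostic_metrics,
    evaluate_ratings,
    find_overlap,
    friedman_test,
    load_ratings,
    reconstruct_study_table,
    study_table,
)
from friedman_oracle import brute_force_friedman, chi2_sf_df2


class TestConfusion:
    def test_study_fixture_observer_counts(self):
        table = study_table()
        c1 = confusion(table["observer_1"], table["contrast"])
        c2 = confusion(table["observer_2"], table["contrast"])
        assert (c1.tp, c1.fp, c1.fn, c1.tn) == (11, 3, 0, 15)
        assert (c2.tp, c2.fp, c2.fn, c2.tn) == (11, 4, 0, 14)

    def test_identical_columns(self):
        col = ["positive", "positive", "negative", "negative", "negative"]
        c = confusion(col, col)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 3)

    def test_nondiagnostic_excluded_pairwise(self):
        rater = ["nondiagnostic"] * 4
        ref = ["positive", "negative", "positive", "negative"]
        c = confusion(rater, ref)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 0)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown rating category"):
            confusion(["maybe"], ["positive"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion(["positive"], ["positive", "negative"])


class TestDiagnosticMetrics:
    def test_study_counts_give_published_percentages(self):
        m = diagnostic_metrics(ConfusionCounts(11, 3, 0, 15)).as_percentages()
        assert m == {"sensitivity": 100, "specificity": 83, "ppv": 79, "npv": 100, "accuracy": 90}

    def test_perfect_rater(self):
        m = diagnostic_metrics(ConfusionCounts(5, 0, 0, 5)).as_percentages()
        assert all(v == 100 for v in m.values())

    def test_zero_denominator_marked_undefined_not_zero(self):
        m = diagnostic_metrics(ConfusionCounts(0, 0, 3, 7))
        assert m.sensitivity == 0
        assert m.ppv is None
        assert m.as_percentages()["ppv"] is None

    def test_exact_rational_identities(self):
        c = ConfusionCounts(7, 2, 3, 5)
        m = diagnostic_metrics(c)
        assert m.sensitivity * (c.tp + c.fn) == c.tp
        assert m.accuracy * c.n == c.tp + c.tn
        assert m.specificity == Fraction(5, 7)


class TestBinaryAuc:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(11, 3, 0, 15), (1 + Fraction(15, 18)) / 2),
            (ConfusionCounts(11, 4, 0, 14), (1 + Fraction(14, 18)) / 2),
            (ConfusionCounts(6, 0, 0, 9), 1.0),
        ],
    )
    def test_two_segment_trapezoid(self, counts, expected):
        assert binary_auc(counts) == pytest.approx(float(expected))

    def test_constant_positive_rater_is_chance(self):
        assert binary_auc(ConfusionCounts(10, 19, 0, 0)) == pytest.approx(0.5)

    def test_undefined_when_no_positives(self):
        with pytest.raises(ValueError, match="undefined"):
            binary_auc(ConfusionCounts(0, 3, 0, 7))


class TestChi2UpperTail:
    def test_df2_closed_form(self):
        assert chi2_upper_tail(6.0, 2) == pytest.approx(np.exp(-3.0))
        assert chi2_upper_tail(4.333, 2) == pytest.approx(0.1146, abs=5e-4)

    def test_zero_statistic(self):
        for df in (1, 2, 5):
            assert chi2_upper_tail(0.0, df) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2_upper_tail(-1.0, 2)
        with pytest.raises(ValueError):
            chi2_upper_tail(1.0, 0)


class TestFriedman:
    def test_no_ties_matches_classic_formula(self):
        # every row a strict ordering: correction factor is exactly 1
        table = np.array([[1, 2, 3], [3, 1, 2], [2, 3, 1], [1, 3, 2]])
        res = friedman_test(table)
        assert res.tie_correction == 1.0
        rank_sums = res.rank_sums
        n, k = table.shape
        classic = 12.0 * np.sum(rank_sums**2) / (n * k * (k + 1)) - 3 * n * (k + 1)
        assert res.chi_square == pytest.approx(classic)

    def test_matches_scipy_on_tied_and_untied_tables(self, rng):
        for _ in range(25):
            table = rng.integers(0, 3, size=(10, 3))
            if all(len(np.unique(row)) == 1 for row in table):
                continue
            res = friedman_test(table)
            if res.degenerate:
                continue
            ref = stats.friedmanchisquare(*(table[:, j] for j in range(3)))
            assert res.chi_square == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_exhaustive_equivalence_with_brute_force_small_tables(self):
        for n in (2, 3):
            for flat in itertools.product(range(3), repeat=3 * n):
                table = [list(flat[i * 3 : (i + 1) * 3]) for i in range(n)]
                rank_sums, chi, C = brute_force_friedman(table)
                res = friedman_test(np.array(table))
                assert res.rank_sums == pytest.approx(rank_sums)
                assert res.chi_square == pytest.approx(chi, abs=1e-9)
                assert res.tie_correction == pytest.approx(C, abs=1e-12)

    def test_random_larger_tables_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 31))
            k = int(rng.integers(2, 5))
            table = rng.integers(0, 3, size=(n, k))
            rank_sums, chi, C = brute_force_friedman(table.tolist())
            res = friedman_test(table)
            assert res.rank_sums == pytest.approx(rank_sums)
            assert res.chi_square == pytest.approx(chi, abs=1e-9)

    def test_mean_ranks_sum_invariant(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            table = rng.integers(0, 3, size=(12, k))
            res = friedman_test(table)
            assert res.mean_ranks.sum() == pytest.approx(k * (k + 1) / 2)

    def test_fully_tied_table_is_degenerate(self):
        table = np.array([[1, 1, 1], [0, 0, 0], [2, 2, 2]])
        res = friedman_test(table)
        assert res.degenerate
        assert res.chi_square == 0.0
        assert res.p_value == 1.0
        assert res.tie_correction == 0.0

    def test_df2_p_value_closed_form(self):
        table = reconstruct_study_table()
        res = friedman_test(table)
        assert res.df == 2
        assert res.p_value == pytest.approx(chi2_sf_df2(res.chi_square))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.array([[1, 2, 3]]))


class TestStudyReconstruction:
    def test_marginals_of_reconstruction(self):
        t = reconstruct_study_table(overlap=1)
        pos = (t == "positive").sum()
        assert len(t) == 29
        assert pos["observer_1"] == 14
        assert pos["observer_2"] == 15
        assert pos["contrast"] == 11
        # no false negatives: every contrast-positive called positive by both
        ref_pos = t["contrast"] == "positive"
        assert (t.loc[ref_pos] == "positive").all().all()

    def test_rank_sums_invariant_to_overlap(self):
        expected = [59.0, 60.5, 54.5]
        for a in range(0, 4):
            res = friedman_test(reconstruct_study_table(overlap=a))
            assert list(res.rank_sums) == pytest.approx(expected)

    def test_overlap_one_uniquely_reproduces_reported_statistic(self):
        assert find_overlap() == 1
        chis = {a: friedman_test(reconstruct_study_table(overlap=a)).chi_square for a in range(4)}
        assert chis[1] == pytest.approx(4.333, abs=5e-4)
        assert all(abs(chis[a] - 4.333) > 0.1 for a in (0, 2, 3))

    def test_inconsistent_marginals_rejected(self):
        with pytest.raises(ValueError, match="no-false-negative"):
            reconstruct_study_table(rater1_pos=10)  # fewer positives than the reference
        with pytest.raises(ValueError, match="overlap"):
            reconstruct_study_table(overlap=5)

    def test_packaged_fixture_equals_reconstruction(self):
        assert study_table().reset_index(drop=True).equals(
            reconstruct_study_table(overlap=1).reset_index(drop=True)
        )


class TestReportsAndIO:
    def test_full_report_on_study_fixture(self):
        report = evaluate_ratings(study_table())
        obs1 = report["raters"]["observer_1"]
        assert obs1["metrics_percent"]["sensitivity"] == 100
        assert obs1["auc"] == 0.917
        assert report["raters"]["observer_2"]["auc"] == 0.889
        assert report["friedman"]["chi_square"] == 4.333
        assert report["friedman"]["mean_ranks"] == [2.03, 2.09, 1.88]
        assert report["friedman"]["p_value"] == 0.115

    def test_single_rater_identical_to_reference_degenerate_friedman(self):
        df = pd.DataFrame(
            {"rater": ["positive", "negative"] * 3, "contrast": ["positive", "negative"] * 3}
        )
        report = evaluate_ratings(df)
        assert all(v == 100 for v in report["raters"]["rater"]["metrics_percent"].values())
        assert report["friedman"]["degenerate"]

    def test_bad_token_in_csv_names_row_and_column(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("patient_id,rater,contrast\np1,positive,positive\np2,bogus,negative\n")
        with pytest.raises(ValueError, match=r"p2.*rater|rater.*p2"):
            load_ratings(path)

    def test_missing_reference_column_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            evaluate_ratings(study_table(), reference="mri")
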