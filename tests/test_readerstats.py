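"""Signal-detection scoring: d', paired tests, report layout."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermibc import (
    ResponseTable,
    build_study_report,
    dprime,
    paired_test,
    paired_test_from_differences,
    roc_pair_points,
    score_reader,
)
from dermibc.readerstats import DegenerateTestError, round_half_up


def make_table(hits, n_pos, cr, n_neg, hits_with=None, cr_with=None, reader="r1"):
    hits_with = hits if hits_with is None else hits_with
    cr_with = cr if cr_with is None else cr_with
    rows = []
    for i in range(n_pos):
        rows.append((reader, f"m{i}", "melanoma",
                     "melanoma" if i < hits else "nevus",
                     "melanoma" if i < hits_with else "nevus"))
    for i in range(n_neg):
        rows.append((reader, f"n{i}", "nevus",
                     "nevus" if i < cr else "melanoma",
                     "nevus" if i < cr_with else "melanoma"))
    return ResponseTable(pd.DataFrame(rows, columns=ResponseTable.COLUMNS))


class TestScoreReader:
    def test_sensitivity_27_of_38(self):
        perf = score_reader(make_table(27, 38, 28, 40), "r1", "without")
        assert round_half_up(perf.sensitivity, 1) == 71.1
        assert round_half_up(perf.specificity, 1) == 70.0
        assert (perf.hits, perf.misses, perf.false_alarms, perf.correct_rejections) == (
            27, 11, 12, 28,
        )

    def test_perfect_reader(self):
        perf = score_reader(make_table(38, 38, 40, 40), "r1", "without")
        assert perf.sensitivity == 100.0 and perf.specificity == 100.0

    def test_unknown_reader_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            score_reader(make_table(10, 20, 10, 20), "nobody", "with")


class TestDprime:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(0.711, 0.70, 1.08), (0.5, 0.5, 0.0), (0.947, 0.575, 1.81)],
    )
    def test_printed_pairs(self, sens, spec, expected):
        assert round_half_up(dprime(sens, spec), 2) == expected

    def test_extreme_rate_uses_half_count_correction(self):
        from scipy.stats import norm

        val = dprime(1.0, 0.5, n_pos=38)
        assert val == pytest.approx(norm.ppf(1 - 1 / 76) - norm.ppf(0.5))

    def test_extreme_rate_without_n_is_an_error(self):
        with pytest.raises(ValueError, match="1/\\(2n\\)"):
            dprime(1.0, 0.5)

    def test_label_swap_antisymmetry(self):
        # swapping positive/negative classes maps (sens, spec) -> (spec, sens)
        assert dprime(0.8, 0.6) == pytest.approx(-dprime(1 - 0.8, 1 - 0.6))

    @given(
        sens=st.floats(0.02, 0.98),
        spec=st.floats(0.02, 0.98),
        bump=st.floats(0.005, 0.02),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_each_rate(self, sens, spec, bump):
        base = dprime(sens, spec)
        assert dprime(min(sens + bump, 0.99), spec) > base
        assert dprime(sens, min(spec + bump, 0.99)) > base


class TestPairedTest:
    def test_published_sensitivity_increase_column(self):
        diffs = [10.5, 13.1, 0, 10.5, 2.6, 2.5, 13.2, 18.4, 10.5, -2.6]
        cmp = paired_test_from_differences(diffs)
        assert round_half_up(cmp.mean_diff, 2) == 7.87
        assert cmp.sd_diff == pytest.approx(6.7951, abs=1e-4)
        assert cmp.df == 9

    def test_two_and_one_sided_p_halve(self):
        rng = np.random.default_rng(0)
        wo = rng.uniform(50, 70, 10)
        wi = wo + rng.uniform(0, 10, 10)
        two = paired_test(wo, wi, sidedness="two")
        one = paired_test(wo, wi, sidedness="one")
        assert one.p_value == pytest.approx(two.p_value / 2)
        assert one.t_statistic == two.t_statistic

    def test_identical_vectors_are_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_needs_two_readers(self):
        with pytest.raises(ValueError, match="two readers"):
            paired_test_from_differences([1.0])


class TestStudyReport:
    def test_row_increases_match_printed_convention(self):
        # 23/38 -> 30/38 and 22/40 -> 28/40: increases 18.4 and 15.0
        table = make_table(23, 38, 22, 40, hits_with=30, cr_with=28)
        report = build_study_report(table)
        row = report.loc["r1"]
        assert row.sens_increase == 18.4
        assert row.spec_increase == 15.0
        assert (row.dprime_without, row.dprime_with, row.dprime_increase) == (
            0.39, 1.33, 0.94,
        )

    def test_perfect_reader_hits_corrected_ceiling(self):
        table = make_table(38, 38, 40, 40)
        report = build_study_report(table)
        ceiling = dprime(1 - 1 / 76, 1 - 1 / 80)
        assert report.loc["r1", "dprime_without"] == round_half_up(ceiling, 2)

    def test_mean_row_averages_rounded_cells(self):
        t1 = make_table(27, 38, 28, 40, hits_with=31, cr_with=31, reader="a")
        t2 = make_table(31, 38, 22, 40, hits_with=36, cr_with=23, reader="b")
        table = ResponseTable(pd.concat([t1.df, t2.df], ignore_index=True))
        report = build_study_report(table)
        assert report.loc["Mean", "sens_without"] == pytest.approx(
            (71.1 + 81.6) / 2
        )
        assert report.index[-1] == "Mean"

    def test_decimal_half_up_rounding(self):
        # float banker's rounding would give 0.46 here
        assert round_half_up(0.465, 2) == 0.47
        assert round_half_up(2.5, 0) == 3.0
        assert round_half_up(-7.5, 1) == -7.5


class TestRocPairs:
    def test_points_from_report(self):
        table = make_table(27, 38, 28, 40, hits_with=31, cr_with=31)
        points = roc_pair_points(build_study_report(table))
        row = points.loc["r1"]
        assert row.fpr_without == pytest.approx(0.30)
        assert row.tpr_without == pytest.approx(0.711)
        assert row.fpr_with == pytest.approx(0.225)
        assert row.tpr_with == pytest.approx(0.816)

    def test_no_change_reader_has_zero_length_segment(self):
        points = roc_pair_points(build_study_report(make_table(20, 38, 25, 40)))
        row = points.loc["r1"]
        assert (row.fpr_without, row.tpr_without) == (row.fpr_with, row.tpr_with)

    def test_points_confined_to_unit_square(self):
        points = roc_pair_points(build_study_report(make_table(38, 38, 1, 40)))
        assert ((points >= 0) & (points <= 1)).all().all()


class TestResponseTableValidation:
    def test_missing_column_rejected(self):
        df = pd.DataFrame({"reader_id": ["a"], "image_id": ["i"], "truth": ["melanoma"]})
        with pytest.raises(ValueError, match="missing column"):
            ResponseTable(df)

    def test_unknown_label_rejected(self):
        df = make_table(5, 10, 5, 10).df.copy()
        df.loc[0, "truth"] = "ambiguous"
        with pytest.raises(ValueError, match="unknown label"):
            ResponseTable(df)

    def test_duplicate_pair_rejected(self):
        df = make_table(5, 10, 5, 10).df
        with pytest.raises(ValueError, match="duplicate"):
            ResponseTable(pd.concat([df, df.iloc[:1]], ignore_index=True))

    def test_single_class_reader_rejected(self):
        df = make_table(5, 10, 5, 10).df
        with pytest.raises(ValueError, match="lack at least one"):
            ResponseTable(df[df.truth == "melanoma"])

    def test_csv_round_trip(self, tmp_path):
        table = make_table(5, 10, 6, 12)
        path = tmp_path / "responses.csv"
        table.to_csv(path)
        assert ResponseTable.from_csv(path).df.equals(table.df)
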