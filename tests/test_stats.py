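import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from terminome.ingest import ConditionDesign
from terminome.stats import (adjust_pvalues, fill_missing, fold_changes,
                             condition_summaries, run_statistics,
                             substrate_filter, summarize, tail_significance)
from terminome.stats import test_differential as differential_tests


def make_design():
    return ConditionDesign(
        conditions={"a": ["a_"], "b": ["b_"]},
        resolved={"a": ["a_1", "a_2", "a_3"], "b": ["b_1", "b_2", "b_3"]})


class TestFillMissing:
    def test_fill_value(self):
        df = pd.DataFrame({"a_1": [1.0], "a_2": [np.nan]})
        out = fill_missing(df, ["a_1", "a_2"], 0)
        assert out.loc[0, "a_2"] == 0.0

    def test_drop_row(self):
        df = pd.DataFrame({"a_1": [1.0, 2.0], "a_2": [np.nan, 3.0]})
        out = fill_missing(df, ["a_1", "a_2"], "drop")
        assert len(out) == 1 and out.loc[0, "a_1"] == 2.0

    def test_complete_matrix_unchanged(self):
        df = pd.DataFrame({"a_1": [1.0], "a_2": [2.0]})
        assert fill_missing(df.copy(), ["a_1", "a_2"], "drop").equals(df)


class TestSummarize:
    @pytest.mark.parametrize("values,expected", [
        ((2, 2, 2), (2.0, 0.0, 0.0)),
        ((1, 2, 3), (2.0, 1.0, 0.5)),
    ])
    def test_closed_form(self, values, expected):
        mean, sd, cv = summarize(values)
        assert (mean, sd, cv) == pytest.approx(expected)

    def test_zero_mean_cv_undefined(self):
        mean, sd, cv = summarize((0.0, 0.0))
        assert mean == 0.0 and cv is None


class TestDifferentialTests:
    def test_ttest_closed_form(self):
        # pooled-variance t on (1,2,3) vs (2,3,4): t = -1.2247, df = 4
        df = pd.DataFrame({"a_1": [1.0], "a_2": [2.0], "a_3": [3.0],
                           "b_1": [2.0], "b_2": [3.0], "b_3": [4.0]})
        out = differential_tests(df, make_design(), method="ttest")
        assert out.loc[0, "p_value_a_vs_b"] == pytest.approx(0.2879, abs=1e-4)

    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"a_1": [5.0], "a_2": [6.0],
                           "b_1": [5.0], "b_2": [6.0]})
        design = ConditionDesign({"a": ["a_"], "b": ["b_"]},
                                 {"a": ["a_1", "a_2"], "b": ["b_1", "b_2"]})
        out = differential_tests(df, design, method="ttest")
        assert out.loc[0, "p_value_a_vs_b"] == pytest.approx(1.0)

    def test_insufficient_replicates_gives_empty(self):
        df = pd.DataFrame({"a_1": [1.0], "a_2": [np.nan], "a_3": [np.nan],
                           "b_1": [2.0], "b_2": [3.0], "b_3": [4.0]})
        out = differential_tests(df, make_design(), method="ttest")
        assert out.loc[0, "p_value_a_vs_b"] is None

    def test_anova_matches_scipy_direct(self):
        rng = np.random.default_rng(0)
        data = {f"{c}_{r}": rng.normal(size=5)
                for c in "abc" for r in (1, 2, 3)}
        df = pd.DataFrame(data)
        design = ConditionDesign(
            {c: [f"{c}_"] for c in "abc"},
            {c: [f"{c}_{r}" for r in (1, 2, 3)] for c in "abc"})
        out = differential_tests(df, design, method="anova")
        for i in range(5):
            expected = sps.f_oneway(
                *[df[[f"{c}_{r}" for r in (1, 2, 3)]].iloc[i]
                  for c in "abc"]).pvalue
            assert out.loc[i, "p_value_anova"] == pytest.approx(expected)


class TestAdjustPvalues:
    def test_step_up_hand_oracle(self):
        # step-up: p_(i) * m / i, monotonized from the largest rank down:
        # (.01*4/1, .02*4/2, .03*4/3, .04*4/4) -> min-accumulated = all .04
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert np.allclose(adjust_pvalues([1.0, 1.0, 1.0]), 1.0)

    def test_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        assert (adjust_pvalues(p) >= p - 1e-12).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(adjust_pvalues(p)[perm], adjust_pvalues(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])


class TestTailSignificance:
    def test_hundred_distinct_values_label_five_per_tail(self):
        values = list(range(100))
        labels = tail_significance(values, 0.05)
        assert labels.count("significant_high") == 5
        assert labels.count("significant_low") == 5
        assert [v for v, l in zip(values, labels)
                if l == "significant_high"] == [95, 96, 97, 98, 99]

    def test_degenerate_distribution_labels_nothing(self):
        assert set(tail_significance([3.0] * 30)) == {"none"}

    def test_zero_fraction_labels_nothing(self):
        assert set(tail_significance(list(range(100)), 0.0)) == {"none"}

    def test_nonfinite_values_ignored(self):
        values = [np.nan, np.inf] + list(range(40))
        labels = tail_significance(values, 0.05)
        assert labels[0] == "none" and labels[1] == "none"


class TestFoldChanges:
    def test_direction_and_reciprocal(self):
        df = pd.DataFrame({"a_1": [4.0, 1.0], "a_2": [4.0, 1.0],
                           "a_3": [4.0, 1.0], "b_1": [2.0, 2.0],
                           "b_2": [2.0, 2.0], "b_3": [2.0, 2.0]})
        design = make_design()
        df = condition_summaries(df, design)
        df = fold_changes(df, design)
        fc = df["fold_change_a_vs_b"]
        assert fc.tolist() == pytest.approx([2.0, 0.5])
        # reciprocal identity
        rev = df["mean_b"] / df["mean_a"]
        assert (fc * rev).tolist() == pytest.approx([1.0, 1.0])

    def test_zero_mean_gives_empty_fc(self):
        df = pd.DataFrame({"a_1": [0.0], "a_2": [0.0], "a_3": [0.0],
                           "b_1": [2.0], "b_2": [2.0], "b_3": [2.0]})
        design = make_design()
        df = fold_changes(condition_summaries(df, design), design)
        assert np.isnan(df.loc[0, "fold_change_a_vs_b"])


class TestPower:
    def test_spiked_rows_detected_with_predicted_power(self):
        """log2FC = 2, sd = 0.5, n = 5/group: closed-form power of the
        pooled t-test at alpha = 0.01 exceeds 0.95; the simulation agrees."""
        n, sd, delta, alpha = 5, 0.5, 2.0, 0.01
        df_t = 2 * n - 2
        ncp = delta / (sd * np.sqrt(2 / n))
        tcrit = sps.t.ppf(1 - alpha / 2, df_t)
        power = 1 - sps.nct.cdf(tcrit, df_t, ncp) + sps.nct.cdf(-tcrit, df_t,
                                                                ncp)
        assert power > 0.95

        rng = np.random.default_rng(3)
        reps = 500
        x = rng.normal(delta, sd, size=(reps, n))
        y = rng.normal(0.0, sd, size=(reps, n))
        p = sps.ttest_ind(x, y, axis=1).pvalue
        detected = (p < alpha).mean()
        assert detected == pytest.approx(power, abs=0.05)
        assert detected >= 0.95


class TestSubstrateFilter:
    def _table(self):
        return pd.DataFrame({
            "p": [0.001, 0.001, 0.5, 0.001],
            "fc": [8.0, 8.0, 8.0, 1.2],
            "label_state": ["labeled", "free", "labeled", "labeled"],
            "category": ["internal", "internal", "internal", "internal"],
            "known_proteases": [None, None, None, None],
        })

    def test_cascade(self):
        out = substrate_filter(self._table(), "p", "fc")
        assert out.index.tolist() == [0]

    def test_without_label_requirement(self):
        out = substrate_filter(self._table(), "p", "fc",
                               require_nterm_label=False)
        assert out.index.tolist() == [0, 1]

    def test_known_cleavage_exclusion(self):
        t = self._table()
        t.loc[0, "known_proteases"] = "MMP9(M10.004)"
        out = substrate_filter(t, "p", "fc",
                               exclude_known_merops_id="M10.004")
        assert out.empty

    def test_empty_table(self):
        assert substrate_filter(pd.DataFrame(), "p", "fc").empty


class TestRunStatistics:
    def test_full_stage_appends_expected_columns(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({c: rng.lognormal(10, 1, 30).astype(str)
                           for c in ["a_1", "a_2", "a_3",
                                     "b_1", "b_2", "b_3"]})
        out = run_statistics(df, make_design())
        for col in ["mean_a", "cv_b", "fold_change_a_vs_b", "log2_fc_a_vs_b",
                    "p_value_a_vs_b", "p_adjusted_a_vs_b",
                    "tail_label_a_vs_b", "volcano_significant_a_vs_b"]:
            assert col in out.columns
        padj = out["p_adjusted_a_vs_b"].to_numpy(float)
        praw = out["p_value_a_vs_b"].to_numpy(float)
        assert (padj >= praw - 1e-12).all()
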