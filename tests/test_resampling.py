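"""Bootstrap schemes, ANOVA, chi-squared and the DI slope regression."""

import numpy as np
import pandas as pd
import pytest

from placecode1d import (
    bootstrap_between,
    bootstrap_proportion,
    bootstrap_within_subsampled,
    chi2_proportions,
    di_slope_regression,
    pairwise_posthoc,
    two_way_anova,
)


class TestBootstrapBetween:
    def test_complete_separation_gives_extreme_p(self):
        values = np.array([1.0, 1.2, 0.9, 1.1])
        low = bootstrap_between(values, 5.0, 2000, "smaller", seed=0)
        high = bootstrap_between(values, 5.0, 2000, "greater", seed=0)
        assert low.p == 1.0
        assert high.p == 0.0
        assert high.p_corrected == pytest.approx(1 / 2001)

    def test_ties_count_as_non_exceeding(self):
        values = np.full(10, 3.0)  # every resample mean equals the reference
        res = bootstrap_between(values, 3.0, 1000, "greater", seed=0)
        assert res.exceedance == 0

    def test_seeded_reproducibility(self, rng):
        values = rng.normal(0, 1, 40)
        a = bootstrap_between(values, 0.1, 5000, "smaller", seed=77)
        b = bootstrap_between(values, 0.1, 5000, "smaller", seed=77)
        assert a.exceedance == b.exceedance

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_between([], 0.0)


class TestBootstrapWithin:
    def test_constant_shift_fully_separates(self):
        fam = np.linspace(0, 1, 30)
        res = bootstrap_within_subsampled(fam, fam + 10, 30, 2000, "greater", seed=0)
        assert res.p == 1.0
        assert res.observed == pytest.approx(10.0)

    def test_identical_populations_are_symmetric(self, rng):
        values = rng.normal(0, 1, 200)
        res = bootstrap_within_subsampled(values, values, 60, 10000, "greater", seed=4)
        assert abs(res.p - 0.5) < 0.05

    def test_seeded_reproducibility(self, rng):
        fam = rng.normal(0, 1, 50)
        nov = rng.normal(0.2, 1, 80)
        a = bootstrap_within_subsampled(fam, nov, 50, 3000, "greater", seed=9)
        b = bootstrap_within_subsampled(fam, nov, 50, 3000, "greater", seed=9)
        assert a.exceedance == b.exceedance


class TestBootstrapProportion:
    def test_separated_fractions(self):
        labels = ["UC"] * 12 + ["OBC"] * 88
        res = bootstrap_proportion(labels, "UC", 0.22, 5000, "greater", seed=0)
        assert res.p < 0.02
        assert res.observed == pytest.approx(0.12)

    def test_single_label_population_degenerates(self):
        res = bootstrap_proportion(["UC"] * 20, "UC", 0.5, 1000, "greater", seed=1)
        assert res.p == 1.0  # every resample is all-UC

    def test_absent_category_warns(self):
        with pytest.warns(UserWarning, match="absent"):
            res = bootstrap_proportion(["OBC"] * 10, "UC", 0.1, 100, "greater", seed=0)
        assert res.observed == 0.0
        assert res.p == 0.0

    def test_matches_explicit_label_resampling(self):
        """Binomial sampling equals literal label-list resampling in distribution."""
        rng = np.random.default_rng(12)
        labels = np.where(rng.random(200) < 0.3, "UC", "other")
        p_hat = (labels == "UC").mean()
        res = bootstrap_proportion(labels, "UC", 0.3, 20000, "greater", seed=5)
        explicit = (
            labels[rng.integers(0, 200, (20000, 200))] == "UC"
        ).mean(axis=1)
        expect = (explicit > 0.3).mean()
        assert res.p == pytest.approx(expect, abs=0.02)


class TestTwoWayAnova:
    @staticmethod
    def _frame(cells):
        rows = []
        for (g, s), values in cells.items():
            rows += [{"group": g, "session": s, "value": v} for v in values]
        return pd.DataFrame(rows)

    def test_identical_cell_distributions_give_null_f(self):
        df = self._frame(
            {
                ("ctrl", "fam"): [1.0, 2.0, 3.0],
                ("ctrl", "nov"): [1.0, 2.0, 3.0],
                ("tg", "fam"): [1.0, 2.0, 3.0],
                ("tg", "nov"): [1.0, 2.0, 3.0],
            }
        )
        table = two_way_anova(df)
        assert table.f_group == pytest.approx(0.0, abs=1e-12)
        assert table.p_group == pytest.approx(1.0)

    def test_balanced_2x2_matches_hand_decomposition(self):
        """Textbook sums-of-squares oracle computed from scratch."""
        cells = {
            ("a", "x"): [3.0, 5.0, 4.0],
            ("a", "y"): [8.0, 9.0, 10.0],
            ("b", "x"): [2.0, 3.0, 1.0],
            ("b", "y"): [4.0, 6.0, 5.0],
        }
        df = self._frame(cells)
        table = two_way_anova(df)
        data = {k: np.asarray(v) for k, v in cells.items()}
        grand = np.mean([v for vs in data.values() for v in vs])
        n = 3
        mean_a = np.concatenate([data[("a", "x")], data[("a", "y")]]).mean()
        mean_b = np.concatenate([data[("b", "x")], data[("b", "y")]]).mean()
        mean_x = np.concatenate([data[("a", "x")], data[("b", "x")]]).mean()
        mean_y = np.concatenate([data[("a", "y")], data[("b", "y")]]).mean()
        ss_group = 2 * n * ((mean_a - grand) ** 2 + (mean_b - grand) ** 2)
        ss_sess = 2 * n * ((mean_x - grand) ** 2 + (mean_y - grand) ** 2)
        ss_int = 0.0
        for (g, s), vs in data.items():
            mg = mean_a if g == "a" else mean_b
            ms = mean_x if s == "x" else mean_y
            ss_int += n * (vs.mean() - mg - ms + grand) ** 2
        ss_err = sum(((vs - vs.mean()) ** 2).sum() for vs in data.values())
        df_err = 8
        assert table.f_group == pytest.approx(ss_group / (ss_err / df_err), abs=1e-9)
        assert table.f_session == pytest.approx(ss_sess / (ss_err / df_err), abs=1e-9)
        assert table.f_interaction == pytest.approx(ss_int / (ss_err / df_err), abs=1e-9)
        assert table.df_residual == df_err

    def test_group_permutation_preserves_session_effect(self, rng):
        df = self._frame(
            {
                ("a", "x"): rng.normal(0, 1, 10),
                ("a", "y"): rng.normal(1, 1, 10),
                ("b", "x"): rng.normal(0, 1, 10),
                ("b", "y"): rng.normal(1, 1, 10),
            }
        )
        base = two_way_anova(df)
        flipped = df.copy()
        flipped["group"] = flipped["group"].map({"a": "b", "b": "a"})
        assert two_way_anova(flipped).f_session == pytest.approx(base.f_session, rel=1e-9)

    def test_empty_cell_rejected(self):
        df = self._frame(
            {("a", "x"): [1.0, 2.0], ("a", "y"): [1.0], ("b", "x"): [2.0]}
        )
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(df)

    def test_posthoc_tables_have_all_pairs(self, rng):
        df = self._frame(
            {
                ("a", "x"): rng.normal(0, 1, 8),
                ("a", "y"): rng.normal(2, 1, 8),
                ("b", "x"): rng.normal(0, 1, 8),
                ("b", "y"): rng.normal(0, 1, 8),
            }
        )
        holm = pairwise_posthoc(df, correction="holm")
        tukey = pairwise_posthoc(df, correction="tukey")
        assert len(holm) == len(tukey) == 6
        assert (holm["p_adj"] >= holm["p_raw"] - 1e-12).all()


class TestChi2:
    def test_equal_proportions_large_n(self):
        assert chi2_proportions(200, 1000, 200, 1000) == pytest.approx(1.0)

    def test_strongly_different_proportions(self):
        # UC counts like the familiar/novel contrast in a large cell sample
        assert chi2_proportions(81, 324, 117, 975) < 0.001

    def test_symmetry(self):
        assert chi2_proportions(30, 100, 50, 120) == pytest.approx(
            chi2_proportions(50, 120, 30, 100)
        )

    def test_matches_scipy_oracle_value(self):
        import scipy.stats

        expect = scipy.stats.chi2_contingency(
            [[25, 75], [40, 60]], correction=False
        ).pvalue
        assert chi2_proportions(25, 100, 40, 100) == pytest.approx(expect)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chi2_proportions(5, 4, 1, 10)


class TestDISlopeRegression:
    @staticmethod
    def _frame(series_fam, series_nov):
        rows = []
        for i, v in enumerate(series_fam):
            rows.append({"di": v, "trial": i, "session": "familiar"})
        for i, v in enumerate(series_nov):
            rows.append({"di": v, "trial": i, "session": "novel"})
        return pd.DataFrame(rows)

    def test_identical_series_give_zero_interaction(self):
        series = 0.3 + 0.01 * np.arange(10)
        res = di_slope_regression(self._frame(series, series))
        assert res.beta == pytest.approx(0.0, abs=1e-12)

    def test_constructed_slopes_recovered_exactly(self):
        trials = np.arange(10)
        fam = 0.3 + 0.02 * trials
        nov = np.full(10, 0.4)
        res = di_slope_regression(self._frame(fam, nov))
        assert res.beta == pytest.approx(-0.02, abs=1e-12)
        assert res.slopes["familiar"] == pytest.approx(0.02, abs=1e-12)
        assert res.slopes["novel"] == pytest.approx(0.0, abs=1e-12)

    def test_doubling_values_doubles_beta(self, rng):
        fam = 0.3 + 0.01 * np.arange(8) + rng.normal(0, 0.01, 8)
        nov = 0.3 + 0.03 * np.arange(8) + rng.normal(0, 0.01, 8)
        res1 = di_slope_regression(self._frame(fam, nov))
        res2 = di_slope_regression(self._frame(2 * fam, 2 * nov))
        assert res2.beta == pytest.approx(2 * res1.beta, rel=1e-9)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            di_slope_regression(self._frame([0.1, 0.2], [0.1, 0.2]))
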