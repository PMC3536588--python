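import math

import numpy as np
import pytest

from xmricc import (
    AnovaDecomposition,
    chisq_table,
    icc_confidence_interval,
    icc_from_anova,
    month_labels,
    sem,
    sequential_scan,
    strata_index,
    trend_stats,
    two_way_anova,
    yearly_blocks,
    yearly_icc_series,
)
from xmricc import ExpenditureMatrix


def brute_force_anova(x):
    """Definition-level SS sums, written independently of the implementation."""
    n, k = len(x), len(x[0])
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i]) / k for i in range(n)]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    return ss_rows, ss_cols, ss_total - ss_rows - ss_cols


def cronbach_alpha(x):
    """Direct alpha formula: (k/(k-1)) * (1 - sum var(col) / var(row sums))."""
    n, k = x.shape
    col_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    return (k / (k - 1)) * (1 - col_vars.sum() / total_var)


class TestTwoWayAnova:
    def test_matches_brute_force_on_3x3(self, rng):
        x = rng.normal(size=(3, 3))
        a = two_way_anova(x)
        ss_r, ss_c, ss_e = brute_force_anova(x.tolist())
        assert a.ss_rows == pytest.approx(ss_r, rel=1e-12)
        assert a.ss_cols == pytest.approx(ss_c, rel=1e-12)
        assert a.ss_error == pytest.approx(ss_e, rel=1e-9)

    def test_ss_additivity_and_nonnegativity(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 15, size=2))
            a = two_way_anova(x)
            assert a.ss_rows >= 0 and a.ss_cols >= 0 and a.ss_error >= 0
            assert a.ss_total == pytest.approx(a.ss_rows + a.ss_cols + a.ss_error)
            assert a.ms_rows == pytest.approx(a.ss_rows / a.df_rows)
            assert a.f_rows == pytest.approx(a.ms_rows / a.ms_error)

    def test_printed_anova_table_additivity(self):
        # year-2000 table: SS sum to the printed total within print rounding
        a = AnovaDecomposition.from_ss(3044.90, 420, 3915.00, 11, 7643.33, 4620)
        assert a.ss_total == pytest.approx(14603.24, abs=0.02)
        assert a.df_rows + a.df_cols + a.df_error == 5051

    def test_constant_matrix_is_degenerate(self):
        a = two_way_anova(np.full((4, 5), 3.0))
        assert a.degenerate
        assert a.ss_total == 0.0
        assert math.isnan(a.f_rows) and math.isnan(a.p_rows)

    def test_rejects_missing_cells_and_tiny_grids(self):
        with pytest.raises(ValueError):
            two_way_anova(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValueError):
            two_way_anova(np.ones((1, 5)))


class TestIccFromAnova:
    def test_year_2000_worked_example(self):
        a = AnovaDecomposition.from_ss(3044.90, 420, 3915.00, 11, 7643.33, 4620)
        e = icc_from_anova(a)
        assert e.icc == pytest.approx(0.772, abs=5e-4)
        assert e.f_obs == pytest.approx(4.38, abs=5e-3)
        assert e.p < 0.001

    def test_year_2009_worked_example(self):
        a = AnovaDecomposition.from_ss(1488.20, 420, 503.22, 11, 9573.44, 4620)
        e = icc_from_anova(a)
        assert e.icc == pytest.approx(0.415, abs=5e-4)
        assert e.f_obs == pytest.approx(1.71, abs=5e-3)

    def test_zero_error_variance_gives_perfect_consistency(self):
        a = AnovaDecomposition.from_ss(10.0, 4, 1.0, 2, 0.0, 8)
        e = icc_from_anova(a)
        assert e.icc == 1.0 and e.ci_low == 1.0

    def test_zero_row_variance_is_degenerate(self):
        a = AnovaDecomposition.from_ss(0.0, 4, 1.0, 2, 2.0, 8)
        e = icc_from_anova(a)
        assert e.degenerate and math.isnan(e.icc)

    def test_alpha_oracle_equivalence_on_random_matrices(self, rng):
        """ICC(C,k) from the ANOVA route equals Cronbach's alpha computed by
        the direct variance formula, to 1e-9, on 100 random matrices."""
        for _ in range(100):
            n, k = rng.integers(3, 20), rng.integers(2, 12)
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            e = icc_from_anova(two_way_anova(x))
            assert e.icc == pytest.approx(cronbach_alpha(x), abs=1e-9)

    def test_matches_pingouin_icc3k(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(size=(12, 5)) + rng.normal(size=(12, 1))
        long = pd.DataFrame(
            {"targets": np.repeat(np.arange(12), 5),
             "raters": np.tile(np.arange(5), 12),
             "ratings": x.ravel()})
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="ratings").set_index("Type")
        e = icc_from_anova(two_way_anova(x))
        assert e.icc == pytest.approx(ref.loc["ICC(C,k)", "ICC"], abs=1e-6)
        lo, hi = ref.loc["ICC(C,k)", "CI95"]  # pingouin prints CI at 2 dp
        assert e.ci_low == pytest.approx(lo, abs=6e-3)
        assert e.ci_high == pytest.approx(hi, abs=6e-3)

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=(8, 6))
        e = icc_from_anova(two_way_anova(x))
        rp = icc_from_anova(two_way_anova(x[rng.permutation(8)]))
        cp = icc_from_anova(two_way_anova(x[:, rng.permutation(6)]))
        assert rp.icc == pytest.approx(e.icc, abs=1e-12)
        assert cp.icc == pytest.approx(e.icc, abs=1e-12)


class TestConfidenceInterval:
    def test_pins_random_data_row(self):
        lo, hi = icc_confidence_interval(0.040, 421, 13)
        assert lo == pytest.approx(-0.101, abs=0.005)
        assert hi == pytest.approx(0.170, abs=0.005)

    def test_pins_in_control_row(self):
        lo, hi = icc_confidence_interval(0.533, 421, 13)
        assert lo == pytest.approx(0.464, abs=0.005)
        assert hi == pytest.approx(0.594, abs=0.005)

    def test_interval_collapses_as_alpha_to_one(self):
        # at alpha=1 both bounds sit at the F-median-adjusted point estimate,
        # which converges to the point estimate as the dfs grow
        lo, hi = icc_confidence_interval(0.5, 421, 13, alpha=0.9999)
        assert hi - lo == pytest.approx(0.0, abs=1e-3)
        assert lo == pytest.approx(0.5, abs=2e-3)
        # width shrinks monotonically with alpha
        widths = [np.subtract(*icc_confidence_interval(0.5, 421, 13, alpha=a)[::-1])
                  for a in (0.01, 0.05, 0.5, 0.9999)]
        assert widths == sorted(widths, reverse=True)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            icc_confidence_interval(0.5, 1, 10)


class TestDerivedIndices:
    @pytest.mark.parametrize("sd,r,expected", [(10, 0.75, 5), (3, 1, 0), (7, 0, 7)])
    def test_sem(self, sd, r, expected):
        assert sem(sd, r) == pytest.approx(expected)

    def test_sem_rejects_reliability_above_one(self):
        with pytest.raises(ValueError):
            sem(1.0, 1.1)

    @pytest.mark.parametrize("r,gp,strata", [
        (0.5, 1.0, 5 / 3), (0.0, 0.0, 1 / 3), (0.8, 2.0, 3.0)])
    def test_strata_index(self, r, gp, strata):
        g, s = strata_index(r)
        assert g == pytest.approx(gp)
        assert s == pytest.approx(strata)

    def test_strata_rejects_reliability_one(self):
        with pytest.raises(ValueError):
            strata_index(1.0)


class TestYearlySeriesAndTrend:
    def test_yearly_series_one_estimate_per_block(self, rng):
        m = ExpenditureMatrix([f"h{i}" for i in range(10)],
                              month_labels("1999-01", 48),
                              100 + rng.standard_normal((10, 48)))
        scores = sequential_scan(m)
        blocks = yearly_blocks(scores.month_labels, scores.first_scored_index)
        series = yearly_icc_series(scores, blocks)
        assert sorted(series) == [2000, 2001, 2002]
        assert all(e.n_cases == 10 and e.k_items == 12 for e in series.values())

    def test_block_with_burn_in_cells_rejected(self, rng):
        m = ExpenditureMatrix(["a", "b", "c"], month_labels("1999-01", 24),
                              100 + rng.standard_normal((3, 24)))
        scores = sequential_scan(m)
        from xmricc import YearBlock
        bad = [YearBlock(1999, tuple(range(0, 12)))]  # burn-in columns
        with pytest.raises(ValueError, match="1999"):
            yearly_icc_series(scores, bad)

    def test_trend_worked_example(self):
        # series engineered to have r = -0.94 exactly against years 0..9
        years = np.arange(10, dtype=float)
        base = -(years - years.mean())
        resid = np.array([1, -1, 1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        resid -= resid.mean()
        resid -= resid @ base / (base @ base) * base
        r_target = -0.94
        scale = math.sqrt((1 / r_target**2 - 1) * (base @ base) / (resid @ resid))
        icc = base + scale * resid
        series = {2000 + int(y): float(v) for y, v in zip(years, icc)}
        tr = trend_stats(series)
        assert tr.r == pytest.approx(-0.94, abs=1e-9)
        assert tr.t_stat == pytest.approx(7.79, abs=0.01)
        assert tr.r_squared == pytest.approx(0.88, abs=0.005)
        assert tr.p < 0.0001

    def test_constant_series_flagged_degenerate(self):
        tr = trend_stats({2000: 0.5, 2001: 0.5, 2002: 0.5})
        assert tr.degenerate and math.isnan(tr.r)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            trend_stats({2000: 0.1, 2001: 0.2})


class TestChisqTable:
    def test_independent_table_gives_zero(self):
        chi2, df, p = chisq_table([[10, 10], [10, 10]])
        assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        chi2, df, _ = chisq_table([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(6.667, abs=1e-3)  # all E = 15
        assert df == 1

    def test_doubling_counts_doubles_chi2(self, rng):
        obs = rng.integers(1, 30, size=(3, 4))
        c1, _, _ = chisq_table(obs)
        c2, _, _ = chisq_table(2 * obs)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_table([[0, 0], [5, 5]])
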