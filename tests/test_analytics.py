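"""Uptake arithmetic, closed-form trend fits, chi-square, reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fopnl.analytics import (
    TrendError,
    UptakeSeries,
    build_report,
    chi_square_uptake,
    fit_linear_trend,
    format_pct,
    parse_pct,
    project_uptake,
    round_half_up,
    uptake_eligible,
    uptake_series,
    uptake_total,
)


class TestUptakeRatios:
    @pytest.mark.parametrize(
        "n, d, pct",
        [(829, 7767, "10.7"), (64, 266, "24.1"), (0, 100, "0.0")],
    )
    def test_uptake_per_total(self, n, d, pct):
        assert format_pct(uptake_total(n, d)) == pct

    @pytest.mark.parametrize(
        "n, d, pct",
        [(829, 2097, "39.5"), (125, 195, "64.1"), (7, 7, "100.0")],
    )
    def test_uptake_per_eligible(self, n, d, pct):
        assert format_pct(uptake_eligible(n, d)) == pct

    def test_zero_denominators_are_not_available(self):
        assert uptake_total(0, 0) is None
        assert uptake_eligible(0, 0) is None
        assert format_pct(None) == "N/A"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            uptake_total(5, 3)

    def test_half_up_display_rounding(self):
        assert round_half_up(6.25, 1) == 6.3  # 3/48 row convention
        assert round_half_up(28.125, 1) == 28.1

    @settings(max_examples=100, derandomize=True)
    @given(x=st.floats(0, 1))
    def test_percent_format_round_trips(self, x):
        assert abs(parse_pct(format_pct(x)) - x) <= 0.0005  # 0.05 pp


class TestTrendFit:
    def test_exact_line_recovered(self):
        years = [2017, 2018, 2019, 2020, 2021]
        y = [0.05 + 0.03 * x for x in range(1, 6)]
        fit = fit_linear_trend(years, y)
        assert fit.slope == pytest.approx(0.03, abs=1e-12)
        assert fit.intercept == pytest.approx(0.05, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_series_degenerate(self):
        fit = fit_linear_trend([2017, 2018, 2019], [0.2, 0.2, 0.2])
        assert fit.slope == pytest.approx(0.0)
        assert fit.degenerate and fit.r_squared is None

    def test_too_few_points_is_error(self):
        with pytest.raises(TrendError):
            fit_linear_trend([2020], [0.1])

    @settings(max_examples=100, derandomize=True)
    @given(
        data=st.lists(st.floats(0, 1), min_size=3, max_size=8),
    )
    def test_matches_generic_least_squares_oracle(self, data):
        years = list(range(2010, 2010 + len(data)))
        fit = fit_linear_trend(years, data)
        t = np.arange(1, len(data) + 1, dtype=float)
        coef, *_ = np.linalg.lstsq(np.c_[np.ones_like(t), t], np.array(data), rcond=None)
        assert fit.intercept == pytest.approx(coef[0], abs=1e-10)
        assert fit.slope == pytest.approx(coef[1], abs=1e-10)

    def test_ci_half_width_matches_t_based_ols(self):
        rng = np.random.default_rng(11)
        y = 0.1 + 0.05 * np.arange(1, 6) + rng.normal(0, 0.01, 5)
        fit = fit_linear_trend([2017, 2018, 2019, 2020, 2021], y)
        res = stats.linregress(np.arange(1, 6), y)
        expected = stats.t.ppf(0.975, 3) * res.stderr
        assert fit.slope_ci_half_width == pytest.approx(expected, rel=1e-9)

    def test_subperiod_fit_reuses_machinery(self):
        years = [2017, 2018, 2019, 2020, 2021]
        y = [0.02, 0.06, 0.10, 0.11, 0.12]
        full = fit_linear_trend(years, y)
        late = fit_linear_trend(years[2:], y[2:], x_start=2019)
        assert late.n == 3 and late.slope < full.slope


class TestProjection:
    def test_projection_is_linear_and_clamped(self):
        fit = fit_linear_trend([2017, 2018, 2019], [0.5, 0.8, 1.1])
        proj = project_uptake(fit, 2022)
        assert list(proj["year"]) == [2020, 2021, 2022]
        assert proj["predicted"].iloc[-1] > 1.0
        assert proj["predicted_clamped"].iloc[-1] == 1.0

    def test_zero_slope_projects_flat(self):
        fit = fit_linear_trend([2017, 2018], [0.3, 0.3])
        proj = project_uptake(fit, 2020)
        assert np.allclose(proj["predicted"], 0.3)

    def test_horizon_before_window_rejected(self):
        fit = fit_linear_trend([2017, 2018], [0.1, 0.2])
        with pytest.raises(TrendError):
            project_uptake(fit, 2017)


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        res = chi_square_uptake([[10, 20], [30, 60]])
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        cells=st.lists(st.integers(1, 200), min_size=4, max_size=12).filter(lambda c: len(c) % 2 == 0)
    )
    def test_matches_direct_oe_oracle(self, cells):
        obs = np.array(cells, dtype=float).reshape(2, -1)
        res = chi_square_uptake(obs)
        stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
        assert res["statistic"] == pytest.approx(stat, rel=1e-12)
        assert res["p_value"] == pytest.approx(p, rel=1e-9)
        assert res["df"] == df

    def test_doubling_cells_doubles_statistic(self):
        obs = np.array([[12, 30], [40, 18]])
        a = chi_square_uptake(obs)["statistic"]
        b = chi_square_uptake(2 * obs)["statistic"]
        assert b == pytest.approx(2 * a)

    def test_low_expected_cells_warn(self):
        res = chi_square_uptake([[1, 0], [1, 1]])
        assert res["low_expected_warning"]


def _toy_frame():
    rows = []
    # constructed counts, 2019-2021, one reporting group + one tiny group
    plan = {
        2019: (100, 30, 10),
        2020: (100, 40, 20),
        2021: (100, 50, 30),
    }
    i = 0
    for year, (total, eligible, labeled) in plan.items():
        for k in range(total):
            rows.append(
                {
                    "barcode": str(i := i + 1),
                    "release_year": year,
                    "status": "assigned_in_window",
                    "reporting_group": "soft drinks",
                    "manufacturer": "Big Cola" if k < labeled else f"Firm {k % 7}",
                    "eligible": k < eligible,
                    "thcl_displayed": k < labeled,
                    "uptake_flag": "displayed_eligible" if k < labeled else "x",
                    "stars": 3.0,
                }
            )
    for k in range(10):  # all-ineligible stratum
        rows.append(
            {
                "barcode": str(i := i + 1),
                "release_year": 2020,
                "status": "assigned_in_window",
                "reporting_group": "small meals",
                "manufacturer": "Tiny Foods",
                "eligible": False,
                "thcl_displayed": False,
                "uptake_flag": "not_displayed_ineligible",
                "stars": 2.0,
            }
        )
    return pd.DataFrame(rows)


class TestReports:
    def test_report_rows_match_hand_computation(self):
        report = build_report(_toy_frame(), by="reporting_group")
        sd = report[report["stratum"] == "soft drinks"].iloc[0]
        assert sd["labeled_per_total"] == "60/300"
        assert sd["pct_labeled_per_total"] == 20.0
        assert sd["labeled_per_eligible"] == "60/120"
        assert sd["pct_labeled_per_eligible"] == 50.0
        assert sd["pct_eligible_per_total"] == 40.0
        # yearly uptake/total 10%, 20%, 30% -> slope 10 pp per annum
        assert sd["trend_slope_pct_total"] == pytest.approx(10.0)
        assert sd["trend_r2_total"] == pytest.approx(1.0)

    def test_all_ineligible_stratum_is_na(self):
        report = build_report(_toy_frame(), by="reporting_group")
        tiny = report[report["stratum"] == "small meals"].iloc[0]
        assert pd.isna(tiny["pct_labeled_per_eligible"])
        assert tiny["labeled_per_eligible"] == "0/0"

    def test_marginal_consistency(self):
        report = build_report(_toy_frame(), by="reporting_group")
        body = report[report["stratum"] != "Total"]
        total = report[report["stratum"] == "Total"].iloc[0]
        for col in ("n_labeled", "n_eligible", "n_total"):
            assert body[col].sum() == total[col]

    def test_small_manufacturers_fold_into_residual_row(self):
        frame = _toy_frame()
        report = build_report(frame, by="manufacturer", min_labeled=5)
        strata = list(report["stratum"])
        assert "Big Cola" in strata  # 60 labeled products
        assert "All other companies" in strata
        assert all(s not in strata for s in frame["manufacturer"].unique() if s.startswith("Firm"))
        assert strata[-1] == "Total" and strata[-2] == "All other companies"


def test_series_invariant_enforced():
    with pytest.raises(ValueError):
        UptakeSeries(years=[2020], n_labeled=[5], n_eligible=[3], n_total=[10])


def test_series_from_annotated_frame(annotated):
    series = uptake_series(annotated)
    assert sum(series.n_total) == 7767  # window logic trims pre-criteria launches
    for lab, eli, tot in zip(series.n_labeled, series.n_eligible, series.n_total):
        assert 0 <= lab <= eli <= tot
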