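"""Cohort statistics: regressions, stepwise selection, splits, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from octspeckle import (
    CohortSpec,
    GGParams,
    InsufficientDataError,
    ParameterDomainError,
    SampleSizeSpec,
    SchemaError,
    cohort_analysis,
    compare_group_pdfs,
    forward_stepwise,
    generate_cohort,
    gg_quantile,
    group_compare,
    median_split,
    sample_size,
    simple_regression,
)


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.linspace(0, 10, 25)
        reg = simple_regression(x, 2 * x + 1)
        assert reg.slope == pytest.approx(2.0, abs=1e-12)
        assert reg.intercept == pytest.approx(1.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        y = 0.4 * x + rng.normal(size=80)
        reg = simple_regression(x, y)
        r = stats.pearsonr(x, y).statistic
        assert reg.r_squared == pytest.approx(r**2, abs=1e-10)
        sse = np.sum((y - (reg.intercept + reg.slope * x)) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert reg.r_squared == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_band_widens_away_from_mean(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 56)
        reg = simple_regression(x, rng.normal(size=56))
        width = reg.band_high - reg.band_low
        mid = np.argmin(np.abs(reg.x_grid - x.mean()))
        assert width[0] > width[mid] and width[-1] > width[mid]

    def test_degenerate_predictor(self):
        with pytest.raises(ParameterDomainError):
            simple_regression(np.ones(10), np.arange(10.0))


class TestForwardStepwise:
    def test_exact_signal_selects_only_it(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=60)
        cand = {"x1": x1, "x2": rng.normal(size=60), "x3": rng.normal(size=60)}
        model = forward_stepwise(cand, 2.0 * x1)
        assert model.selected == ["x1"]
        assert model.coefficients["x1"] == pytest.approx(2.0, abs=1e-10)

    def test_alpha_one_takes_all_useful_orthogonal_predictors(self):
        rng = np.random.default_rng(4)
        n, k = 200, 4
        X = np.linalg.qr(rng.normal(size=(n, k)))[0]
        y = X @ np.arange(1, k + 1) + 0.01 * rng.normal(size=n)
        model = forward_stepwise({f"x{i}": X[:, i] for i in range(k)}, y,
                                 alpha_enter=0.999999)
        assert sorted(model.selected) == [f"x{i}" for i in range(k)]

    def test_vanishing_alpha_selects_none(self):
        rng = np.random.default_rng(5)
        cand = {"a": rng.normal(size=50), "b": rng.normal(size=50)}
        model = forward_stepwise(cand, rng.normal(size=50), alpha_enter=1e-15)
        assert model.selected == []
        assert model.r_squared == 0.0

    def test_collinear_candidate_skipped(self, caplog):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = x + 0.1 * rng.normal(size=50)
        model = forward_stepwise({"x": x, "x_copy": x.copy()}, y)
        assert model.selected == ["x"]  # tie broken by name, duplicate skipped

    def test_entry_pvalues_below_threshold(self, cohort56):
        from octspeckle.analysis import MACRO_PREDICTORS, MICRO_PREDICTORS

        model = forward_stepwise(
            cohort56[MACRO_PREDICTORS + MICRO_PREDICTORS], cohort56["IOP_nc"]
        )
        assert all(p < model.alpha_enter for p in model.entry_p_values)
        # refitting the selected set reproduces the stored coefficients
        X = np.column_stack(
            [np.ones(len(cohort56))] + [cohort56[k] for k in model.selected]
        )
        beta, *_ = np.linalg.lstsq(X, cohort56["IOP_nc"], rcond=None)
        assert beta[0] == pytest.approx(model.intercept, rel=1e-8)
        for b, name in zip(beta[1:], model.selected):
            assert b == pytest.approx(model.coefficients[name], rel=1e-8)


class TestSampleSize:
    def test_reference_study_configuration(self):
        # sigma = delta_mu: n = (t_{0.95,54} + t_{0.99,54})^2 ~= 16.6
        n = sample_size(SampleSizeSpec(sigma=1.0, delta_mu=1.0))
        assert n == pytest.approx(16.573, abs=0.01)
        assert sample_size(SampleSizeSpec(sigma=1.0, delta_mu=1.0), ceil=True) == 17

    def test_scales_with_sigma_squared(self):
        n1 = sample_size(SampleSizeSpec(sigma=1.0, delta_mu=0.5))
        n2 = sample_size(SampleSizeSpec(sigma=2.0, delta_mu=0.5))
        assert n2 == pytest.approx(4 * n1, rel=1e-12)

    def test_monotone_in_delta(self):
        ns = [
            sample_size(SampleSizeSpec(sigma=1.0, delta_mu=d))
            for d in (0.2, 0.4, 0.8, 1.6)
        ]
        assert all(a > b for a, b in zip(ns, ns[1:]))

    def test_validation(self):
        with pytest.raises(ParameterDomainError):
            SampleSizeSpec(sigma=0.0, delta_mu=1.0)
        with pytest.raises(ParameterDomainError):
            SampleSizeSpec(sigma=1.0, delta_mu=-1.0)


class TestMedianSplit:
    def test_even_count_split(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]})
        g1, g2 = median_split(df, "v")
        assert g1["v"].tolist() == [1.0, 2.0]
        assert g2["v"].tolist() == [3.0, 4.0]

    def test_median_ties_go_below(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 2.0, 3.0, 9.0]})
        g1, g2 = median_split(df, "v")
        assert g1["v"].tolist() == [1.0, 2.0, 2.0]
        assert g2["v"].tolist() == [3.0, 9.0]

    def test_constant_column_degenerate(self):
        df = pd.DataFrame({"v": np.ones(6)})
        g1, g2 = median_split(df, "v")
        assert len(g1) == 6 and len(g2) == 0

    def test_group_sizes_balanced_up_to_ties(self, cohort56):
        g1, g2 = median_split(cohort56, "IOP_nc")
        ties = int((cohort56["IOP_nc"] == cohort56["IOP_nc"].median()).sum())
        assert abs(len(g1) - len(g2)) <= max(ties, 1)


def _rank_sum_power_normal_shift(delta, n, alpha=0.05):
    """Noether normal-approximation power of the two-sided rank-sum test.

    For X ~ N(0,1) vs Y ~ N(delta,1): p1 = P(X<Y), with the second-order
    concordance probabilities obtained by quadrature.
    """
    p1 = stats.norm.cdf(delta / np.sqrt(2))
    # p2 = P(X < Y1, X < Y2), p3 = P(X1 < Y, X2 < Y)
    p2 = integrate.quad(
        lambda x: stats.norm.pdf(x) * stats.norm.sf(x - delta) ** 2, -np.inf, np.inf
    )[0]
    p3 = integrate.quad(
        lambda y: stats.norm.pdf(y - delta) * stats.norm.cdf(y) ** 2, -np.inf, np.inf
    )[0]
    m = n * n * p1
    var0 = n * n * (2 * n + 1) / 12.0
    var1 = (
        n * n * p1 * (1 - p1)
        + n * n * (n - 1) * (p2 - p1**2)
        + n * n * (n - 1) * (p3 - p1**2)
    )
    z = stats.norm.ppf(1 - alpha / 2)
    null_mean = n * n / 2.0
    upper = null_mean + z * np.sqrt(var0)
    lower = null_mean - z * np.sqrt(var0)
    return stats.norm.sf((upper - m) / np.sqrt(var1)) + stats.norm.cdf(
        (lower - m) / np.sqrt(var1)
    )


class TestGroupCompare:
    def test_identical_groups_null(self):
        df = pd.DataFrame({"v": np.arange(20.0)})
        c = group_compare(df, df, "v")
        assert c.p_value == pytest.approx(1.0, abs=0.05)

    def test_small_group_rejected(self):
        df = pd.DataFrame({"v": [1.0]})
        with pytest.raises(InsufficientDataError):
            group_compare(df, pd.DataFrame({"v": [1.0, 2.0]}), "v")

    def test_power_matches_normal_approximation(self):
        # shifted normals, delta = 1 SD, n = 28 per group
        rng = np.random.default_rng(7)
        n, reps = 28, 1000
        rejections = 0
        for _ in range(reps):
            g1 = pd.DataFrame({"v": rng.normal(0, 1, n)})
            g2 = pd.DataFrame({"v": rng.normal(1, 1, n)})
            rejections += group_compare(g1, g2, "v").p_value < 0.05
        power_hat = rejections / reps
        power_ref = _rank_sum_power_normal_shift(1.0, n)
        se = np.sqrt(power_ref * (1 - power_ref) / reps)
        assert abs(power_hat - power_ref) < 3 * se


class TestPdfContrast:
    def test_identical_parameters(self):
        p = GGParams(0.29, 0.43, 2.8)
        stat, pval = compare_group_pdfs(p, p, m=28)
        assert stat <= 1 / 28
        assert pval > 0.99

    def test_separated_scales(self):
        stat, pval = compare_group_pdfs(
            GGParams(0.1, 0.437, 2.8), GGParams(10.0, 0.437, 2.8), m=28
        )
        assert pval < 1e-6

    def test_statistic_matches_brute_force(self):
        p1 = GGParams(0.30, 0.43, 2.85)
        p2 = GGParams(0.27, 0.45, 2.60)
        m = 28
        stat, _ = compare_group_pdfs(p1, p2, m=m)
        q = (np.arange(m) + 0.5) / m
        s1, s2 = gg_quantile(q, p1), gg_quantile(q, p2)
        pooled = np.concatenate([s1, s2])
        brute = max(
            abs(np.mean(s1 <= t) - np.mean(s2 <= t)) for t in pooled
        )
        assert stat == pytest.approx(brute, abs=1e-12)

    def test_invalid_m(self):
        with pytest.raises(ParameterDomainError):
            compare_group_pdfs(GGParams(1, 1, 1), GGParams(1, 1, 1), m=1)


class TestCohortAnalysis:
    def test_noiseless_cohort_recovers_generator(self, noiseless_cohort):
        report = cohort_analysis(noiseless_cohort)
        step = report.stepwise
        assert sorted(step.selected) == ["CCT", "GG_a"]
        assert step.coefficients["CCT"] == pytest.approx(0.0248, rel=1e-9)
        assert step.coefficients["GG_a"] == pytest.approx(-16.534, rel=1e-9)
        assert step.intercept == pytest.approx(6.853, rel=1e-9)
        assert step.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_missing_column_schema_error(self, cohort56):
        with pytest.raises(SchemaError) as err:
            cohort_analysis(cohort56.drop(columns=["GG_a"]))
        assert "GG_a" in str(err.value)

    def test_report_contents_and_write(self, cohort56, tmp_path):
        report = cohort_analysis(cohort56)
        assert report.n_subjects == 56
        assert set(report.regressions["parameter"]) == {
            "CCT", "CR", "AL", "ACD", "WTW", "age",
            "GG_a", "GG_v", "GG_p", "GG_v_over_p",
        }
        # structural signal present: CCT and GG_a correlate with IOP_nc
        r2 = report.regressions.set_index("parameter")["r_squared_IOP_nc"]
        assert r2["CCT"] > 0.05 and r2["GG_a"] > 0.05
        outdir = report.write(tmp_path / "report")
        assert (outdir / "report.json").exists()
        assert (outdir / "regressions.csv").exists()
        assert (outdir / "figure_data" / "CCT_vs_IOP_nc.csv").exists()
        fig = pd.read_csv(outdir / "figure_data" / "CCT_vs_IOP_nc.csv")
        assert list(fig.columns) == ["x", "y", "fit", "band_low", "band_high"]

    def test_cohort_too_small(self, cohort56):
        with pytest.raises(InsufficientDataError):
            cohort_analysis(cohort56.head(2))
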