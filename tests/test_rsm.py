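"""Quadratic response-surface fit, ANOVA decomposition and diagnostics."""

import numpy as np
import pytest

import biofabopt as b
from biofabopt.design import CcrdDesign
from biofabopt.errors import (
    DegenerateDataError,
    DomainError,
    IncompleteDataError,
    RankDeficiencyError,
)
from biofabopt.rsm import build_model_matrix, model_row, press_statistic


def _random_design(rng, n=20, k=2, n_center=3):
    factors = [b.FactorDef(f"f{i}", f"X{i+1}", 0.0, 1.0) for i in range(k)]
    d = b.generate_ccrd(factors, n_center=n_center)
    return d.with_responses(rng.normal(5.0, 1.0, size=d.n_runs))


class TestModelMatrix:
    def test_center_row(self):
        row = model_row(np.zeros(4), "quadratic")
        assert row[0] == 1.0 and np.all(row[1:] == 0.0)

    def test_all_minus_one_signs(self):
        row = model_row(-np.ones(4), "quadratic")
        assert np.all(row[5:11] == 1.0)  # interactions
        assert np.all(row[11:] == 1.0)  # quadratics

    def test_shape_on_study(self, study):
        assert build_model_matrix(study, "quadratic").shape == (30, 15)
        assert build_model_matrix(study, "2FI").shape == (30, 11)
        assert build_model_matrix(study, "linear").shape == (30, 5)

    def test_missing_response_raises(self):
        d = b.generate_ccrd(b.YIELD_STUDY_FACTORS, n_center=6)
        with pytest.raises(IncompleteDataError):
            build_model_matrix(d)


class TestFitOls:
    def test_study_coefficients_match_published(self, quad_fit):
        coef = dict(zip(quad_fit.terms, quad_fit.beta))
        assert coef["1"] == pytest.approx(11.66, abs=0.01)
        assert coef["X2"] == pytest.approx(1.57, abs=0.01)
        assert coef["X1^2"] == pytest.approx(-1.42, abs=0.01)

    def test_exact_recovery_of_noiseless_quadratic(self, rng):
        d = b.generate_ccrd(b.YIELD_STUDY_FACTORS, n_center=6)
        beta = rng.normal(size=15)
        X = np.vstack([model_row(np.array(r.coded)) for r in d.runs])
        fit = b.fit_ols(d.with_responses(X @ beta))
        assert np.allclose(fit.beta, beta, atol=1e-10)
        assert np.abs(fit.residuals).max() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        # brute-force normal equations on an arbitrary matrix
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        from biofabopt.rsm import _ols

        beta, *_ = _ols(X, y, [f"c{i}" for i in range(6)])
        assert np.allclose(beta, beta_oracle, atol=1e-9)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            d = _random_design(rng)
            fit = b.fit_ols(d)
            X = build_model_matrix(d)
            res = sm.OLS(d.responses(), X).fit()
            assert np.allclose(fit.beta, res.params, atol=1e-8)
            assert np.allclose(fit.hat_diag, res.get_influence().hat_matrix_diag, atol=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        from biofabopt.rsm import _ols

        x = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, x])  # duplicated regressor
        with pytest.raises(RankDeficiencyError) as exc:
            _ols(X, rng.normal(size=20), ["1", "X1", "X1_copy"])
        assert "X1_copy" in exc.value.columns

    def test_hat_diag_sums_to_p(self, quad_fit):
        assert quad_fit.hat_diag.sum() == pytest.approx(15.0, abs=1e-8)


class TestAnova:
    def test_study_headline_statistics(self, anova_table):
        t = anova_table
        assert t.row("model").f == pytest.approx(452.49, rel=0.01)
        assert t.row("lack_of_fit").f == pytest.approx(2.29, rel=0.05)
        assert t.row("pure_error").ss == pytest.approx(0.07, abs=0.02)
        assert t.row("pure_error").df == 5
        assert t.r2 == pytest.approx(0.9976, abs=5e-4)
        assert t.cv_percent == pytest.approx(1.94, abs=0.02)

    def test_per_term_partial_f(self, anova_table):
        # the dominant linear and quadratic terms of the published table
        assert anova_table.row("X2").f == pytest.approx(2237.83, rel=0.01)
        assert anova_table.row("X1^2").f == pytest.approx(2091.69, rel=0.01)
        assert anova_table.row("X1*X4").p == pytest.approx(0.7067, abs=0.01)

    def test_additivity(self, anova_table):
        t = anova_table
        assert t.row("model").ss + t.row("residual").ss == pytest.approx(
            t.row("total").ss, abs=1e-8
        )
        assert t.row("lack_of_fit").ss + t.row("pure_error").ss == pytest.approx(
            t.row("residual").ss, abs=1e-8
        )
        assert t.row("model").df + t.row("residual").df == t.row("total").df

    def test_intercept_equals_center_mean(self, study, quad_fit):
        centers = [r.response for r in study.runs if r.role == "center"]
        assert quad_fit.predict(np.zeros(4)) == pytest.approx(np.mean(centers), abs=5e-3)

    def test_zero_noise_gives_r2_one(self, rng):
        d = b.generate_ccrd(b.YIELD_STUDY_FACTORS, n_center=6)
        X = np.vstack([model_row(np.array(r.coded)) for r in d.runs])
        d = d.with_responses(X @ rng.normal(size=15) + 100.0)
        fit = b.fit_ols(d)
        t = b.anova(fit, d)
        assert t.row("residual").ss == pytest.approx(0.0, abs=1e-12)
        assert t.r2 == pytest.approx(1.0)

    def test_press_equals_explicit_leave_one_out(self, rng):
        for _ in range(5):
            d = _random_design(rng)
            fit = b.fit_ols(d)
            X = build_model_matrix(d)
            y = d.responses()
            press_loo = 0.0
            for i in range(d.n_runs):
                keep = [j for j in range(d.n_runs) if j != i]
                bi = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
                press_loo += (y[i] - X[i] @ bi) ** 2
            assert press_statistic(fit) == pytest.approx(press_loo, abs=1e-8)

    def test_degenerate_response(self, study):
        d = study.with_responses(np.full(30, 3.0))
        fit = b.fit_ols(d)
        with pytest.raises(DegenerateDataError):
            b.anova(fit, d)


class TestBoxCox:
    def test_study_profile(self, study):
        res = b.box_cox(study)
        assert res.lambda_opt == pytest.approx(1.13, abs=0.1)
        assert res.ci_low == pytest.approx(0.33, abs=0.15)
        assert res.ci_high == pytest.approx(2.09, abs=0.15)
        assert res.ci_low <= res.lambda_opt <= res.ci_high
        i = np.argmin(res.ln_ss_profile)
        assert res.lambda_grid[i] == res.lambda_opt

    def test_identity_transform_covered_under_gaussian_noise(self):
        grid = np.arange(-2.0, 4.0 + 1e-9, 0.05)
        spec = b.SimulationSpec(noise_sigma=0.163)
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            spec.seed = seed
            d = b.simulate_campaign(spec)
            res = b.box_cox(d, lambda_grid=grid)
            hits += res.ci_low <= 1.0 <= res.ci_high
        assert hits / n_rep >= 0.90

    def test_log_scale_data_pulls_lambda_to_zero(self, rng):
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.05)
        base = b.generate_ccrd(b.YIELD_STUDY_FACTORS, n_center=6)
        # a strong log-scale signal (two decades of response range) keeps
        # the power transformation identifiable despite the flexible model
        lin = np.array([r.coded for r in base.runs]) @ np.array([1.0, 1.6, -0.6, 0.4])
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            g = np.random.default_rng(seed)
            y = np.exp(2.0 + lin + g.normal(0, 0.15, size=base.n_runs))
            res = b.box_cox(base.with_responses(y), lambda_grid=grid)
            hits += abs(res.lambda_opt) < 0.3
        assert hits / n_rep >= 0.90

    def test_nonpositive_response_rejected(self, study):
        y = study.responses()
        y[0] = 0.0
        with pytest.raises(DomainError):
            b.box_cox(study.with_responses(y))


class TestFitSummary:
    def test_study_summary_matches_published(self, study):
        fs = b.fit_summary(study)
        assert fs.suggested == "quadratic"
        assert fs.summary["quadratic"]["adj_r2"] == pytest.approx(0.9954, abs=1e-3)
        assert fs.summary["linear"]["pred_r2"] == pytest.approx(0.3448, abs=0.01)
        assert fs.summary["linear"]["press"] == pytest.approx(110.5, rel=0.01)
        assert fs.sequential["quadratic"]["f"] == pytest.approx(819.41, rel=0.01)
        assert fs.lack_of_fit["linear"]["f"] == pytest.approx(318.17, rel=0.01)

    def test_pure_linear_truth_keeps_quadratic_insignificant(self):
        beta = np.zeros(15)
        beta[:5] = [10.0, 1.0, -0.5, 0.3, 0.8]
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            spec = b.SimulationSpec(true_beta=beta, noise_sigma=0.3, seed=seed)
            fs = b.fit_summary(b.simulate_campaign(spec))
            hits += fs.sequential["quadratic"]["p"] > 0.05
        assert hits / n_rep >= 0.90

    def test_zero_variance_is_degenerate(self, study):
        with pytest.raises(DegenerateDataError):
            b.fit_summary(study.with_responses(np.full(30, 1.0)))


class TestDiagnostics:
    def test_symmetric_residuals_have_zero_middle_quantile(self):
        fit = _tiny_fit(residuals=np.array([-1.0, 0.0, 1.0]))
        d = b.diagnostics(fit)
        assert d["npp"]["theoretical_quantiles"][1] == pytest.approx(0.0)
        assert d["npp"]["sorted_residuals"][1] == 0.0

    def test_study_studentized_bounded(self, quad_fit):
        d = b.diagnostics(quad_fit)
        assert np.abs(d["studentized"]).max() < 3.5

    def test_constant_fitted_values_ok(self):
        fit = _tiny_fit(residuals=np.array([0.5, -0.2, 0.1]), fitted=np.full(3, 2.0))
        d = b.diagnostics(fit)
        assert np.allclose(d["actual_vs_predicted"]["predicted"], 2.0)


def _tiny_fit(residuals, fitted=None):
    n = len(residuals)
    if fitted is None:
        fitted = np.zeros(n)
    return b.QuadraticFit(
        terms=["1"],
        beta=np.array([0.0]),
        fitted=fitted,
        residuals=residuals,
        hat_diag=np.full(n, 1.0 / n),
        sigma2=float(residuals @ residuals) / max(n - 1, 1),
        df_residual=n - 1,
        model="linear",
        xtx_inv=np.eye(1),
        y=fitted + residuals,
        k=1,
    )
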