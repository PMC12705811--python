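"""Derringer desirability ramp and response-surface optimization."""

import numpy as np
import pytest

import biofabopt as b
from biofabopt.desirability import (
    DesirabilityProblem,
    desirability,
    optimize,
    optimize_design,
    point_predict,
    problem_for_design,
    surface_grid,
)
from biofabopt.errors import ConfigurationError
from biofabopt.rsm import model_row


def _quad_fit_from_beta(beta, k=4):
    """A QuadraticFit wrapper around a known coefficient vector."""
    beta = np.asarray(beta, float)
    return b.QuadraticFit(
        terms=[f"t{i}" for i in range(len(beta))],
        beta=beta,
        fitted=np.zeros(1),
        residuals=np.zeros(1),
        hat_diag=np.zeros(1),
        sigma2=1.0,
        df_residual=1,
        model="quadratic",
        xtx_inv=np.eye(len(beta)),
        y=np.zeros(1),
        k=k,
    )


class TestRamp:
    @pytest.mark.parametrize(
        "y,expected", [(4.0, 0.0), (12.0, 1.0), (8.0, 0.5), (3.0, 0.0), (20.0, 1.0)]
    )
    def test_maximize_ramp(self, y, expected):
        prob = DesirabilityProblem(
            fit=_quad_fit_from_beta(np.zeros(15)), response_low=4.0, response_high=12.0
        )
        assert desirability(y, prob) == pytest.approx(expected)

    def test_weight_bends_the_ramp(self):
        prob = DesirabilityProblem(
            fit=_quad_fit_from_beta(np.zeros(15)),
            response_low=0.0,
            response_high=1.0,
            weight=2.0,
        )
        assert desirability(0.5, prob) == pytest.approx(0.25)

    def test_invalid_bounds(self):
        with pytest.raises(ConfigurationError):
            DesirabilityProblem(
                fit=_quad_fit_from_beta(np.zeros(15)), response_low=2.0, response_high=1.0
            )


class TestOptimize:
    def test_study_optimum(self, study, quad_fit):
        res = optimize_design(quad_fit, study, seed=1)
        # published optimum: 12.45 mg/mL at pH 7.18, 14.7 mg/mL, 70.02 h, 32.75 degC
        assert res.predicted_response == pytest.approx(12.45, abs=0.15)
        published_coded = np.array([0.18, 0.675, -0.0825, -0.45])
        assert np.all(np.abs(res.coded_opt - published_coded) <= 0.4)  # 10% of coded span
        assert res.desirability == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.abs(res.coded_opt) <= 1.0 + 1e-9)

    def test_concave_quadratic_optimum_at_origin(self):
        beta = np.zeros(15)
        beta[0] = 10.0
        beta[11:] = -1.0  # y = 10 - sum x_i^2
        fit = _quad_fit_from_beta(beta)
        prob = DesirabilityProblem(fit=fit, response_low=0.0, response_high=9.0)
        res = optimize(prob, seed=0)
        assert res.predicted_response == pytest.approx(10.0, abs=1e-6)
        assert np.allclose(res.coded_opt, 0.0, atol=1e-3)

    def test_matches_closed_form_stationary_point(self, rng):
        # random negative-definite quadratic with interior stationary point
        for _ in range(5):
            A = rng.normal(size=(4, 4))
            B = -(A @ A.T) - 0.5 * np.eye(4)  # negative definite
            x_star = rng.uniform(-0.5, 0.5, size=4)
            bvec = -2.0 * B @ x_star  # gradient zero at x_star
            beta = np.zeros(15)
            beta[1:5] = bvec
            idx = 5
            for i in range(4):
                for j in range(i + 1, 4):
                    beta[idx] = 2.0 * B[i, j]
                    idx += 1
            beta[11:] = np.diag(B)
            fit = _quad_fit_from_beta(beta)
            y_star = float(model_row(x_star) @ beta)
            prob = DesirabilityProblem(
                fit=fit, response_low=y_star - 10.0, response_high=y_star + 1.0
            )
            res = optimize(prob, seed=0)
            assert np.allclose(res.coded_opt, x_star, atol=1e-4)

    def test_optimum_dominates_design_points(self, study, quad_fit):
        prob = problem_for_design(quad_fit, study)
        res = optimize(prob, seed=3)
        for run in study.runs:
            x = np.array(run.coded)
            if np.all(np.abs(x) <= 1.0):
                d_run = desirability(quad_fit.predict(x), prob)
                assert res.desirability >= d_run - 1e-12

    def test_more_starts_never_worse(self, study, quad_fit):
        prob = problem_for_design(quad_fit, study)
        best = -np.inf
        for n in (1, 3, 10):
            res = optimize(prob, n_starts=n, seed=5)
            assert res.desirability >= best - 1e-12
            best = res.desirability

    def test_desirability_recomputable_from_definition(self, study, quad_fit):
        prob = problem_for_design(quad_fit, study)
        res = optimize(prob, seed=2)
        assert res.desirability == pytest.approx(
            desirability(res.predicted_response, prob), abs=1e-10
        )


class TestPointPredict:
    # published conditional maxima from the surface-plot analysis
    @pytest.mark.parametrize(
        "fixed,expected",
        [
            ({2: 0.0, 3: 0.0}, 12.30),
            ({1: 0.0, 3: 0.0}, 11.74),
            ({0: 0.0, 3: 0.0}, 12.43),
            ({0: 0.0, 2: 0.0}, 12.47),
            ({0: 0.0, 1: 0.0}, 11.82),
        ],
    )
    def test_conditional_maxima(self, quad_fit, fixed, expected):
        res = point_predict(quad_fit, fixed, optimize_rest=True)
        assert res["predicted"] == pytest.approx(expected, abs=0.15)

    def test_all_fixed_at_zero_gives_intercept(self, quad_fit):
        res = point_predict(quad_fit, {i: 0.0 for i in range(4)})
        assert res["predicted"] == pytest.approx(quad_fit.beta[0])

    def test_overconstrained_returns_plain_prediction_with_notice(self, quad_fit):
        res = point_predict(quad_fit, {i: 0.0 for i in range(4)}, optimize_rest=True)
        assert res["notice"] is not None
        assert res["predicted"] == pytest.approx(quad_fit.beta[0])

    def test_conditional_pH_collagen_settings(self, quad_fit):
        res = point_predict(quad_fit, {2: 0.0, 3: 0.0}, optimize_rest=True)
        # published: pH 7.06, collagen 14.76 mg/mL
        assert res["coded"][0] == pytest.approx(0.06, abs=0.4)
        assert res["coded"][1] == pytest.approx(0.69, abs=0.4)


class TestSurfaceGrid:
    def test_matches_hand_evaluation(self, quad_fit):
        g = surface_grid(quad_fit, (0, 1), resolution=3)
        for a, xi in enumerate(g["axis_i"]):
            for c, xj in enumerate(g["axis_j"]):
                x = np.zeros(4)
                x[0], x[1] = xi, xj
                assert g["predicted"][a, c] == pytest.approx(quad_fit.predict(x))

    def test_grid_maximum_consistent_with_point_predict(self, quad_fit):
        g = surface_grid(quad_fit, (0, 1), resolution=41)
        i, j = np.unravel_index(np.argmax(g["predicted"]), g["predicted"].shape)
        res = point_predict(quad_fit, {2: 0.0, 3: 0.0}, optimize_rest=True)
        cell = g["axis_i"][1] - g["axis_i"][0]
        assert abs(g["axis_i"][i] - res["coded"][0]) <= cell
        assert abs(g["axis_j"][j] - res["coded"][1]) <= cell

    def test_resolution_two_gives_corners(self, quad_fit):
        g = surface_grid(quad_fit, (2, 3), resolution=2)
        assert g["predicted"].shape == (2, 2)
        assert list(g["axis_i"]) == [-1.0, 1.0]

    def test_duplicate_indices_rejected(self, quad_fit):
        with pytest.raises(ConfigurationError):
            surface_grid(quad_fit, (1, 1))
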