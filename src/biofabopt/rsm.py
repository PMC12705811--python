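"""Second-order response-surface fitting with full ANOVA diagnostics.

The model is the usual RSM quadratic in coded units

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2 + e

fitted by ordinary least squares. The ANOVA decomposes the total sum of
squares into the model, lack-of-fit and pure-error components, reports
partial (Type III) per-term F tests, and derives the standard adequacy
statistics used in designed-experiment practice: R^2, adjusted and predicted
R^2, PRESS, the coefficient of variation and adequate precision. PRESS uses
the leave-one-out hat-diagonal identity e_(i) = e_i / (1 - h_ii).

A Box-Cox power-transformation profile and a linear/2FI/quadratic fit
summary complete the model-adequacy toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .design import CcrdDesign
from .errors import (
    DegenerateDataError,
    DomainError,
    IncompleteDataError,
    RankDeficiencyError,
)

__all__ = [
    "ModelKind",
    "term_labels",
    "build_model_matrix",
    "QuadraticFit",
    "fit_ols",
    "AnovaRow",
    "AnovaTable",
    "anova",
    "BoxCoxResult",
    "box_cox",
    "FitSummary",
    "fit_summary",
    "diagnostics",
]

ModelKind = Literal["linear", "2FI", "quadratic"]

_RANK_TOL = 1e-9


def term_labels(symbols: Sequence[str], model: ModelKind = "quadratic") -> List[str]:
    """Ordered term labels: intercept, linear, interactions, quadratics."""
    labels = ["1"] + list(symbols)
    if model in ("2FI", "quadratic"):
        k = len(symbols)
        labels += [f"{symbols[i]}*{symbols[j]}" for i in range(k) for j in range(i + 1, k)]
    if model == "quadratic":
        labels += [f"{s}^2" for s in symbols]
    return labels


def model_row(x: Sequence[float], model: ModelKind = "quadratic") -> np.ndarray:
    """Model-matrix row for one coded point."""
    x = np.asarray(x, dtype=float)
    k = x.shape[0]
    parts = [np.ones(1), x]
    if model in ("2FI", "quadratic"):
        parts.append(np.array([x[i] * x[j] for i in range(k) for j in range(i + 1, k)]))
    if model == "quadratic":
        parts.append(x * x)
    return np.concatenate(parts)


def build_model_matrix(design: CcrdDesign, model: ModelKind = "quadratic") -> np.ndarray:
    """n x p model matrix in coded units for the requested polynomial order."""
    y = design.responses()
    if np.isnan(y).any():
        missing = [design.runs[i].run_id for i in np.where(np.isnan(y))[0]]
        raise IncompleteDataError(f"runs without responses: {missing}")
    X = design.coded_matrix()
    return np.vstack([model_row(row, model) for row in X])


@dataclass
class QuadraticFit:
    """An OLS fit of a polynomial response-surface model in coded units."""

    terms: List[str]
    beta: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    hat_diag: np.ndarray
    sigma2: float  # residual mean square
    df_residual: int
    model: ModelKind
    xtx_inv: np.ndarray
    y: np.ndarray
    k: int

    @property
    def p(self) -> int:
        return len(self.terms)

    def predict(self, coded: Sequence[float]) -> float:
        """Predicted response at one coded point."""
        return float(model_row(np.asarray(coded, float), self.model) @ self.beta)

    def predict_many(self, coded: np.ndarray) -> np.ndarray:
        M = np.vstack([model_row(r, self.model) for r in np.atleast_2d(coded)])
        return M @ self.beta

    def coef_confint(self, level: float = 0.95) -> np.ndarray:
        """Per-coefficient confidence intervals, shape (p, 2)."""
        se = np.sqrt(self.sigma2 * np.diag(self.xtx_inv))
        t = stats.t.ppf(0.5 + level / 2, self.df_residual)
        return np.column_stack([self.beta - t * se, self.beta + t * se])


def _ols(X: np.ndarray, y: np.ndarray, labels: Sequence[str]):
    """Plain normal-equation OLS via QR; raises on rank deficiency."""
    n, p = X.shape
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = max(diag.max(), 1.0)
    if (diag < _RANK_TOL * scale).any():
        bad = [labels[i] for i in np.where(diag < _RANK_TOL * scale)[0]]
        raise RankDeficiencyError(bad)
    beta = np.linalg.solve(r, q.T @ y)
    fitted = X @ beta
    resid = y - fitted
    hat = np.einsum("ij,ij->i", q, q)
    rinv = np.linalg.solve(r, np.eye(p))
    xtx_inv = rinv @ rinv.T
    return beta, fitted, resid, hat, xtx_inv


def fit_ols(design: CcrdDesign, model: ModelKind = "quadratic") -> QuadraticFit:
    """Fit the polynomial model to the design's responses by OLS."""
    X = build_model_matrix(design, model)
    y = design.responses()
    n, p = X.shape
    if n <= p:
        raise IncompleteDataError(f"need n > p for error estimation (n={n}, p={p})")
    labels = term_labels([f.symbol for f in design.factors], model)
    beta, fitted, resid, hat, xtx_inv = _ols(X, y, labels)
    df_res = n - p
    sigma2 = float(resid @ resid) / df_res
    return QuadraticFit(
        terms=labels,
        beta=beta,
        fitted=fitted,
        residuals=resid,
        hat_diag=hat,
        sigma2=sigma2,
        df_residual=df_res,
        model=model,
        xtx_inv=xtx_inv,
        y=y,
        k=design.k,
    )


@dataclass
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: Optional[float]
    f: Optional[float]
    p: Optional[float]


@dataclass
class AnovaTable:
    """ANOVA decomposition plus the standard adequacy statistics."""

    rows: List[AnovaRow]
    r2: float
    adj_r2: float
    pred_r2: Optional[float]
    press: Optional[float]
    std_dev: float
    mean: float
    cv_percent: float
    adeq_precision: float
    coefficients: Dict[str, float]

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_dict(self) -> dict:
        return {
            "rows": [vars(r) for r in self.rows],
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "pred_r2": self.pred_r2,
            "press": self.press,
            "std_dev": self.std_dev,
            "mean": self.mean,
            "cv_percent": self.cv_percent,
            "adeq_precision": self.adeq_precision,
            "coefficients": self.coefficients,
        }


def _pure_error(design: CcrdDesign, y: np.ndarray) -> Tuple[float, int]:
    """Pure-error SS/df from replicated coded points (grouped exactly)."""
    groups: Dict[tuple, list] = {}
    for run, yi in zip(design.runs, y):
        key = tuple(round(c, 12) for c in run.coded)
        groups.setdefault(key, []).append(yi)
    ss = 0.0
    df = 0
    for vals in groups.values():
        if len(vals) > 1:
            v = np.asarray(vals)
            ss += float(((v - v.mean()) ** 2).sum())
            df += len(vals) - 1
    return ss, df


def press_statistic(fit: QuadraticFit) -> float:
    """Leave-one-out prediction error sum of squares via hat diagonals."""
    if np.any(fit.hat_diag >= 1 - 1e-12):
        raise DomainError("a run has leverage 1; PRESS is undefined")
    loo = fit.residuals / (1.0 - fit.hat_diag)
    return float(loo @ loo)


def anova(fit: QuadraticFit, design: CcrdDesign) -> AnovaTable:
    """Full ANOVA table with partial (Type III) per-term tests.

    The partial SS of a single-df term is beta_j^2 / [(X'X)^-1]_jj — the
    SS increase from dropping that term from the otherwise full model.
    Lack of fit is the residual left after removing replicate pure error.
    If the design has no replicated points, the lack-of-fit split is
    omitted and the residual row stands alone.
    """
    y = fit.y
    n = len(y)
    p = fit.p
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total <= 0:
        raise DegenerateDataError("response has zero variance")
    ss_res = float(fit.residuals @ fit.residuals)
    ss_model = ss_total - ss_res
    df_model = p - 1
    df_res = fit.df_residual
    ms_res = fit.sigma2
    rows: List[AnovaRow] = []

    def fp(ss, df):
        if df <= 0 or ms_res <= 0:
            return None, None
        f = (ss / df) / ms_res
        return f, float(stats.f.sf(f, df, df_res))

    f_m, p_m = fp(ss_model, df_model)
    rows.append(AnovaRow("model", ss_model, df_model, ss_model / df_model, f_m, p_m))
    # per-term partial SS (skip intercept)
    d = np.diag(fit.xtx_inv)
    for j in range(1, p):
        ss_j = float(fit.beta[j] ** 2 / d[j])
        f_j, p_j = fp(ss_j, 1)
        rows.append(AnovaRow(fit.terms[j], ss_j, 1, ss_j, f_j, p_j))

    ss_pe, df_pe = _pure_error(design, y)
    if df_pe > 0 and df_res > df_pe:
        ss_lof = max(ss_res - ss_pe, 0.0)
        df_lof = df_res - df_pe
        ms_pe = ss_pe / df_pe
        f_lof = (ss_lof / df_lof) / ms_pe if ms_pe > 0 else None
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe)) if f_lof is not None else None
        rows.append(AnovaRow("lack_of_fit", ss_lof, df_lof, ss_lof / df_lof, f_lof, p_lof))
        rows.append(AnovaRow("pure_error", ss_pe, df_pe, ms_pe, None, None))
    rows.append(AnovaRow("residual", ss_res, df_res, ms_res, None, None))
    rows.append(AnovaRow("total", ss_total, n - 1, None, None, None))

    press = press_statistic(fit)
    r2 = 1 - ss_res / ss_total
    adj_r2 = 1 - (ss_res / df_res) / (ss_total / (n - 1))
    pred_r2 = 1 - press / ss_total
    mean_y = float(y.mean())
    cv = 100.0 * np.sqrt(ms_res) / mean_y
    adeq = float((fit.fitted.max() - fit.fitted.min()) / np.sqrt(p * ms_res / n))
    return AnovaTable(
        rows=rows,
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        press=press,
        std_dev=float(np.sqrt(ms_res)),
        mean=mean_y,
        cv_percent=float(cv),
        adeq_precision=adeq,
        coefficients=dict(zip(fit.terms, fit.beta)),
    )


@dataclass
class BoxCoxResult:
    lambda_grid: np.ndarray
    ln_ss_profile: np.ndarray
    lambda_opt: float
    ci_low: float
    ci_high: float


def box_cox(
    design: CcrdDesign,
    model: ModelKind = "quadratic",
    lambda_grid: Optional[np.ndarray] = None,
    conf: float = 0.95,
) -> BoxCoxResult:
    """Box-Cox power-transformation profile for the fitted model.

    For each lambda the response is transformed with the geometric-mean
    scaling z = (y^λ - 1)/(λ g^(λ-1)) (z = g ln y at λ = 0), the model is
    refitted and ln SS_residual recorded. The confidence region uses the
    F-based threshold SS_λ <= SS_min (1 + F(conf, 1, df_res)/df_res), the
    construction used by standard DoE software and the one that matches
    the bundled study's printed interval.
    """
    y = design.responses()
    if np.isnan(y).any():
        raise IncompleteDataError("all runs need responses for the Box-Cox profile")
    if (y <= 0).any():
        raise DomainError("Box-Cox requires strictly positive responses")
    if lambda_grid is None:
        lambda_grid = np.arange(-3.0, 3.0 + 1e-9, 0.01)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    X = build_model_matrix(design, model)
    q, _ = np.linalg.qr(X)
    g = float(np.exp(np.log(y).mean()))
    lny = np.log(y)
    ss = np.empty(lambda_grid.shape)
    for i, lam in enumerate(lambda_grid):
        if abs(lam) < 1e-12:
            z = g * lny
        else:
            z = (y**lam - 1.0) / (lam * g ** (lam - 1.0))
        proj = q.T @ z
        ss[i] = float(z @ z - proj @ proj)
    ln_ss = np.log(ss)
    i_opt = int(np.argmin(ss))
    df_res = X.shape[0] - X.shape[1]
    thresh = ss[i_opt] * (1.0 + stats.f.ppf(conf, 1, df_res) / df_res)
    inside = lambda_grid[ss <= thresh]
    return BoxCoxResult(
        lambda_grid=lambda_grid,
        ln_ss_profile=ln_ss,
        lambda_opt=float(lambda_grid[i_opt]),
        ci_low=float(inside.min()),
        ci_high=float(inside.max()),
    )


@dataclass
class FitSummary:
    """Linear / 2FI / quadratic candidate comparison (sequential + LOF)."""

    sequential: Dict[str, dict]  # per model: ss, df, ms, f, p (vs previous)
    lack_of_fit: Dict[str, dict]  # per model: ss, df, ms, f, p
    summary: Dict[str, dict]  # per model: std_dev, r2, adj_r2, pred_r2, press
    suggested: str


_CANDIDATES: List[ModelKind] = ["linear", "2FI", "quadratic"]


def fit_summary(design: CcrdDesign) -> FitSummary:
    """Sequential model sums of squares, per-model lack of fit and summary
    statistics for the linear, two-factor-interaction and quadratic models.

    The sequential F for each model tests its extra terms against the
    residual mean square of that (augmented) model. The suggested model has
    insignificant lack of fit (p > 0.05) and the largest adjusted R^2 among
    candidates meeting that bar; if none does, the largest adjusted R^2 wins.
    """
    y = design.responses()
    n = len(y)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total <= 0:
        raise DegenerateDataError("response has zero variance")
    ss_pe, df_pe = _pure_error(design, y)

    sequential: Dict[str, dict] = {}
    lof: Dict[str, dict] = {}
    summary: Dict[str, dict] = {}
    prev_ss_model = 0.0
    prev_df_model = 0
    fits = {m: fit_ols(design, m) for m in _CANDIDATES}
    for m in _CANDIDATES:
        f = fits[m]
        ss_res = float(f.residuals @ f.residuals)
        ss_model = ss_total - ss_res
        df_model = f.p - 1
        d_ss = ss_model - prev_ss_model
        d_df = df_model - prev_df_model
        ms_res = f.sigma2
        f_seq = (d_ss / d_df) / ms_res if ms_res > 0 else np.inf
        p_seq = float(stats.f.sf(f_seq, d_df, f.df_residual))
        sequential[m] = {"ss": d_ss, "df": d_df, "ms": d_ss / d_df, "f": f_seq, "p": p_seq}
        prev_ss_model, prev_df_model = ss_model, df_model

        if df_pe > 0 and f.df_residual > df_pe:
            ss_l = max(ss_res - ss_pe, 0.0)
            df_l = f.df_residual - df_pe
            ms_pe = ss_pe / df_pe
            f_l = (ss_l / df_l) / ms_pe if ms_pe > 0 else np.inf
            p_l = float(stats.f.sf(f_l, df_l, df_pe))
            lof[m] = {"ss": ss_l, "df": df_l, "ms": ss_l / df_l, "f": f_l, "p": p_l}
        press = press_statistic(f)
        summary[m] = {
            "std_dev": float(np.sqrt(ms_res)),
            "r2": 1 - ss_res / ss_total,
            "adj_r2": 1 - (ss_res / f.df_residual) / (ss_total / (n - 1)),
            "pred_r2": 1 - press / ss_total,
            "press": press,
        }

    ok = [m for m in _CANDIDATES if m in lof and lof[m]["p"] > 0.05]
    pool = ok if ok else _CANDIDATES
    suggested = max(pool, key=lambda m: summary[m]["adj_r2"])
    return FitSummary(sequential=sequential, lack_of_fit=lof, summary=summary, suggested=suggested)


def diagnostics(fit: QuadraticFit) -> dict:
    """Residual diagnostic series for normal-probability and fit plots.

    Returns Blom normal plotting positions (i - 3/8)/(n + 1/4) paired with
    sorted residuals, residual-vs-predicted pairs, actual-vs-predicted
    pairs, and internally studentized residuals.
    """
    n = len(fit.residuals)
    order = np.argsort(fit.residuals)
    pp = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    quantiles = stats.norm.ppf(pp)
    denom = np.sqrt(fit.sigma2 * np.clip(1.0 - fit.hat_diag, 1e-12, None))
    return {
        "npp": {
            "theoretical_quantiles": quantiles,
            "sorted_residuals": fit.residuals[order],
        },
        "residual_vs_predicted": {"predicted": fit.fitted, "residuals": fit.residuals},
        "actual_vs_predicted": {"predicted": fit.fitted, "actual": fit.y},
        "studentized": fit.residuals / denom,
    }
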