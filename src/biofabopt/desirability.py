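"""Derringer desirability optimization of a fitted response surface.

A single-response desirability ramp d(y) in [0, 1] encodes the optimization
goal (maximize, minimize, or hit a target); the optimizer then searches the
coded factor box with a coarse grid followed by Nelder-Mead polish from the
best grid cells.

For the maximize goal with the conventional ramp bounds (min/max observed
response), every point whose prediction exceeds the upper bound has d = 1,
so the desirability surface can have a flat plateau. Ties are broken
deterministically in favor of the larger predicted response, which keeps
the returned optimum unique and makes argmax(d) coincide with argmax(y)
whenever the goal is monotone in y.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .design import CcrdDesign, decode
from .errors import ConfigurationError, InfeasibleError
from .rsm import QuadraticFit

__all__ = [
    "DesirabilityProblem",
    "DesirabilityResult",
    "desirability",
    "optimize",
    "point_predict",
    "surface_grid",
]


@dataclass
class DesirabilityProblem:
    fit: QuadraticFit
    goal: str = "maximize"  # "maximize" | "minimize" | "target"
    response_low: float = 0.0
    response_high: float = 1.0
    target: Optional[float] = None
    weight: float = 1.0
    factor_bounds: Optional[Sequence[Tuple[float, float]]] = None  # coded intervals

    def __post_init__(self) -> None:
        if not self.response_low < self.response_high:
            raise ConfigurationError(
                f"response_low ({self.response_low}) must be < response_high ({self.response_high})"
            )
        if self.goal not in ("maximize", "minimize", "target"):
            raise ConfigurationError(f"unknown goal {self.goal!r}")
        if self.goal == "target" and self.target is None:
            raise ConfigurationError("target goal needs a target value")

    def bounds(self) -> list:
        if self.factor_bounds is not None:
            return [tuple(b) for b in self.factor_bounds]
        return [(-1.0, 1.0)] * self.fit.k


def problem_for_design(
    fit: QuadraticFit,
    design: CcrdDesign,
    goal: str = "maximize",
    bounds: str = "factorial",
    weight: float = 1.0,
) -> DesirabilityProblem:
    """Convenience constructor using the software defaults: the ramp spans
    the observed response range and the search box is the factorial region
    [-1, 1]^k (``bounds="axial"`` widens it to the axial box)."""
    y = design.responses()
    box = (-1.0, 1.0) if bounds == "factorial" else (-design.alpha, design.alpha)
    return DesirabilityProblem(
        fit=fit,
        goal=goal,
        response_low=float(np.nanmin(y)),
        response_high=float(np.nanmax(y)),
        weight=weight,
        factor_bounds=[box] * fit.k,
    )


def desirability(y: float, problem: DesirabilityProblem) -> float:
    """Derringer ramp value d(y) in [0, 1]."""
    lo, hi, w = problem.response_low, problem.response_high, problem.weight
    if problem.goal == "maximize":
        if y <= lo:
            return 0.0
        if y >= hi:
            return 1.0
        return float(((y - lo) / (hi - lo)) ** w)
    if problem.goal == "minimize":
        if y >= hi:
            return 0.0
        if y <= lo:
            return 1.0
        return float(((hi - y) / (hi - lo)) ** w)
    t = problem.target
    if y <= lo or y >= hi:
        return 0.0 if y != t else 1.0
    if y <= t:
        return float(((y - lo) / (t - lo)) ** w)
    return float(((hi - y) / (hi - t)) ** w)


@dataclass
class DesirabilityResult:
    coded_opt: np.ndarray
    actual_opt: np.ndarray
    predicted_response: float
    desirability: float
    n_starts: int
    converged: bool


def _score(problem: DesirabilityProblem, x: np.ndarray) -> Tuple[float, float]:
    """(desirability, signed response) — lexicographic maximization key."""
    yv = problem.fit.predict(x)
    d = desirability(yv, problem)
    sign = -1.0 if problem.goal == "minimize" else 1.0
    return d, sign * yv


def _polish(problem, x0, bounds):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def neg(x):
        xc = np.clip(x, lo, hi)
        d, s = _score(problem, xc)
        # tiny monotone tie-break keeps the plateau search moving toward
        # larger responses without perturbing d at visible precision
        return -(d + 1e-9 * np.tanh(s / max(abs(problem.response_high), 1.0)))

    res = minimize(neg, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    return np.clip(res.x, lo, hi), res.success


def optimize(
    problem: DesirabilityProblem,
    n_starts: int = 10,
    seed: int = 0,
    grid_per_axis: int = 5,
) -> DesirabilityResult:
    """Multi-start search: coarse grid seeding + Nelder-Mead polish.

    Deterministic for a given seed; the seed only breaks ties among equally
    desirable grid cells. For monotone goals the plateau tie-break returns
    the point with the best predicted response among d-ties.
    """
    bounds = problem.bounds()
    k = len(bounds)
    axes = [np.linspace(b[0], b[1], grid_per_axis) for b in bounds]
    grid = np.array(list(itertools.product(*axes)))
    scores = [_score(problem, g) for g in grid]
    order = sorted(range(len(grid)), key=lambda i: scores[i], reverse=True)
    rng = np.random.default_rng(seed)
    starts = [grid[i] for i in order[: max(n_starts, 1)]]
    while len(starts) < n_starts:
        starts.append(np.array([rng.uniform(b[0], b[1]) for b in bounds]))

    best_x = None
    best_key = None
    any_ok = False
    for x0 in starts[:n_starts]:
        x, ok = _polish(problem, np.asarray(x0, float), bounds)
        any_ok = any_ok or ok
        key = _score(problem, x)
        if best_key is None or key > best_key:
            best_key, best_x = key, x
    if best_x is None:
        raise InfeasibleError("no feasible point found")
    if problem.goal in ("maximize", "minimize"):
        # crisp plateau tie-break: polish the response itself from the best
        # desirability point (monotone goals only; cannot lower d)
        sign = 1.0 if problem.goal == "maximize" else -1.0
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        res = minimize(
            lambda x: -sign * problem.fit.predict(np.clip(x, lo, hi)),
            best_x,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000},
        )
        cand = np.clip(res.x, lo, hi)
        if _score(problem, cand) >= best_key:
            best_x = cand
    y_opt = problem.fit.predict(best_x)
    return DesirabilityResult(
        coded_opt=best_x,
        actual_opt=np.asarray(best_x, float),  # replaced below if factors known
        predicted_response=float(y_opt),
        desirability=desirability(y_opt, problem),
        n_starts=n_starts,
        converged=any_ok,
    )


def optimize_design(
    fit: QuadraticFit,
    design: CcrdDesign,
    goal: str = "maximize",
    bounds: str = "factorial",
    n_starts: int = 10,
    seed: int = 0,
) -> DesirabilityResult:
    """Optimize over a design's coded box and report actual-unit settings."""
    problem = problem_for_design(fit, design, goal=goal, bounds=bounds)
    res = optimize(problem, n_starts=n_starts, seed=seed)
    res.actual_opt = decode(res.coded_opt, design.factors)
    return res


def point_predict(
    fit: QuadraticFit,
    fixed: dict,
    optimize_rest: bool = False,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    n_starts: int = 10,
    seed: int = 0,
) -> dict:
    """Evaluate or conditionally maximize the surface.

    ``fixed`` maps factor index -> coded value. With ``optimize_rest`` the
    free coordinates are maximized over the box with the fixed ones clamped;
    otherwise free coordinates sit at 0. If every factor is fixed, the plain
    prediction is returned with a notice.
    """
    k = fit.k
    if bounds is None:
        bounds = [(-1.0, 1.0)] * k
    free = [i for i in range(k) if i not in fixed]
    x = np.zeros(k)
    for i, v in fixed.items():
        lo, hi = bounds[i]
        if not lo <= v <= hi:
            raise ConfigurationError(f"fixed value {v} for factor {i} outside bounds [{lo}, {hi}]")
        x[i] = v
    notice = None
    if optimize_rest and not free:
        notice = "all factors fixed; returning the plain prediction"
        optimize_rest = False
    if optimize_rest:
        sub_bounds = [bounds[i] for i in free]
        axes = [np.linspace(b[0], b[1], 5) for b in sub_bounds]
        cells = sorted(
            itertools.product(*axes),
            key=lambda v: fit.predict(_embed(x, free, v)),
            reverse=True,
        )[: max(n_starts, 1)]
        lo = np.array([b[0] for b in sub_bounds])
        hi = np.array([b[1] for b in sub_bounds])
        best_v, best_y = None, -np.inf
        for v0 in cells:
            res = minimize(
                lambda v: -fit.predict(_embed(x, free, np.clip(v, lo, hi))),
                np.asarray(v0, float),
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-12},
            )
            v = np.clip(res.x, lo, hi)
            yv = fit.predict(_embed(x, free, v))
            if yv > best_y:
                best_y, best_v = yv, v
        x = _embed(x, free, best_v)
    return {"coded": x, "predicted": fit.predict(x), "notice": notice}


def _embed(x: np.ndarray, free: list, values) -> np.ndarray:
    out = x.copy()
    for i, v in zip(free, np.atleast_1d(values)):
        out[i] = v
    return out


def surface_grid(
    fit: QuadraticFit,
    pair: Tuple[int, int],
    held: Optional[dict] = None,
    resolution: int = 25,
    bounds: Tuple[float, float] = (-1.0, 1.0),
) -> dict:
    """Predictions over a regular coded grid for one factor pair (3D plots)."""
    i, j = pair
    if i == j:
        raise ConfigurationError("surface_grid needs two distinct factor indices")
    if resolution < 2:
        raise ConfigurationError("resolution must be >= 2")
    held = held or {}
    ax = np.linspace(bounds[0], bounds[1], resolution)
    Z = np.empty((resolution, resolution))
    base = np.zeros(fit.k)
    for idx, v in held.items():
        base[idx] = v
    for a, xi in enumerate(ax):
        for b, xj in enumerate(ax):
            x = base.copy()
            x[i], x[j] = xi, xj
            Z[a, b] = fit.predict(x)
    return {"axis_i": ax, "axis_j": ax, "predicted": Z}
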