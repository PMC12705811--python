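"""Shallow tanh-network surrogate with holdback validation.

Architecture: k inputs (coded factor levels), one hidden layer of H tanh
units, a linear output. Training is full-batch gradient descent on the
training-split sum of squared errors with an adaptive step (the learning
rate is halved whenever a step fails to decrease the loss, floored at
1e-6). "Tours" are independent random restarts; the tour with the lowest
validation SSE (training SSE when there is no validation split) is kept.

Inputs enter in coded units, which are already centered and scaled; the
output is min-max scaled to [0, 1] for training and inverse-transformed
for reporting. All randomness flows through one seeded generator, so a
given (config, data) pair trains bit-reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .design import CcrdDesign, decode
from .errors import ConfigurationError, TrainingFailureError
from .rsm import QuadraticFit

__all__ = [
    "AnnConfig",
    "AnnModel",
    "AnnMetrics",
    "split_holdback",
    "train",
    "evaluate",
    "ann_optimize",
    "compare_models",
]


@dataclass
class AnnConfig:
    n_hidden: int = 20
    tours: int = 50  # the source study used 5000; 50 is the desk-scale default
    learning_rate: float = 0.1
    max_epochs: int = 2000
    holdback_fraction: float = 0.2
    seed: int = 0
    split_source: str = "random"  # "random" | "fixture_labels"

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ConfigurationError("n_hidden must be >= 1")
        if not 0 < self.holdback_fraction < 1:
            raise ConfigurationError("holdback_fraction must lie in (0, 1)")


@dataclass
class AnnModel:
    """Trained network weights plus the input/output scalers."""

    W1: np.ndarray  # H x k
    b1: np.ndarray  # H
    w2: np.ndarray  # H
    b2: float
    y_low: float
    y_high: float
    training_history: List[float] = field(default_factory=list)

    def predict(self, coded: np.ndarray) -> np.ndarray:
        """Predicted response (original units) at coded points."""
        X = np.atleast_2d(np.asarray(coded, float))
        hidden = np.tanh(X @ self.W1.T + self.b1)
        scaled = hidden @ self.w2 + self.b2
        return scaled * (self.y_high - self.y_low) + self.y_low

    def to_dict(self) -> dict:
        return {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "y_low": self.y_low,
            "y_high": self.y_high,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnModel":
        return cls(
            W1=np.asarray(d["W1"], float),
            b1=np.asarray(d["b1"], float),
            w2=np.asarray(d["w2"], float),
            b2=float(d["b2"]),
            y_low=float(d["y_low"]),
            y_high=float(d["y_high"]),
        )


@dataclass
class AnnMetrics:
    """Fit metrics per split; RASE/AAE are the overall-data names for
    RMSE/MAD. The Gaussian profile -log-likelihood n/2 (ln(2 pi s2) + 1)
    with s2 = SSE/n follows the reporting convention of common statistical
    software, which is what makes small-residual fits report negative
    values."""

    r2: float
    rmse: float
    mad: float
    sse: float
    neg_log_likelihood: float
    n: int


def _metrics(obs: np.ndarray, pred: np.ndarray) -> AnnMetrics:
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    n = len(obs)
    e = obs - pred
    sse = float(e @ e)
    sst = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    rmse = float(np.sqrt(sse / n))
    mad = float(np.abs(e).mean())
    s2 = sse / n
    nll = 0.5 * n * (np.log(2 * np.pi * s2) + 1.0) if s2 > 0 else -np.inf
    return AnnMetrics(r2=r2, rmse=rmse, mad=mad, sse=sse, neg_log_likelihood=float(nll), n=n)


def evaluate(model: AnnModel, coded: np.ndarray, obs: np.ndarray) -> AnnMetrics:
    """Metrics of a trained model on any set of coded points."""
    return _metrics(obs, model.predict(coded))


def split_holdback(design: CcrdDesign, config: AnnConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Training/validation index arrays.

    ``random``: a seeded uniform holdback of round(n * fraction) runs.
    ``fixture_labels``: the split labels stored on the design's runs.
    """
    n = design.n_runs
    if n < 5:
        raise ConfigurationError(f"need at least 5 runs to hold back, got {n}")
    if config.split_source == "fixture_labels":
        labels = design.splits()
        if any(s is None for s in labels):
            raise ConfigurationError("design carries no split labels")
        val = np.array([i for i, s in enumerate(labels) if s == "validation"])
        tr = np.array([i for i, s in enumerate(labels) if s == "training"])
    else:
        n_val = int(round(n * config.holdback_fraction))
        if n_val == 0 or n_val == n:
            raise ConfigurationError("holdback fraction yields an empty split")
        rng = np.random.default_rng(config.seed)
        val = np.sort(rng.choice(n, size=n_val, replace=False))
        tr = np.array([i for i in range(n) if i not in set(val.tolist())])
    if len(tr) == 0 or len(val) == 0:
        raise ConfigurationError("holdback produced an empty split")
    return tr, val


def _train_tour(
    X: np.ndarray, y: np.ndarray, H: int, lr0: float, max_epochs: int, rng: np.random.Generator
):
    """One restart of full-batch gradient descent; returns weights + loss."""
    n, k = X.shape
    W1 = rng.normal(0.0, 1.0 / np.sqrt(k), size=(H, k))
    b1 = np.zeros(H)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(H), size=H)
    b2 = 0.0
    lr = lr0
    A = np.tanh(X @ W1.T + b1)
    pred = A @ w2 + b2
    loss = float(((pred - y) ** 2).sum())
    history = [loss]
    for _ in range(max_epochs):
        r = 2.0 * (pred - y)
        g_w2 = A.T @ r
        g_b2 = float(r.sum())
        dA = np.outer(r, w2) * (1.0 - A * A)
        g_W1 = dA.T @ X
        g_b1 = dA.sum(axis=0)
        gnorm = np.sqrt(
            float((g_W1**2).sum() + (g_b1**2).sum() + (g_w2**2).sum() + g_b2**2)
        )
        if gnorm < 1e-10:
            break
        W1n, b1n = W1 - lr * g_W1, b1 - lr * g_b1
        w2n, b2n = w2 - lr * g_w2, b2 - lr * g_b2
        An = np.tanh(X @ W1n.T + b1n)
        predn = An @ w2n + b2n
        lossn = float(((predn - y) ** 2).sum())
        if not np.isfinite(lossn):
            return None  # diverged
        if lossn < loss:
            W1, b1, w2, b2, A, pred, loss = W1n, b1n, w2n, b2n, An, predn, lossn
            history.append(loss)
        else:
            lr = max(lr / 2.0, 1e-6)
    return W1, b1, w2, b2, loss, history


def train(design: CcrdDesign, config: AnnConfig) -> Tuple[AnnModel, Dict[str, AnnMetrics]]:
    """Train the surrogate; returns the best-tour model and split metrics."""
    tr, val = split_holdback(design, config)
    Xc = design.coded_matrix()
    y = design.responses()
    y_low, y_high = float(y.min()), float(y.max())
    if y_high <= y_low:
        raise ConfigurationError("response has no range; cannot scale")
    ys = (y - y_low) / (y_high - y_low)
    Xtr, ytr = Xc[tr], ys[tr]
    Xval, yval = Xc[val], ys[val]

    rng = np.random.default_rng(config.seed)
    best = None
    best_sel = np.inf
    diverged = 0
    for _ in range(config.tours):
        out = _train_tour(Xtr, ytr, config.n_hidden, config.learning_rate, config.max_epochs, rng)
        if out is None:
            diverged += 1
            continue
        W1, b1, w2, b2, loss, history = out
        pv = np.tanh(Xval @ W1.T + b1) @ w2 + b2
        val_sse = float(((pv - yval) ** 2).sum())
        sel = val_sse if len(val) else loss
        if sel < best_sel:
            best_sel = sel
            best = (W1, b1, w2, b2, history)
    if best is None:
        raise TrainingFailureError(f"all {config.tours} tours diverged")
    W1, b1, w2, b2, history = best
    model = AnnModel(
        W1=W1, b1=b1, w2=w2, b2=b2, y_low=y_low, y_high=y_high, training_history=history
    )
    metrics = {
        "training": evaluate(model, Xc[tr], y[tr]),
        "validation": evaluate(model, Xc[val], y[val]),
        "overall": evaluate(model, Xc, y),
    }
    if diverged:
        metrics["diverged_tours"] = diverged
    return model, metrics


def ann_optimize(
    model: AnnModel,
    bounds: Tuple[float, float] = (-2.0, 2.0),
    resolution: int = 9,
    polish: bool = True,
    response_low: Optional[float] = None,
    response_high: Optional[float] = None,
) -> dict:
    """Maximize the network prediction over the coded box.

    Dense grid search (the default box is the axial region, where a trained
    surrogate may place its optimum at a boundary), optionally polished
    with Nelder-Mead. The Derringer maximize ramp shared with the
    response-surface optimizer converts the best prediction into a
    desirability score.
    """
    from scipy.optimize import minimize

    k = model.W1.shape[1]
    ax = np.linspace(bounds[0], bounds[1], resolution)
    mesh = np.meshgrid(*([ax] * k), indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    pred = model.predict(pts)
    i = int(np.argmax(pred))
    x_best, y_best = pts[i], float(pred[i])
    if polish:
        res = minimize(
            lambda x: -float(model.predict(np.clip(x, bounds[0], bounds[1]))[0]),
            x_best,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
        )
        cand = np.clip(res.x, bounds[0], bounds[1])
        y_cand = float(model.predict(cand)[0])
        if y_cand > y_best:
            x_best, y_best = cand, y_cand
    lo = model.y_low if response_low is None else response_low
    hi = model.y_high if response_high is None else response_high
    d = 0.0 if y_best <= lo else 1.0 if y_best >= hi else ((y_best - lo) / (hi - lo))
    return {"coded_opt": x_best, "predicted": y_best, "desirability": float(d)}


def compare_models(
    ccrd_fit: QuadraticFit, ann_model: AnnModel, design: CcrdDesign
) -> dict:
    """Side-by-side predictive-capability report on the same design.

    Emits overall R^2, RASE and AAE per model plus a per-run table of
    observed/predicted/residual values, mirroring how hybrid RSM-vs-ANN
    studies tabulate their comparison.
    """
    Xc = design.coded_matrix()
    y = design.responses()
    pred_ccrd = ccrd_fit.predict_many(Xc)
    pred_ann = ann_model.predict(Xc)
    m_ccrd = _metrics(y, pred_ccrd)
    m_ann = _metrics(y, pred_ann)
    table = []
    for run, yo, pc, pa in zip(design.runs, y, pred_ccrd, pred_ann):
        table.append(
            {
                "std": run.std_order,
                "run": run.run_id,
                "actual": float(yo),
                "ccrd_predicted": float(pc),
                "ccrd_residual": float(yo - pc),
                "ann_predicted": float(pa),
                "ann_residual": float(yo - pa),
                "split": run.split,
            }
        )
    return {
        "ccrd": {"r2": m_ccrd.r2, "rase": m_ccrd.rmse, "aae": m_ccrd.mad},
        "ann": {"r2": m_ann.r2, "rase": m_ann.rmse, "aae": m_ann.mad},
        "per_run": table,
    }
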