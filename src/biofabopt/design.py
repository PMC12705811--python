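"""Rotatable central composite designs (CCRD) and coded/actual factor mapping.

A CCRD for k factors consists of a full 2^k factorial core at coded levels
±1, 2k axial (star) points at ±alpha, and replicated center points. With the
rotatable choice alpha = (2^k)^(1/4) the prediction variance of the fitted
second-order model depends only on the distance from the design center.

Coded units are the canonical computational representation: every fit and
optimization in this package happens in coded space, and the affine map

    actual_i = center_i + coded_i * step_i

translates to physical units (pH, mg/mL, h, °C for the bundled study).
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    IntegrityError,
    InvalidDesignError,
    InvalidFactorError,
)

__all__ = [
    "FactorDef",
    "RunPoint",
    "CcrdDesign",
    "generate_ccrd",
    "code",
    "decode",
    "load_yield_study",
    "YIELD_STUDY_FACTORS",
]

Role = Literal["factorial", "axial", "center"]


@dataclass(frozen=True)
class FactorDef:
    """One controllable factor of the experiment.

    ``center`` and ``step`` define the affine coded->actual map: coded 0 is
    the center and one coded unit equals ``step`` actual units.
    """

    name: str
    symbol: str
    center: float
    step: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise InvalidFactorError(f"factor {self.name!r}: step must be > 0, got {self.step}")

    def actual(self, coded: float) -> float:
        return self.center + coded * self.step

    def coded(self, actual: float) -> float:
        return (actual - self.center) / self.step


@dataclass(frozen=True)
class RunPoint:
    """A single experimental run with coded and actual coordinates."""

    run_id: int
    std_order: int
    coded: tuple
    actual: tuple
    role: Role
    response: Optional[float] = None
    split: Optional[str] = None  # "training" | "validation"


@dataclass
class CcrdDesign:
    """A central composite design plus (optionally) observed responses."""

    factors: list
    alpha: float
    n_center: int
    runs: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def coded_matrix(self) -> np.ndarray:
        return np.array([r.coded for r in self.runs], dtype=float)

    def actual_matrix(self) -> np.ndarray:
        return np.array([r.actual for r in self.runs], dtype=float)

    def responses(self) -> np.ndarray:
        return np.array(
            [np.nan if r.response is None else r.response for r in self.runs], dtype=float
        )

    def splits(self) -> list:
        return [r.split for r in self.runs]

    def with_responses(self, y: Sequence[float]) -> "CcrdDesign":
        y = np.asarray(y, dtype=float)
        if y.shape[0] != self.n_runs:
            raise DimensionError(f"expected {self.n_runs} responses, got {y.shape[0]}")
        runs = [replace(r, response=float(v)) for r, v in zip(self.runs, y)]
        return CcrdDesign(self.factors, self.alpha, self.n_center, runs)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the documented CSV dialect column order."""
        rows = []
        for r in self.runs:
            row = {"std": r.std_order, "run": r.run_id, "role": r.role}
            for f, a in zip(self.factors, r.actual):
                row[f.name] = a
            row["yield_mg_ml"] = r.response
            row["split"] = r.split
            rows.append(row)
        return pd.DataFrame(rows)


def generate_ccrd(
    factors: Sequence[FactorDef],
    n_center: int,
    alpha_rule: "float | str" = "rotatable",
) -> CcrdDesign:
    """Build a CCRD in deterministic standard order.

    Standard order: the 2^k factorial core in binary order with the first
    factor varying fastest, then the 2k axial points (low/high per factor),
    then the ``n_center`` center replicates.

    ``alpha_rule`` is either the string ``"rotatable"`` (alpha = (2^k)^(1/4))
    or an explicit positive axial distance.
    """
    factors = list(factors)
    k = len(factors)
    if k < 2:
        raise InvalidDesignError(f"a central composite design needs k >= 2 factors, got {k}")
    if n_center < 1:
        raise InvalidDesignError(f"n_center must be >= 1, got {n_center}")
    if alpha_rule == "rotatable":
        alpha = (2.0**k) ** 0.25
    else:
        alpha = float(alpha_rule)
        if alpha <= 0:
            raise InvalidDesignError(f"explicit alpha must be > 0, got {alpha}")

    runs = []
    std = 1
    # factorial core, first factor fastest (matches the bundled study's table)
    for combo in itertools.product([-1.0, 1.0], repeat=k):
        coded = tuple(reversed(combo))
        runs.append(_mk_run(std, coded, "factorial", factors))
        std += 1
    for i in range(k):
        for s in (-alpha, alpha):
            coded = tuple(s if j == i else 0.0 for j in range(k))
            runs.append(_mk_run(std, coded, "axial", factors))
            std += 1
    for _ in range(n_center):
        runs.append(_mk_run(std, (0.0,) * k, "center", factors))
        std += 1
    return CcrdDesign(factors=factors, alpha=alpha, n_center=n_center, runs=runs)


def _mk_run(std: int, coded: tuple, role: Role, factors: Sequence[FactorDef]) -> RunPoint:
    actual = tuple(f.actual(c) for f, c in zip(factors, coded))
    return RunPoint(run_id=std, std_order=std, coded=coded, actual=actual, role=role)


def code(values: Sequence[float], factors: Sequence[FactorDef]) -> np.ndarray:
    """Map actual factor values to coded units."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != len(factors):
        raise DimensionError(f"expected {len(factors)} values, got {values.shape[-1]}")
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return (values - centers) / steps


def decode(coded: Sequence[float], factors: Sequence[FactorDef]) -> np.ndarray:
    """Map coded factor values to actual units (inverse of :func:`code`)."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(factors):
        raise DimensionError(f"expected {len(factors)} values, got {coded.shape[-1]}")
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return centers + coded * steps


#: The four factors of the bundled collagen-nanoparticle yield study:
#: initial pH, collagen concentration, incubation time, temperature.
YIELD_STUDY_FACTORS = [
    FactorDef("pH", "X1", center=7.0, step=1.0, unit=""),
    FactorDef("collagen_mg_ml", "X2", center=12.0, step=4.0, unit="mg/mL"),
    FactorDef("time_h", "X3", center=72.0, step=24.0, unit="h"),
    FactorDef("temp_c", "X4", center=35.0, step=5.0, unit="degC"),
]

_FIXTURE_NAME = "ccrd_yield.csv"
_FIXTURE_SHA256 = "fffa176dfb1091578ae1027eb7eeb448f3c74053a378318df80cda4cf00c627d"


def load_yield_study() -> CcrdDesign:
    """Load the bundled 30-run CCRD yield dataset.

    Four factors, alpha = 2, six center replicates; responses are the
    observed nanoparticle yields (mg/mL) and each run carries its published
    training/validation label. Runs are ordered by run number; analyses key
    on standard order.
    """
    data = resources.files("biofabopt").joinpath("data", _FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise IntegrityError(
            f"bundled design fixture failed its checksum ({digest} != {_FIXTURE_SHA256})"
        )
    from .io import parse_design_frame  # local import to avoid a cycle

    import io as _io

    df = pd.read_csv(_io.BytesIO(data))
    return parse_design_frame(df, factors=YIELD_STUDY_FACTORS)
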