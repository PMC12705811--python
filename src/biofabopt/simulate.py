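"""Synthetic campaigns with the statistical structure the analysis assumes.

A simulated CCRD campaign draws responses from a known second-order
polynomial in coded units plus i.i.d. Gaussian noise, which is exactly the
model the response-surface fit estimates — so coefficient recovery,
confidence-interval coverage and lack-of-fit test size are all directly
checkable. Defaults mirror the bundled yield study: its four factors, six
center replicates, its fitted quadratic coefficients as the true surface,
and a noise standard deviation of 0.163 mg/mL (the study's residual scale).

Dose-response and tumor-table generators provide the same service for the
bioassay computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bioassay import TumorRecord
from .design import CcrdDesign, FactorDef, YIELD_STUDY_FACTORS, generate_ccrd
from .errors import DimensionError, DomainError
from .rsm import model_row

__all__ = [
    "YIELD_STUDY_BETA",
    "YIELD_STUDY_SIGMA",
    "SimulationSpec",
    "simulate_campaign",
    "simulate_dose_response",
    "simulate_tumor_table",
]

#: True quadratic surface used by default: the yield study's fitted
#: second-order polynomial in coded units (intercept, X1..X4, the six
#: pairwise interactions in lexicographic order, then the four squares).
YIELD_STUDY_BETA = np.array(
    [11.66, 0.44, 1.57, -0.41, -0.63, -0.21, 0.08, -0.02, -0.32, -0.13, -0.19,
     -1.42, -0.97, -0.88, -0.79]
)

#: Default noise sd (mg/mL), the residual scale of the yield study.
YIELD_STUDY_SIGMA = 0.163


def _n_quad_terms(k: int) -> int:
    return 1 + k + k * (k - 1) // 2 + k


@dataclass
class SimulationSpec:
    factors: Sequence[FactorDef] = field(default_factory=lambda: list(YIELD_STUDY_FACTORS))
    true_beta: np.ndarray = field(default_factory=lambda: YIELD_STUDY_BETA.copy())
    noise_sigma: float = YIELD_STUDY_SIGMA
    n_center: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_beta = np.asarray(self.true_beta, float)
        k = len(self.factors)
        if len(self.true_beta) != _n_quad_terms(k):
            raise DimensionError(
                f"true_beta has length {len(self.true_beta)}; "
                f"a quadratic in {k} factors needs {_n_quad_terms(k)} terms"
            )
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")


def simulate_campaign(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> CcrdDesign:
    """One synthetic CCRD campaign: y = m(x)'beta + N(0, sigma^2).

    Negative simulated yields are floored at zero (a yield cannot be
    negative); the floor count is recorded on the returned design as
    ``design.n_floored``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    design = generate_ccrd(spec.factors, n_center=spec.n_center, alpha_rule="rotatable")
    M = np.vstack([model_row(np.asarray(r.coded), "quadratic") for r in design.runs])
    y = M @ spec.true_beta + rng.normal(0.0, spec.noise_sigma, size=design.n_runs)
    n_floored = int((y < 0).sum())
    y = np.clip(y, 0.0, None)
    out = design.with_responses(y)
    out.n_floored = n_floored
    return out


def simulate_dose_response(
    ic50: float,
    hill: float,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Logistic cytotoxicity curve with Gaussian noise, clipped to [0, 100].

    response(d) = 100 / (1 + (ic50/d)^hill), i.e. 50% exactly at the IC50.
    Returns (doses, responses) arrays.
    """
    if ic50 <= 0:
        raise DomainError("ic50 must be positive")
    doses = np.asarray(doses, float)
    rng = np.random.default_rng(seed)
    resp = 100.0 / (1.0 + (ic50 / doses) ** hill)
    resp = resp + rng.normal(0.0, noise_sd, size=doses.shape)
    return doses, np.clip(resp, 0.0, 100.0)


def simulate_tumor_table(
    base_dims: dict,
    inhibition_targets: dict,
    seed: int = 0,
) -> dict:
    """Construct tumor records whose growth inhibition hits given targets.

    ``base_dims`` describes the control group:
    {"L0", "S0", "L20", "S20"} in cm. Each entry of ``inhibition_targets``
    (group -> TGI% in [0, 100]) produces a treated record whose day-20
    volume is set so that unrounded volumes reproduce the target exactly;
    the day-20 short diameter keeps the control's aspect ratio. Day-0
    dimensions get a small seeded jitter, mimicking randomized group
    allocation, with day-20 recomputed so the target still holds.
    """
    rng = np.random.default_rng(seed)
    L0, S0 = base_dims["L0"], base_dims["S0"]
    L20, S20 = base_dims["L20"], base_dims["S20"]
    control = TumorRecord("control", L0, S0, L20, S20)
    v0c, v20c = control.volumes(rounding_dp=None)
    dc = v20c - v0c
    records = {"control": control}
    ratio = S20 / L20
    for group, target in inhibition_targets.items():
        if not 0.0 <= target <= 100.0:
            raise DomainError(f"target for {group!r} must be in [0, 100], got {target}")
        l0 = L0 * (1.0 + rng.uniform(-0.02, 0.02))
        s0 = min(S0 * (1.0 + rng.uniform(-0.02, 0.02)), l0)
        v0 = l0 * s0 * s0 * 0.5
        v20 = v0 + (1.0 - target / 100.0) * dc
        if v20 <= 0:
            raise DomainError(f"target {target} for {group!r} gives a non-positive volume")
        # solve L*(ratio*L)^2/2 = v20 for the day-20 long diameter
        l20 = (2.0 * v20 / ratio**2) ** (1.0 / 3.0)
        s20 = ratio * l20
        if s20 > l20:
            raise DomainError("infeasible geometry: short diameter exceeds long diameter")
        records[group] = TumorRecord(group, l0, s0, l20, s20)
    return records
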