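"""Closed-form assay and tumor effect-size computations.

Absorbance-ratio assays (MTT viability/cytotoxicity, ABTS radical
scavenging, AAPH-induced hemolysis protection), the ellipsoid-style tumor
volume approximation V = L * S^2 / 2 from caliper diameters, and tumor
growth inhibition TGI% = 100 - 100 * dT/dC on volume changes, plus a
log-linear IC50 interpolation helper for dose-response summaries.

Printed tumor tables typically report group-mean diameters and group-mean
volumes side by side; because the volume of mean diameters is not the mean
of per-animal volumes, :class:`TumorRecord` can carry explicit volumes, and
growth inhibition prefers them when present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, NotEstimableError

__all__ = [
    "AbsorbancePair",
    "TumorRecord",
    "viability_pct",
    "cytotoxicity_pct",
    "abts_inhibition_pct",
    "hemolysis_protection_pct",
    "tumor_volume",
    "growth_inhibition_pct",
    "ic50_interpolate",
    "load_tumor_study",
]


@dataclass(frozen=True)
class AbsorbancePair:
    """A test/control absorbance pair from a plate reader."""

    a_test: float
    a_control: float

    def __post_init__(self) -> None:
        if self.a_control <= 0:
            raise DomainError(f"control absorbance must be > 0, got {self.a_control}")
        if self.a_test < 0:
            raise DomainError(f"test absorbance must be >= 0, got {self.a_test}")


def viability_pct(pair: AbsorbancePair) -> float:
    """Cell viability % = 100 * A_test / A_control (MTT convention)."""
    return 100.0 * pair.a_test / pair.a_control


def cytotoxicity_pct(pair: AbsorbancePair) -> float:
    """Cytotoxicity % = 100 - viability %."""
    return 100.0 - viability_pct(pair)


def abts_inhibition_pct(pair: AbsorbancePair) -> float:
    """ABTS radical scavenging % = 100 * (A_control - A_test) / A_control."""
    return 100.0 * (pair.a_control - pair.a_test) / pair.a_control


def hemolysis_protection_pct(pair: AbsorbancePair) -> float:
    """Anti-hemolytic protection % = 100 - 100 * A_sample / A_control."""
    return 100.0 - 100.0 * pair.a_test / pair.a_control


def _round_half_away(x: float, dp: int) -> float:
    q = 10.0**dp
    return math.floor(abs(x) * q + 0.5) / q * (1.0 if x >= 0 else -1.0)


def tumor_volume(
    L: float,
    S: float,
    rounding_dp: Optional[int] = None,
    mode: str = "round",
) -> float:
    """Tumor volume V = L * S^2 * 0.5 from caliper diameters (cm -> cm^3).

    ``rounding_dp`` optionally rounds the result; ``mode`` is ``"round"``
    (half away from zero) or ``"truncate"`` (drop digits). Published mean
    volumes are averages of per-animal volumes and generally cannot be
    regenerated from the printed group-mean diameters under either mode;
    see :class:`TumorRecord` for carrying published volumes directly.
    """
    if L <= 0 or S <= 0:
        raise DomainError(f"diameters must be positive, got L={L}, S={S}")
    if S > L:
        raise DomainError(f"short diameter S={S} exceeds long diameter L={L}")
    v = L * S * S * 0.5
    if rounding_dp is None:
        return v
    if mode == "truncate":
        q = 10.0**rounding_dp
        return math.floor(v * q + 1e-9) / q
    if mode == "round":
        return _round_half_away(v, rounding_dp)
    raise DomainError(f"unknown rounding mode {mode!r}")


@dataclass(frozen=True)
class TumorRecord:
    """Group-level tumor dimensions (cm) at day 0 and day 20.

    ``volume_day0``/``volume_day20`` optionally carry the published mean
    volumes (cm^3); when present they take precedence over recomputing the
    volume from the (possibly rounded mean) diameters.
    """

    group: str
    long_day0: float
    short_day0: float
    long_day20: float
    short_day20: float
    volume_day0: Optional[float] = None
    volume_day20: Optional[float] = None

    def __post_init__(self) -> None:
        for L, S, day in (
            (self.long_day0, self.short_day0, 0),
            (self.long_day20, self.short_day20, 20),
        ):
            if not 0 < S <= L:
                raise DomainError(f"group {self.group!r} day {day}: need 0 < S <= L, got L={L}, S={S}")

    def volumes(self, rounding_dp: Optional[int] = None, mode: str = "round"):
        if self.volume_day0 is not None and self.volume_day20 is not None:
            return float(self.volume_day0), float(self.volume_day20)
        return (
            tumor_volume(self.long_day0, self.short_day0, rounding_dp, mode),
            tumor_volume(self.long_day20, self.short_day20, rounding_dp, mode),
        )


def growth_inhibition_pct(
    control: TumorRecord,
    treated: TumorRecord,
    rounding_dp: Optional[int] = 2,
    mode: str = "round",
) -> float:
    """Tumor growth inhibition % = 100 - 100 * dT/dC.

    dT and dC are the day-20 minus day-0 volume changes of the treated and
    control groups. Volumes are rounded to ``rounding_dp`` before
    differencing (2 dp matches published tables); pass ``rounding_dp=None``
    for full precision.
    """
    c0, c20 = control.volumes(rounding_dp, mode)
    t0, t20 = treated.volumes(rounding_dp, mode)
    dc = c20 - c0
    if dc == 0:
        raise DomainError("control volume change is zero; growth inhibition undefined")
    dt = t20 - t0
    return 100.0 - (dt / dc) * 100.0


def load_tumor_study() -> "list[TumorRecord]":
    """The bundled six-group murine tumor table (EAC control, collagen,
    DOX, nanoparticles, and the two combinations): group-mean caliper
    diameters and published mean volumes at day 0 and day 20."""
    import pandas as pd
    from importlib import resources

    with resources.files("biofabopt").joinpath("data", "tumor_groups.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        TumorRecord(
            group=r.group,
            long_day0=r.L_day0,
            short_day0=r.S_day0,
            long_day20=r.L_day20,
            short_day20=r.S_day20,
            volume_day0=r.vol_day0,
            volume_day20=r.vol_day20,
        )
        for r in df.itertuples()
    ]


def ic50_interpolate(doses: Sequence[float], responses: Sequence[float]) -> float:
    """Log-linear IC50 from a monotone dose-response crossing 50%.

    Interpolates log10(dose) linearly between the two doses bracketing the
    50% response. Deliberately interpolation-only: no sigmoidal curve fit.
    """
    doses = np.asarray(doses, float)
    responses = np.asarray(responses, float)
    if len(doses) != len(responses) or len(doses) < 2:
        raise NotEstimableError("need matching dose/response vectors of length >= 2")
    if (doses <= 0).any():
        raise DomainError("doses must be positive for log interpolation")
    order = np.argsort(doses)
    d, r = doses[order], responses[order]
    hits = np.where(r == 50.0)[0]
    if len(hits):
        return float(d[hits[0]])
    for i in range(len(d) - 1):
        lo, hi = r[i], r[i + 1]
        if (lo - 50.0) * (hi - 50.0) < 0:
            t = (50.0 - lo) / (hi - lo)
            return float(10 ** (np.log10(d[i]) + t * (np.log10(d[i + 1]) - np.log10(d[i]))))
    raise NotEstimableError("responses never cross 50%")
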