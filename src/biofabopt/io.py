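"""CSV/JSON/YAML I/O, report rendering and run configuration.

The design CSV dialect is fixed: UTF-8, comma separators, '.' decimals,
mandatory header ``std,run,role,<factor columns>,yield_mg_ml,split``. The
source tables of designed experiments are typeset, not machine-readable,
so the dialect is stated explicitly and violations fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import CcrdDesign, FactorDef, RunPoint, code
from .errors import SchemaError

__all__ = [
    "read_design_csv",
    "write_design_csv",
    "parse_design_frame",
    "read_factor_config",
    "render_report",
    "RunConfig",
]

_FIXED_COLS = ["std", "run", "role", "yield_mg_ml", "split"]


def read_factor_config(path) -> list:
    """Factor definitions from a YAML/JSON config: a list of mappings with
    name, symbol, center, step, unit."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    data = yaml.safe_load(text)
    return [
        FactorDef(
            name=d["name"],
            symbol=d.get("symbol", f"X{i + 1}"),
            center=float(d["center"]),
            step=float(d["step"]),
            unit=d.get("unit", ""),
        )
        for i, d in enumerate(data)
    ]


def parse_design_frame(df: pd.DataFrame, factors: Sequence[FactorDef]) -> CcrdDesign:
    """Build a design from a dataframe in the documented dialect."""
    factor_cols = [f.name for f in factors]
    required = ["std", "run", "role"] + factor_cols + ["yield_mg_ml"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"design table is missing columns: {missing}")
    for col in factor_cols + ["yield_mg_ml"]:
        bad = df[col].apply(lambda v: not (pd.isna(v) or isinstance(v, (int, float, np.number))))
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise SchemaError(f"non-numeric value in column {col!r} at file row {row}")
    runs = []
    for _, r in df.iterrows():
        actual = tuple(float(r[c]) for c in factor_cols)
        coded = tuple(code(actual, factors))
        resp = None if pd.isna(r["yield_mg_ml"]) else float(r["yield_mg_ml"])
        split = None
        if "split" in df.columns and isinstance(r.get("split"), str):
            split = r["split"].strip().lower() or None
        runs.append(
            RunPoint(
                run_id=int(r["run"]),
                std_order=int(r["std"]),
                coded=coded,
                actual=actual,
                role=str(r["role"]),
                response=resp,
                split=split,
            )
        )
    coded_mat = np.array([r.coded for r in runs])
    alpha = float(np.abs(coded_mat).max()) if len(runs) else 1.0
    n_center = sum(1 for r in runs if all(abs(c) < 1e-12 for c in r.coded))
    return CcrdDesign(factors=list(factors), alpha=alpha, n_center=n_center, runs=runs)


def read_design_csv(path, factors: Sequence[FactorDef]) -> CcrdDesign:
    """Read a design CSV in the documented dialect."""
    try:
        df = pd.read_csv(path, dtype={"split": "string"})
    except Exception as exc:  # malformed file
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        if df[col].dtype == object and col not in ("role", "split"):
            # locale comma decimals and similar must fail, not misread
            raise SchemaError(f"column {col!r} contains non-numeric text (comma decimals?)")
    return parse_design_frame(df, factors)


def write_design_csv(design: CcrdDesign, path) -> None:
    """Write a design in the same dialect (lossless round-trip)."""
    df = design.to_frame()
    df.to_csv(path, index=False, float_format="%.12g")


def file_sha256(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    input_path: str
    output_dir: str = "."
    model: str = "quadratic"
    bounds: str = "factorial"
    seed: int = 0
    n_starts: int = 10
    ann_hidden: int = 20
    ann_tours: int = 50
    ann_lr: float = 0.1
    ann_holdback: float = 0.2
    ann_split: str = "random"
    verbosity: int = 1
    extras: dict = field(default_factory=dict)


def _fmt(v, nd=2):
    if v is None:
        return ""
    return f"{v:.{nd}f}"


def render_report(
    anova_table,
    fit_summary=None,
    optimum=None,
    ann_report=None,
    seed: Optional[int] = None,
    input_checksum: Optional[str] = None,
) -> "tuple[str, dict]":
    """Fixed-width text report plus a full-precision JSON document.

    The text table mirrors the conventional ANOVA layout of DoE software:
    model row, per-term rows, lack of fit, pure error, and the adequacy
    statistics block. Sections for the fit summary, the desirability
    optimum and the ANN comparison render only when supplied.
    """
    lines = []
    lines.append(f"biofabopt v{__version__} analysis report")
    if seed is not None:
        lines.append(f"seed: {seed}")
    if input_checksum is not None:
        lines.append(f"input sha256: {input_checksum}")
    lines.append("")
    lines.append("ANOVA (coded units, partial SS)")
    hdr = f"{'Source':<14}{'SS':>10}{'df':>5}{'MS':>10}{'F':>10}{'p':>9}"
    lines.append(hdr)
    lines.append("-" * len(hdr))
    for row in anova_table.rows:
        lines.append(
            f"{row.source:<14}{_fmt(row.ss):>10}{row.df:>5}"
            f"{_fmt(row.ms):>10}{_fmt(row.f):>10}"
            f"{_fmt(row.p, 4):>9}"
        )
    lines.append("")
    lines.append(
        f"R2 {anova_table.r2:.4f}  adj R2 {anova_table.adj_r2:.4f}  "
        f"pred R2 {anova_table.pred_r2:.4f}  PRESS {_fmt(anova_table.press)}"
    )
    lines.append(
        f"Std Dev {_fmt(anova_table.std_dev)}  Mean {_fmt(anova_table.mean)}  "
        f"CV% {_fmt(anova_table.cv_percent)}  Adeq Precision {anova_table.adeq_precision:.1f}"
    )
    doc = {
        "version": __version__,
        "seed": seed,
        "input_sha256": input_checksum,
        "anova": anova_table.to_dict(),
    }
    if fit_summary is not None:
        lines.append("")
        lines.append(f"Fit summary: suggested model = {fit_summary.suggested}")
        for m, s in fit_summary.summary.items():
            lines.append(
                f"  {m:<10} adjR2 {s['adj_r2']:.4f}  predR2 {s['pred_r2']:.4f}  "
                f"PRESS {s['press']:.2f}"
            )
        doc["fit_summary"] = {
            "sequential": fit_summary.sequential,
            "lack_of_fit": fit_summary.lack_of_fit,
            "summary": fit_summary.summary,
            "suggested": fit_summary.suggested,
        }
    if optimum is not None:
        lines.append("")
        lines.append(
            f"Desirability optimum: predicted {optimum.predicted_response:.2f} "
            f"(d = {optimum.desirability:.4f}) at coded "
            + np.array2string(np.asarray(optimum.coded_opt), precision=3)
        )
        doc["optimum"] = {
            "coded": list(map(float, optimum.coded_opt)),
            "actual": list(map(float, optimum.actual_opt)),
            "predicted_response": optimum.predicted_response,
            "desirability": optimum.desirability,
        }
    if ann_report is not None:
        lines.append("")
        lines.append(
            f"Model comparison (overall): CCRD R2 {ann_report['ccrd']['r2']:.4f} "
            f"RASE {ann_report['ccrd']['rase']:.4f} | ANN R2 {ann_report['ann']['r2']:.4f} "
            f"RASE {ann_report['ann']['rase']:.4f}"
        )
        doc["comparison"] = {k: ann_report[k] for k in ("ccrd", "ann")}
    return "\n".join(lines) + "\n", doc


def write_json(doc: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
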