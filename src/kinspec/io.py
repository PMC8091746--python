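"""File I/O, run configuration, and report rendering.

Canonical curves CSV schema (long format, one row per reading)::

    sample_id,concentration_ug_ml,time_s,absorbance[,replicate,wavelength_nm]

``concentration_ug_ml`` is empty for unknown samples. Times are seconds;
``read_curves_csv(..., time_unit="minutes")`` converts minute-labelled
inputs on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel
from .errors import DataError
from .kinetics import AbsorbanceTimeCurve, KineticSeriesSet
from .validation import MethodComparison, RecoveryRow, SensitivityMetrics

__all__ = [
    "RunConfig",
    "read_curves_csv",
    "write_curves_csv",
    "render_report",
    "load_run_config",
]

REQUIRED_COLUMNS = ("sample_id", "concentration_ug_ml", "time_s", "absorbance")


@dataclass(frozen=True)
class RunConfig:
    """Parameters steering one calibration/validation run."""

    method: str = "fixed_time"
    fixed_time: float = 600.0  # s
    fixed_absorbance: float = 1.2  # AU
    confidence: float = 95.0  # %
    window_end: float = 600.0  # s, initial-rate tangent window
    filter_enabled: bool = False  # relative-response screen
    seed: int = 0
    molar_mass: float = 461.44  # g/mol

    def __post_init__(self) -> None:
        if self.method not in {"initial_rate", "rate_constant", "fixed_absorbance", "fixed_time"}:
            raise DataError("bad-method", f"unknown method {self.method!r}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise DataError("schema-error", "config file must hold a mapping")
    return RunConfig(**data)


def read_curves_csv(path: str | Path, time_unit: str = "seconds") -> KineticSeriesSet:
    """Read a long-format curves CSV into a :class:`KineticSeriesSet`.

    Rows are grouped by ``sample_id`` and sorted by time (with a warning
    when the file was unsorted). Duplicate (sample, time) pairs are
    rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError("schema-error", f"missing column(s): {', '.join(missing)}")
    if time_unit == "minutes":
        df = df.assign(time_s=df["time_s"] * 60.0)
    elif time_unit != "seconds":
        raise DataError("bad-time-unit", f"unknown time unit {time_unit!r}")
    if df.duplicated(subset=["sample_id", "time_s"]).any():
        raise DataError("duplicate-timepoint", "duplicate (sample_id, time_s) rows")
    curves = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        if not grp["time_s"].is_monotonic_increasing:
            warnings.warn(f"{sample_id}: rows were unsorted; sorted by time", stacklevel=2)
            grp = grp.sort_values("time_s")
        conc = grp["concentration_ug_ml"].iloc[0]
        conc = None if pd.isna(conc) else float(conc)
        curves.append(AbsorbanceTimeCurve(
            sample_id=str(sample_id),
            times=grp["time_s"].to_numpy(dtype=float),
            absorbances=grp["absorbance"].to_numpy(dtype=float),
            concentration=conc,
            wavelength=float(grp["wavelength_nm"].iloc[0]) if "wavelength_nm" in grp else 350.0,
            replicate_index=int(grp["replicate"].iloc[0]) if "replicate" in grp else 0,
        ))
    return KineticSeriesSet(curves=curves)


def write_curves_csv(series: KineticSeriesSet, path: str | Path) -> None:
    """Write a series set to the canonical long-format CSV."""
    rows = []
    for curve in series.curves:
        for t, a in zip(curve.times, curve.absorbances):
            rows.append({
                "sample_id": curve.sample_id,
                "concentration_ug_ml": curve.concentration,
                "time_s": t,
                "absorbance": a,
                "replicate": curve.replicate_index,
                "wavelength_nm": curve.wavelength,
            })
    # %.17g is round-trip exact for float64
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# report rendering


def _round(x: float | None, nd: int) -> float | None:
    return None if x is None else round(x, nd)


def _bundle_to_dict(bundle: dict[str, Any]) -> dict[str, Any]:
    """Normalize a results bundle to plain JSON-serializable structures."""
    out: dict[str, Any] = {}
    cal = bundle.get("calibration")
    if cal is not None:
        out["calibration"] = cal.to_dict() if isinstance(cal, CalibrationModel) else cal
    sens = bundle.get("sensitivity")
    if sens is not None:
        if isinstance(sens, SensitivityMetrics):
            sens = {
                "lod_ug_ml": sens.lod, "loq_ug_ml": sens.loq,
                "epsilon_l_mol_cm": sens.epsilon, "sigma_au": sens.sigma_used,
                "slope_au_per_ug_ml": sens.slope_used,
                "molar_mass_g_mol": sens.molar_mass, "path_cm": sens.path_length,
            }
        out["sensitivity"] = sens
    rows = bundle.get("recovery")
    if rows is not None:
        out["recovery"] = [
            {
                "taken_ug_ml": r.taken, "found_mean_ug_ml": r.found_mean,
                "sd_ug_ml": r.sd, "rsd_pct": r.rsd_pct,
                "recovery_pct": r.recovery_pct, "n": r.n_replicates,
            } if isinstance(r, RecoveryRow) else r
            for r in rows
        ]
    comp = bundle.get("comparison")
    if comp is not None:
        if isinstance(comp, MethodComparison):
            comp = {
                "t_stat": comp.t_stat, "f_stat": comp.f_stat,
                "t_crit": comp.t_crit, "f_crit": comp.f_crit,
                "confidence_pct": comp.confidence,
                "df_t": comp.df_t, "df_f": list(comp.df_f),
                "mean_a": comp.mean_a, "mean_b": comp.mean_b,
                "sd_a": comp.sd_a, "sd_b": comp.sd_b,
                "significant_t": comp.significant_t,
                "significant_f": comp.significant_f,
            }
        out["comparison"] = comp
    for key in bundle:
        if key not in out and key not in {"calibration", "sensitivity", "recovery", "comparison"}:
            out[key] = bundle[key]
    return out


def _fmt(x: Any) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:g}"
    return str(x)


def render_report(bundle: dict[str, Any], format: str = "json") -> str:
    """Render a results bundle as JSON or Markdown.

    Output is deterministic (stable key and column order). JSON stores full
    precision and round-trips losslessly; Markdown rounds to conventional
    table precision (two decimals for percentages). The recovery table uses
    the column order Taken, Found, SD, RSD %, % Recovery.
    """
    data = _bundle_to_dict(bundle)
    if format == "json":
        return json.dumps(data, indent=2, sort_keys=True)
    if format != "markdown":
        raise DataError("bad-format", f"unknown format {format!r}")
    lines: list[str] = ["# Kinetic assay report", ""]
    if "calibration" in data:
        c = data["calibration"]
        lines += [
            "## Calibration",
            "",
            f"- method: {c['method']}",
            f"- regression: y = {c['slope']:.6g} x + {c['intercept']:.6g}",
            f"- r^2: {c['r2']:.4f}",
            f"- linear range: {c['linear_range'][0]:g}-{c['linear_range'][1]:g} ug/ml",
            "",
        ]
    if "sensitivity" in data:
        s = data["sensitivity"]
        lines += [
            "## Sensitivity",
            "",
            f"- LOD: {s['lod_ug_ml']:.2f} ug/ml",
            f"- LOQ: {s['loq_ug_ml']:.2f} ug/ml",
            f"- molar absorptivity: {s['epsilon_l_mol_cm']:.4g} L/(mol cm)",
            "",
        ]
    if "recovery" in data:
        lines += [
            "## Accuracy and precision",
            "",
            "| Taken | Found | SD | RSD % | % Recovery |",
            "|---|---|---|---|---|",
        ]
        for r in data["recovery"]:
            lines.append(
                "| " + " | ".join(_fmt(v) for v in (
                    r["taken_ug_ml"], r["found_mean_ug_ml"], r["sd_ug_ml"],
                    _round(r["rsd_pct"], 2), _round(r["recovery_pct"], 2),
                )) + " |"
            )
        lines.append("")
    if "comparison" in data:
        c = data["comparison"]
        verdict_t = "significant" if c["significant_t"] else "not significant"
        verdict_f = "significant" if c["significant_f"] else "not significant"
        lines += [
            "## Method comparison",
            "",
            f"- t = {c['t_stat']:.3f} vs t_crit = {c['t_crit']:.3f} ({verdict_t})",
            f"- F = {c['f_stat']:.3f} vs F_crit = {c['f_crit']:.3f} ({verdict_f})",
            f"- confidence: {c['confidence_pct']:g}%",
            "",
        ]
    return "\n".join(lines)
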