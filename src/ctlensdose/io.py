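"""CSV input, run configuration and report writing.

The procedure CSV is long-format: one row per dosimeter reading (six rows
per procedure), with the procedure metadata repeated.  Columns::

    procedure_id, profession, practice, area, tube_voltage_kVp,
    tube_current_mA, ctdi_vol_mGy, dlp_mGy_cm, extension_tube,
    placement, side, orientation, air_kerma_mGy

Reports mirror the campaign's result tables: orientation (V/H) and
bilateral (R/L) ratio checks, by-profession and by-area summaries with the
nonparametric tests, per-practice compliance projections, and the three
protection-efficiency estimates with their multiplicative combination.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dose_analysis as da
from . import stats as st
from .hp3_conversion import DosimeterReading

__all__ = [
    "RunConfig",
    "CsvSchemaError",
    "COLUMNS",
    "read_procedures",
    "write_procedures",
    "run_analysis",
    "write_report",
]

logger = logging.getLogger(__name__)

COLUMNS = [
    "procedure_id",
    "profession",
    "practice",
    "area",
    "tube_voltage_kVp",
    "tube_current_mA",
    "ctdi_vol_mGy",
    "dlp_mGy_cm",
    "extension_tube",
    "placement",
    "side",
    "orientation",
    "air_kerma_mGy",
]


class CsvSchemaError(ValueError):
    """Raised for missing columns or unparseable rows in a procedure CSV."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    ``annual_limit`` is the 5-year-average annual eye-lens equivalent-dose
    limit (20 mSv); ``single_year_limit`` the any-single-year cap (50 mSv).
    """

    k_coefficient: float = 1.650
    annual_limit: float = 20.0
    single_year_limit: float = 50.0

    def __post_init__(self) -> None:
        if self.k_coefficient <= 0:
            raise ValueError("k_coefficient must be > 0")
        if self.annual_limit <= 0 or self.single_year_limit <= 0:
            raise ValueError("dose limits must be > 0")
        if self.annual_limit > self.single_year_limit:
            raise ValueError("annual_limit must not exceed single_year_limit")


def write_procedures(records, path) -> None:
    """Write records to the long-format CSV (six rows per procedure)."""
    rows = []
    for rec in records:
        for r in rec.readings:
            rows.append(
                {
                    "procedure_id": rec.procedure_id,
                    "profession": rec.profession,
                    "practice": rec.practice,
                    "area": rec.area,
                    "tube_voltage_kVp": rec.tube_voltage,
                    "tube_current_mA": rec.tube_current,
                    "ctdi_vol_mGy": rec.ctdi_vol,
                    "dlp_mGy_cm": rec.dlp,
                    "extension_tube": rec.extension_tube,
                    "placement": r.placement,
                    "side": r.side,
                    "orientation": r.orientation,
                    "air_kerma_mGy": r.air_kerma,
                }
            )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def read_procedures(path, skip_bad: bool = False):
    """Read and validate a long-format procedure CSV.

    Row-level errors are collected with line numbers; the run aborts on any
    error unless ``skip_bad``, in which case offending *procedures* are
    dropped with a warning.
    """
    df = pd.read_csv(path, dtype={"procedure_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CsvSchemaError(f"missing required column(s): {missing}")
    errors: list[str] = []
    procedures: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        pid = row["procedure_id"]
        try:
            reading = DosimeterReading(
                placement=str(row["placement"]),
                side=str(row["side"]),
                orientation=str(row["orientation"]),
                air_kerma=float(row["air_kerma_mGy"]),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line} (procedure {pid}): {exc}")
            procedures.setdefault(pid, {"meta": None, "readings": [], "bad": False})["bad"] = True
            continue
        entry = procedures.setdefault(pid, {"meta": None, "readings": [], "bad": False})
        entry.setdefault("readings", []).append(reading)
        meta = dict(
            profession=str(row["profession"]),
            practice=str(row["practice"]),
            area=str(row["area"]),
            tube_voltage=float(row["tube_voltage_kVp"]),
            tube_current=float(row["tube_current_mA"]),
            ctdi_vol=float(row["ctdi_vol_mGy"]),
            dlp=float(row["dlp_mGy_cm"]),
            extension_tube=_parse_bool(row["extension_tube"]),
        )
        entry["meta"] = meta

    records = []
    for pid, entry in procedures.items():
        if entry.get("bad"):
            continue
        try:
            records.append(
                da.ProcedureRecord(procedure_id=pid, readings=entry["readings"], **entry["meta"])
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"procedure {pid}: {exc}")
    if errors:
        msg = f"{len(errors)} invalid row(s)/procedure(s):\n" + "\n".join(errors)
        if not skip_bad:
            raise CsvSchemaError(msg)
        logger.warning("read_procedures: skipping bad input. %s", msg)
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def _summary_dict(s: da.GroupSummary) -> dict:
    return {
        "n": s.n,
        "mean": _sig(s.mean),
        "sd": _sig(s.sd),
        "median": _sig(s.median),
        "range": [_sig(s.min), _sig(s.max)],
        "q25": _sig(s.q25),
        "q75": _sig(s.q75),
        "ci95": [_sig(s.ci95[0]), _sig(s.ci95[1])],
    }


def _sig(x: float, digits: int = 4) -> float:
    """Round to a fixed number of significant digits for diff-stable reports."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    from math import floor, log10

    return round(float(x), -int(floor(log10(abs(x)))) + digits - 1)


def _test_dict(res: st.TestResult) -> dict:
    out = {"statistic": _sig(res.statistic), "df": res.df, "p_value": _sig(res.p_value)}
    if res.pairwise:
        out["pairwise"] = [
            {
                "pair": [p.label_a, p.label_b],
                "z": _sig(p.z),
                "p_raw": _sig(p.p_raw),
                "p_adjusted": _sig(p.p_adjusted),
            }
            for p in res.pairwise
        ]
    return out


def run_analysis(records, config: RunConfig | None = None, curtain=None) -> dict:
    """Run the full per-procedure pipeline and assemble the report dict.

    ``curtain`` is an optional pair of arrays (without, with) of phantom
    doses; the curtain section is reported as unmeasured when absent.
    """
    cfg = config or RunConfig()
    records = list(records)
    if not records:
        raise ValueError("no procedure records to analyze")
    k = cfg.k_coefficient
    warnings: list[str] = []

    results = {rec.procedure_id: rec.hp3(k) for rec in records}

    # orientation (V/H) ratio check per side, inside the glasses
    vh = {}
    for side in ("left", "right"):
        pairs = []
        for rec in records:
            slots = {(r.placement, r.side, r.orientation): r.air_kerma for r in rec.readings}
            pairs.append(
                (slots[("inside", side, "vertical")], slots[("inside", side, "horizontal")])
            )
        try:
            summary, excluded = da.paired_ratio_summary(pairs)
            vh[side] = {**_summary_dict(summary), "excluded": excluded}
            if excluded:
                warnings.append(f"V/H ratio ({side}): {excluded} zero-denominator pair(s) excluded")
        except ValueError as exc:
            vh[side] = {"error": str(exc)}
            warnings.append(f"V/H ratio ({side}): {exc}")

    # bilateral (right/left) ratio check per placement, after orientation max
    bilateral = {}
    for placement in ("outside", "inside"):
        pairs = []
        for rec in records:
            slots = {(r.placement, r.side, r.orientation): r.air_kerma for r in rec.readings}
            if placement == "outside":
                left = slots[("outside", "left", "none")]
                right = slots[("outside", "right", "none")]
            else:
                left = max(slots[("inside", "left", "vertical")], slots[("inside", "left", "horizontal")])
                right = max(slots[("inside", "right", "vertical")], slots[("inside", "right", "horizontal")])
            pairs.append((right, left))
        try:
            summary, excluded = da.paired_ratio_summary(pairs)
            bilateral[placement] = {**_summary_dict(summary), "excluded": excluded}
            if excluded:
                warnings.append(f"bilateral ratio ({placement}): {excluded} exclusion(s)")
        except ValueError as exc:
            bilateral[placement] = {"error": str(exc)}
            warnings.append(f"bilateral ratio ({placement}): {exc}")

    # by-profession summaries + Kruskal-Wallis / Dunn
    by_prof: dict = {}
    quantities = {
        "hp3_outside_mSv": lambda rec: results[rec.procedure_id].hp3_outside,
        "hp3_inside_mSv": lambda rec: results[rec.procedure_id].hp3_inside,
        "tube_voltage_kVp": lambda rec: rec.tube_voltage,
        "tube_current_mA": lambda rec: rec.tube_current,
        "ctdi_vol_mGy": lambda rec: rec.ctdi_vol,
        "dlp_mGy_cm": lambda rec: rec.dlp,
    }
    prof_groups = {
        p: [rec for rec in records if rec.profession == p]
        for p in da.PROFESSIONS
        if any(rec.profession == p for rec in records)
    }
    for qname, getter in quantities.items():
        entry = {
            prof: _summary_dict(da.group_summary([getter(r) for r in recs]))
            for prof, recs in prof_groups.items()
        }
        if len(prof_groups) >= 2:
            grouped = st.GroupedValues(
                tuple((prof, [getter(r) for r in recs]) for prof, recs in prof_groups.items())
            )
            entry["kruskal_wallis"] = _test_dict(st.kruskal_wallis(grouped))
            entry["dunn"] = _test_dict(st.dunn_bonferroni(grouped))
        by_prof[qname] = entry

    # by-area dose comparison
    by_area: dict = {}
    area_groups = {
        a: [rec for rec in records if rec.area == a]
        for a in da.AREAS
        if any(rec.area == a for rec in records)
    }
    for qname in ("hp3_outside_mSv", "hp3_inside_mSv"):
        getter = quantities[qname]
        entry = {
            area: _summary_dict(da.group_summary([getter(r) for r in recs]))
            for area, recs in area_groups.items()
        }
        if len(area_groups) >= 2:
            grouped = st.GroupedValues(
                tuple((a, [getter(r) for r in recs]) for a, recs in area_groups.items())
            )
            entry["kruskal_wallis"] = _test_dict(st.kruskal_wallis(grouped))
            entry["dunn"] = _test_dict(st.dunn_bonferroni(grouped))
        by_area[qname] = entry

    # per-practice compliance projection
    compliance: dict = {}
    for practice in da.PRACTICES:
        recs = [r for r in records if r.practice == practice]
        if not recs:
            continue
        entry = {}
        for placement, getter in (
            ("outside", lambda r: results[r.procedure_id].hp3_outside),
            ("inside", lambda r: results[r.procedure_id].hp3_inside),
        ):
            s = da.group_summary([getter(r) for r in recs])
            if s.median > 0:
                rep = da.ComplianceReport(
                    annual_limit=cfg.annual_limit,
                    median_dose=s.median,
                    max_procedures=da.max_procedures(cfg.annual_limit, s.median),
                )
                entry[placement] = {
                    "median_mSv": _sig(rep.median_dose),
                    "range_mSv": [_sig(s.min), _sig(s.max)],
                    "annual_limit_mSv": cfg.annual_limit,
                    "max_procedures": rep.max_procedures,
                }
            else:
                entry[placement] = {"median_mSv": 0.0, "max_procedures": None}
                warnings.append(f"compliance ({practice}/{placement}): zero median dose, unbounded")
        compliance[practice] = entry

    # protection efficiencies
    efficiencies: dict = {}
    try:
        ratio, percent = da.glasses_efficiency(records, k)
        efficiencies["glasses"] = {
            "median_ratio_outside_inside": _sig(ratio),
            "reduction_percent": percent,
            "reduction_fraction": _sig((ratio - 1) / ratio),
        }
    except ValueError as exc:
        efficiencies["glasses"] = {"error": str(exc)}
        warnings.append(f"glasses efficiency: {exc}")
    try:
        out_pct, in_pct = da.tube_efficiency(records, k)
        efficiencies["extension_tube"] = {
            "reduction_percent_outside": out_pct,
            "reduction_percent_inside": in_pct,
        }
    except ValueError as exc:
        efficiencies["extension_tube"] = {"error": str(exc)}
        warnings.append(f"extension-tube efficiency: {exc}")
    if curtain is not None:
        without, with_ = (np.asarray(a, dtype=float) for a in curtain)
        pct = da.reduction_from_pair(float(without.mean()), float(with_.mean()))
        efficiencies["curtain"] = {
            "mean_without_mSv": _sig(float(without.mean())),
            "sd_without_mSv": _sig(float(without.std(ddof=1))) if without.size > 1 else 0.0,
            "mean_with_mSv": _sig(float(with_.mean())),
            "sd_with_mSv": _sig(float(with_.std(ddof=1))) if with_.size > 1 else 0.0,
            "n": int(without.size),
            "reduction_percent": pct,
        }
    else:
        efficiencies["curtain"] = {"status": "not measured (no phantom pairs supplied)"}
        warnings.append("curtain efficiency: no phantom measurements supplied")

    fractions = []
    if "reduction_fraction" in efficiencies.get("glasses", {}):
        fractions.append(("glasses", efficiencies["glasses"]["reduction_fraction"]))
    if "reduction_percent_inside" in efficiencies.get("extension_tube", {}):
        fractions.append(
            ("extension_tube", efficiencies["extension_tube"]["reduction_percent_inside"] / 100.0)
        )
    if "reduction_percent" in efficiencies.get("curtain", {}):
        fractions.append(("curtain", efficiencies["curtain"]["reduction_percent"] / 100.0))
    combined = {}
    usable = {n: f for n, f in fractions if 0 <= f < 1}
    if {"glasses", "extension_tube"} <= usable.keys():
        combined["glasses_tube_percent"] = da.combine_measures(
            [usable["glasses"], usable["extension_tube"]]
        )
        if "curtain" in usable:
            combined["glasses_tube_curtain_percent"] = da.combine_measures(
                [usable["glasses"], usable["extension_tube"], usable["curtain"]]
            )
        combined["measures"] = sorted(usable)
    efficiencies["combined"] = combined

    return {
        "config": {
            "k_coefficient": cfg.k_coefficient,
            "annual_limit_mSv": cfg.annual_limit,
            "single_year_limit_mSv": cfg.single_year_limit,
        },
        "n_procedures": len(records),
        "vh_ratio": vh,
        "bilateral_ratio": bilateral,
        "by_profession": by_prof,
        "by_area": by_area,
        "compliance": compliance,
        "glasses": efficiencies["glasses"],
        "extension_tube": efficiencies["extension_tube"],
        "curtain": efficiencies["curtain"],
        "combined_measures": efficiencies["combined"],
        "warnings": warnings,
    }


def _flatten(prefix: str, obj, rows: list) -> None:
    if isinstance(obj, dict):
        for key, val in obj.items():
            _flatten(f"{prefix}.{key}" if prefix else str(key), val, rows)
    elif isinstance(obj, (list, tuple)):
        rows.append({"key": prefix, "value": json.dumps(obj)})
    else:
        rows.append({"key": prefix, "value": obj})


def _markdown(report: dict) -> str:
    lines = ["# Eye-lens dose analysis report", ""]
    lines.append(f"Procedures analyzed: {report['n_procedures']}  ")
    lines.append(f"Conversion coefficient K: {report['config']['k_coefficient']} Sv/Gy")
    lines.append("")
    lines.append("## Compliance projection")
    lines.append("")
    lines.append("| Practice | Placement | Median Hp(3) [mSv] | Max procedures/year |")
    lines.append("|---|---|---|---|")
    for practice, entry in report["compliance"].items():
        for placement, vals in entry.items():
            lines.append(
                f"| {practice} | {placement} | {vals['median_mSv']} | {vals['max_procedures']} |"
            )
    lines.append("")
    lines.append("## Protection efficiencies")
    lines.append("")
    for name in ("glasses", "extension_tube", "curtain", "combined_measures"):
        lines.append(f"- **{name}**: `{json.dumps(report[name])}`")
    if report["warnings"]:
        lines.append("")
        lines.append("## Warnings")
        for w in report["warnings"]:
            lines.append(f"- {w}")
    lines.append("")
    return "\n".join(lines)


def write_report(report: dict, path, format: str = "json") -> None:
    """Serialize a report as json, csv (flattened key/value) or markdown."""
    path = str(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
            fh.write("\n")
    elif format == "csv":
        rows: list = []
        _flatten("", report, rows)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif format == "markdown":
        with open(path, "w") as fh:
            fh.write(_markdown(report))
    else:
        raise ValueError(f"unknown report format {format!r}; choose json, csv or markdown")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
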