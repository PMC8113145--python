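"""Patient-table CSV I/O, display rounding, and flow reports."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import FlowSummary
from .stats import ConfusionMetrics

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "read_patient_table",
    "write_patient_table",
    "round_half_away",
    "report",
]

REQUIRED_COLUMNS = ("patient_id", "label", "rCBV_max", "TBR_max", "TBR_mean",
                    "Slope_suv_per_h", "TTP_min")
_NUMERIC = ("rCBV_max", "TBR_max", "TBR_mean", "Slope_suv_per_h", "TTP_min")


class SchemaError(ValueError):
    """The patient table violates the required CSV schema."""


def _normalize_labels(raw: pd.Series) -> pd.Series:
    labels = raw.astype(str).str.strip().str.upper()
    bad = sorted(set(labels.unique()) - {"TP", "TRC"})
    if bad:
        raise SchemaError(f"label column contains values other than TP/TRC: {bad}")
    return labels


def read_patient_table(path) -> pd.DataFrame:
    """Read and validate a patient parameter table (comma-separated, UTF-8).

    Labels are normalized (trimmed, case-folded to TP/TRC); unknown columns
    are preserved.  Missing required columns and non-numeric parameter
    values raise a SchemaError naming the offender.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df["label"] = _normalize_labels(df["label"])
    for col in _NUMERIC:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-numeric value in column {col!r} at data row {row}")
        df[col] = parsed
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise SchemaError(f"duplicate patient_id {dup!r}")
    return df


def write_patient_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (0.625 -> 0.63 at 2 digits, 86.5 -> 87 at 0)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _fmt_rate(value: float | None) -> str:
    return "n.a." if value is None else f"{round_half_away(value, 2):.2f}"


def _metrics_lines(name: str, m: ConfusionMetrics) -> list[str]:
    return [
        f"{name}: tp={m.tp} fp={m.fp} tn={m.tn} fn={m.fn}",
        f"  sens={_fmt_rate(m.sens)} spec={_fmt_rate(m.spec)} "
        f"acc={_fmt_rate(m.acc)} ppv={_fmt_rate(m.ppv)} npv={_fmt_rate(m.npv)}",
    ]


def report(flow: FlowSummary, table2_stats=None, path=None) -> dict:
    """Write the flow summary as JSON (full precision) + text (display rounding).

    The text mirrors the flow diagram: the full cohort, the stage-1 TP box,
    the unclassified box, and the two stage-2 boxes, with rates rounded half
    away from zero to 2 decimals and headline accuracy to integer percent.
    Returns the JSON-ready dict.
    """
    if flow.n_total == 0:
        raise ValueError("refusing to report on an empty cohort")
    payload = {"flow": _jsonable(flow)}
    if table2_stats is not None:
        payload["parameter_stats"] = _jsonable(table2_stats)

    lines = [
        f"cohort n={flow.n_total}",
        f"stage 1 (rCBV rule) calls TP: n={flow.n_stage1_tp}",
        f"left unclassified: n={flow.n_remaining}",
        f"stage 2 (PET rule) calls TP: n={flow.n_stage2_tp}",
        f"stage 2 calls TRC: n={flow.n_stage2_trc}",
    ]
    lines += _metrics_lines("stage-1-only", flow.stage1_metrics)
    if flow.stage2_metrics is not None:
        lines += _metrics_lines("stage-2 subset", flow.stage2_metrics)
    lines += _metrics_lines("sequential overall", flow.overall_metrics)
    acc = flow.overall_metrics.acc
    sens = flow.overall_metrics.sens
    lines.append(
        f"headline: accuracy {round_half_away(100 * acc):.0f}%"
        + (f", sensitivity {round_half_away(100 * sens):.0f}%" if sens is not None else ""))
    text = "\n".join(lines) + "\n"

    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.with_suffix(".json").write_text(json.dumps(payload, indent=2), encoding="utf-8")
        path.with_suffix(".txt").write_text(text, encoding="utf-8")
    payload["text"] = text
    return payload
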