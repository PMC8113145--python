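"""Per-parameter diagnostic summaries over a patient table.

For each imaging parameter: class medians and unscaled MADs, the
Mann-Whitney intergroup p-value, ROC AUC with DeLong CI and p, and the
optimal cutoff (max sensitivity * specificity) with its confusion-metric
block.  Subgroup analysis (e.g. by IDH status) is just the same summary on
a cohort filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import SequentialCutoffs, classify_combined_pet
from .stats import confusion, mann_whitney, optimal_cutoff, roc_auc

__all__ = ["PARAMETER_DIRECTIONS", "unscaled_mad", "parameter_stats", "subgroup_stats"]

#: ROC direction per parameter: which tail indicates progression
PARAMETER_DIRECTIONS = {
    "rCBV_max": "higher",
    "TBR_max": "higher",
    "TBR_mean": "higher",
    "Slope_suv_per_h": "lower",
    "TTP_min": "higher",
}


def unscaled_mad(x) -> float:
    """median(|x - median(x)|), without the 1.4826 consistency factor."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def _calls_at_cutoff(scores: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    pos = scores > cutoff if direction == "higher" else scores < cutoff
    return np.where(pos, "TP", "TRC")


def parameter_stats(cohort: pd.DataFrame,
                    parameters=tuple(PARAMETER_DIRECTIONS)) -> dict[str, dict]:
    """Full diagnostic summary of each parameter on a labeled cohort."""
    labels = cohort["label"].to_numpy()
    out: dict[str, dict] = {}
    for name in parameters:
        direction = PARAMETER_DIRECTIONS[name]
        scores = cohort[name].to_numpy(dtype=float)
        x_tp = scores[labels == "TP"]
        x_trc = scores[labels == "TRC"]
        u, p_mw = mann_whitney(x_tp, x_trc)
        curve, auc = roc_auc(scores, labels, direction=direction)
        try:
            best = optimal_cutoff(curve)
            cm = confusion(_calls_at_cutoff(scores, best.cutoff, direction), labels)
            cutoff, metrics = best.cutoff, cm
        except ValueError:  # constant marker: no informative threshold exists
            cutoff, metrics = None, None
        out[name] = {
            "median_tp": float(np.median(x_tp)),
            "mad_tp": unscaled_mad(x_tp),
            "median_trc": float(np.median(x_trc)),
            "mad_trc": unscaled_mad(x_trc),
            "mw_u": u,
            "mw_p": p_mw,
            "auc": auc.auc,
            "auc_ci95": auc.ci95,
            "auc_p": auc.p,
            "direction": direction,
            "cutoff": cutoff,
            "metrics": metrics,
        }
    return out


def combined_pet_stats(cohort: pd.DataFrame, cutoffs: SequentialCutoffs) -> dict:
    """Metric block for the and/or-combined PET rule (TBR_max a/o Slope)."""
    calls = np.array([classify_combined_pet(row, cutoffs)
                      for _, row in cohort.iterrows()])
    return {"metrics": confusion(calls, cohort["label"].to_numpy())}


def subgroup_stats(cohort: pd.DataFrame, group_by: str = "idh_status",
                   parameters=tuple(PARAMETER_DIRECTIONS)) -> dict[str, dict]:
    """parameter_stats per subgroup; subgroups missing a class are skipped."""
    out = {}
    for key, sub in cohort.groupby(group_by):
        if sub["label"].nunique() < 2:
            continue
        out[str(key)] = parameter_stats(sub, parameters)
    return out
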