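"""Static and dynamic parameters from amino-acid PET time-activity curves.

An [18F]FET time-activity curve (TAC) carries tumor mean/max and background
mean activity concentrations per frame.  Activities convert to standardized
uptake values (SUV = concentration * body weight / injected activity); from
the SUV curves we derive the tumor-to-brain ratios (TBR_mean, TBR_max), the
time-to-peak (TTP, minutes) and the late slope 20-40 min post-injection
(SUV/h) whose low or negative values mark the washout pattern typical of
tumor progression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Tac", "PetParams", "suv", "tbr", "ttp", "slope_20_40", "pet_params"]

SLOPE_WINDOW_MIN = (20.0, 40.0)


@dataclass(frozen=True)
class Tac:
    """ROI-level PET time-activity curve.

    Frame mid-times in minutes post-injection; activities in Bq/g; patient
    weight in grams and injected activity in Bq for SUV scaling.
    """

    frame_mid_times: np.ndarray
    tumor_mean_activity: np.ndarray
    tumor_max_activity: np.ndarray
    background_mean_activity: np.ndarray
    patient_weight: float
    injected_activity: float

    def __post_init__(self):
        t = np.asarray(self.frame_mid_times, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("frame_mid_times must be 1-D, length >= 2, strictly increasing")
        for name in ("tumor_mean_activity", "tumor_max_activity", "background_mean_activity"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != t.shape:
                raise ValueError(f"{name} must match frame_mid_times in length")
        if self.patient_weight <= 0 or self.injected_activity <= 0:
            raise ValueError("patient_weight and injected_activity must be positive")


@dataclass(frozen=True)
class PetParams:
    """Derived PET parameters: ratios are dimensionless, ttp in minutes, slope in SUV/h."""

    tbr_mean: float
    tbr_max: float
    ttp: float
    slope: float


def suv(activity_concentration, weight: float, injected: float):
    """Standardized uptake value: concentration [Bq/g] * weight [g] / injected [Bq]."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    if injected <= 0:
        raise ValueError("injected activity must be positive")
    return np.asarray(activity_concentration, dtype=float) * weight / injected


def _window_index(tac: Tac, window: tuple[float, float]) -> np.ndarray:
    t = np.asarray(tac.frame_mid_times, dtype=float)
    lo, hi = window
    return (t >= lo) & (t <= hi)


def tbr(tac: Tac, window: tuple[float, float] = SLOPE_WINDOW_MIN) -> tuple[float, float]:
    """Mean and maximum tumor-to-brain ratios over an evaluation window.

    tbr_mean = time-averaged tumor mean SUV / time-averaged background SUV;
    tbr_max likewise with the tumor max curve.  Dose and weight cancel, so
    the ratios are computed on activities directly.
    """
    idx = _window_index(tac, window)
    if not idx.any():
        raise ValueError(f"window {window} overlaps no frames")
    bg = float(np.mean(np.asarray(tac.background_mean_activity, dtype=float)[idx]))
    if bg <= 0:
        raise ValueError("background activity must be positive in the window")
    tm = float(np.mean(np.asarray(tac.tumor_mean_activity, dtype=float)[idx]))
    tx = float(np.mean(np.asarray(tac.tumor_max_activity, dtype=float)[idx]))
    return tm / bg, tx / bg


def ttp(tac: Tac) -> float:
    """Frame mid-time (minutes) of the tumor mean curve's maximum; ties take the earliest."""
    values = np.asarray(tac.tumor_mean_activity, dtype=float)
    return float(np.asarray(tac.frame_mid_times, dtype=float)[int(np.argmax(values))])


def slope_20_40(tac: Tac, window: tuple[float, float] = SLOPE_WINDOW_MIN) -> float:
    """OLS slope of tumor mean SUV vs time over 20-40 min, in SUV per hour.

    Frames are weighted equally; the per-minute slope is scaled by 60.
    """
    idx = _window_index(tac, window)
    if idx.sum() < 2:
        raise ValueError(f"need >= 2 frames with mid-times in {window}, got {int(idx.sum())}")
    t = np.asarray(tac.frame_mid_times, dtype=float)[idx]
    s = suv(np.asarray(tac.tumor_mean_activity, dtype=float)[idx],
            tac.patient_weight, tac.injected_activity)
    slope_per_min = np.polyfit(t, s, 1)[0]
    return float(slope_per_min * 60.0)


def pet_params(tac: Tac, window: tuple[float, float] = SLOPE_WINDOW_MIN) -> PetParams:
    """All four PET parameters for one TAC."""
    tbr_mean, tbr_max = tbr(tac, window)
    return PetParams(tbr_mean=tbr_mean, tbr_max=tbr_max, ttp=ttp(tac),
                     slope=slope_20_40(tac, window))
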