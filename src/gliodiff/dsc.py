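"""Leakage-corrected CBV quantification from dynamic susceptibility contrast MRI.

The gadolinium bolus transiently raises the transverse relaxation rate; the
change dR2*(t) = -ln(S(t)/S0)/TE integrates to a quantity proportional to
cerebral blood volume (CBV).  Where the blood-brain barrier is disrupted,
contrast extravasation biases the curve; the Boxerman-Weisskoff model fits
each target curve as K1 * (nonenhancing reference curve) - K2 * (running
integral of the reference) and adds the K2 term back to correct the CBV.
The hotspot relative CBV (rCBV_max) is the mean of the k highest tumor CBV
values divided by the CBV of an equally sized contralateral
normal-appearing-tissue ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

__all__ = [
    "DscAcquisition",
    "DscSeries",
    "DeltaR2Series",
    "LeakageFit",
    "CbvResult",
    "delta_r2star",
    "reference_curve",
    "bw_fit",
    "cbv_integrate",
    "hotspot_rcbv",
]


@dataclass(frozen=True)
class DscAcquisition:
    """Echo-planar DSC acquisition parameters.

    te/tr in seconds; ``baseline_window`` is a 0-based half-open frame range
    preceding bolus arrival, used to estimate the pre-contrast signal S0.
    """

    te: float
    tr: float
    n_frames: int
    baseline_window: tuple[int, int] = (0, 8)

    def __post_init__(self):
        if self.te <= 0:
            raise ValueError("te must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        lo, hi = self.baseline_window
        if not (0 <= lo < hi <= self.n_frames):
            raise ValueError(f"baseline_window {self.baseline_window} invalid for "
                             f"{self.n_frames} frames")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr


@dataclass(frozen=True)
class DscSeries:
    """Dynamic signal for one ROI (1-D) or voxel block (frames x voxels)."""

    times: np.ndarray
    signal: np.ndarray
    acquisition: DscAcquisition

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        s = np.asarray(self.signal, dtype=float)
        if s.shape[0] != t.size:
            raise ValueError("signal first axis must match times")


@dataclass(frozen=True)
class DeltaR2Series:
    """Baseline-referenced transverse relaxation-rate change, 1/s per frame."""

    times: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class LeakageFit:
    """Boxerman-Weisskoff fit: target ~ k1*reference - k2*integral(reference)."""

    k1: float
    k2: float
    corrected: DeltaR2Series
    residual_sse: float


@dataclass(frozen=True)
class CbvResult:
    cbv_tumor: float
    cbv_reference: float
    rcbv_max: float


def delta_r2star(series: DscSeries) -> DeltaR2Series:
    """Convert a DSC signal curve to dR2*(t) = -ln(S/S0)/TE.

    S0 is the mean signal over the acquisition's baseline window, so the
    baseline frames average to zero by construction.
    """
    s = np.asarray(series.signal, dtype=float)
    bad = np.nonzero(s <= 0)
    if bad[0].size:
        raise ValueError(f"nonpositive signal at frame index {int(bad[0][0])}")
    lo, hi = series.acquisition.baseline_window
    s0 = s[lo:hi].mean(axis=0)
    values = -np.log(s / s0) / series.acquisition.te
    return DeltaR2Series(times=np.asarray(series.times, dtype=float), values=values)


def reference_curve(series_set, mask=None) -> DeltaR2Series:
    """Pointwise mean dR2* over the included (nonenhancing) series."""
    series_set = list(series_set)
    if mask is not None:
        series_set = [s for s, keep in zip(series_set, mask, strict=True) if keep]
    if not series_set:
        raise ValueError("reference_curve requires at least one included series")
    times = series_set[0].times
    for s in series_set[1:]:
        if not np.array_equal(s.times, times):
            raise ValueError("all series must share one time grid")
    values = np.mean([s.values for s in series_set], axis=0)
    return DeltaR2Series(times=times, values=values)


def running_integral(curve: DeltaR2Series) -> np.ndarray:
    """Cumulative trapezoid integral of the curve, zero at the first frame."""
    return cumulative_trapezoid(curve.values, curve.times, initial=0.0)


def bw_fit(target: DeltaR2Series, reference: DeltaR2Series) -> LeakageFit:
    """Boxerman-Weisskoff leakage fit of a target dR2* curve.

    Solves min over (k1, k2) of sum_t [target(t) - k1*ref(t) + k2*R(t)]^2
    where R(t) is the running trapezoid integral of the reference; the 2x2
    normal equations are solved in closed form.  The corrected curve is
    target(t) + k2*R(t): for T1-dominant leakage (k2 > 0) the raw curve is
    depressed and the correction restores area.
    """
    if not np.array_equal(target.times, reference.times):
        raise ValueError("target and reference must share one time grid")
    ref = np.asarray(reference.values, dtype=float)
    if np.allclose(ref, 0.0):
        raise ValueError("reference curve is identically zero")
    if np.ptp(ref) == 0.0:
        # a flat reference carries no bolus shape; the fit is meaningless
        raise ValueError("degenerate fit: constant reference curve")
    big_r = running_integral(reference)
    design = np.column_stack([ref, -big_r])
    gram = design.T @ design
    if np.linalg.matrix_rank(gram) < 2 or np.linalg.cond(gram) > 1e12:
        raise ValueError("degenerate fit: reference and its integral are collinear")
    k1, k2 = np.linalg.solve(gram, design.T @ target.values)
    resid = target.values - design @ np.array([k1, k2])
    corrected = DeltaR2Series(times=target.times, values=target.values + k2 * big_r)
    return LeakageFit(k1=float(k1), k2=float(k2), corrected=corrected,
                      residual_sse=float(resid @ resid))


def cbv_integrate(curve: DeltaR2Series, window: tuple[int, int] | None = None) -> float:
    """Trapezoidal area of dR2* over a frame window (negative lobes included).

    ``window`` is a 0-based half-open frame range; None integrates the whole
    curve.
    """
    n = len(curve.values)
    lo, hi = (0, n) if window is None else window
    if not (0 <= lo < hi <= n):
        raise ValueError(f"window {window} out of range for {n} frames")
    if hi - lo < 2:
        raise ValueError("integration window must span at least 2 frames")
    return float(trapezoid(curve.values[lo:hi], curve.times[lo:hi]))


def hotspot_rcbv(cbv_values, tumor_mask, contralateral_mask, k: int = 10) -> CbvResult:
    """Hotspot rCBV_max from per-voxel CBV values.

    Tumor CBV is the mean of the k largest values inside the tumor mask
    (algorithmic stand-in for the visually placed maximum-CBV ROI); the
    reference is the mean over the first k contralateral voxels in fixed
    index order, emulating an equally sized normal-appearing-tissue ROI.
    """
    cbv = np.asarray(cbv_values, dtype=float).ravel()
    tmask = np.asarray(tumor_mask, dtype=bool).ravel()
    cmask = np.asarray(contralateral_mask, dtype=bool).ravel()
    if cbv.shape != tmask.shape or cbv.shape != cmask.shape:
        raise ValueError("cbv_values and masks must have identical shapes")
    if np.any(tmask & cmask):
        raise ValueError("tumor and contralateral masks overlap")
    if tmask.sum() < k or cmask.sum() < k:
        raise ValueError(f"both masks need at least k={k} voxels")
    tumor_vals = np.sort(cbv[tmask])[-k:]
    ref_vals = cbv[cmask][:k]
    cbv_tumor = float(tumor_vals.mean())
    cbv_reference = float(ref_vals.mean())
    if cbv_reference <= 0:
        raise ValueError("non-physical reference CBV <= 0")
    return CbvResult(cbv_tumor=cbv_tumor, cbv_reference=cbv_reference,
                     rcbv_max=cbv_tumor / cbv_reference)
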