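"""Synthetic cohorts for the sequential PWI + dynamic PET workflow.

Real per-patient imaging parameters for this diagnostic problem are rarely
shared, so the pipeline is exercised on synthetic cohorts built three ways:

* parameter mode — class-conditional draws of the five imaging parameters
  (rCBV_max, TBR_max, TBR_mean, Slope, TTP) calibrated so each class
  reproduces a target median and unscaled median absolute deviation (MAD),
  with an optional Gaussian-copula correlation between rCBV_max and TBR_max;
* curve mode — ROI-level dynamic susceptibility contrast signals with a
  gamma-variate bolus plus a leakage term matching the Boxerman-Weisskoff
  model, and PET time-activity curves with an exactly linear 20-40 min
  phase, so every derived parameter can be recovered and checked against
  ground truth;
* a deterministic 104-patient fixture (83 progression / 21 treatment-related
  change) whose parameter values are placed around the cutoffs 2.85 / 1.95 /
  0.69 so the two-stage rule produces the reference patient flow
  44 / 60 / 49 / 11 and its confusion arithmetic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.stats import norm

from .dsc import DscAcquisition, DscSeries
from .pet import Tac

__all__ = [
    "CalibrationError",
    "ClassDistribution",
    "CohortConfig",
    "PatientTruth",
    "lognormal_from_median_mad",
    "normal_sigma_from_mad",
    "table2_distributions",
    "gen_parameter_cohort",
    "gen_fig4_fixture",
    "gen_binormal_scores",
    "gen_dsc_roi_curves",
    "gen_tac",
    "PARAMETER_COLUMNS",
    "REFERENCE_CUTOFFS",
]

PARAMETER_COLUMNS = ("rCBV_max", "TBR_max", "TBR_mean", "Slope_suv_per_h", "TTP_min")

#: the published operating points of the two-stage rule (rCBV, TBR_max, Slope)
REFERENCE_CUTOFFS = (2.85, 1.95, 0.69)

# z-quantile linking the unscaled MAD of a normal to its SD: MAD = sigma * PHI^-1(3/4)
_Z75 = norm.ppf(0.75)


class CalibrationError(ValueError):
    """No distribution in the family matches the requested median/MAD."""


def lognormal_from_median_mad(median: float, mad: float) -> tuple[float, float]:
    """Calibrate a lognormal to a given median and unscaled MAD.

    Returns (mu, sigma) with exp(mu) = median and
    P(|X - median| <= mad) = 1/2, the defining property of the MAD, solved
    by root-finding on sigma to ~1e-12.  Requires mad < median: otherwise
    median - mad <= 0 and no lognormal satisfies the MAD identity in this
    parameterization.
    """
    if median <= 0 or mad <= 0:
        raise CalibrationError("median and mad must be positive")
    if mad >= median:
        raise CalibrationError(f"mad ({mad}) must be smaller than median ({median})")
    mu = float(np.log(median))

    def coverage_gap(sigma: float) -> float:
        hi = norm.cdf((np.log(median + mad) - mu) / sigma)
        lo = norm.cdf((np.log(median - mad) - mu) / sigma)
        return (hi - lo) - 0.5

    lo_s, hi_s = 1e-6, 10.0
    if coverage_gap(lo_s) < 0 or coverage_gap(hi_s) > 0:
        raise CalibrationError(f"no sigma in ({lo_s}, {hi_s}) matches median={median}, mad={mad}")
    sigma = brentq(coverage_gap, lo_s, hi_s, xtol=1e-13, rtol=8.9e-16)
    return mu, float(sigma)


def normal_sigma_from_mad(mad: float) -> float:
    """SD of a normal with the given unscaled MAD (MAD = sigma * PHI^-1(3/4))."""
    if mad <= 0:
        raise CalibrationError("mad must be positive")
    return float(mad / _Z75)


@dataclass(frozen=True)
class ClassDistribution:
    """One class-conditional marginal, parameterized by median and MAD.

    ``family`` is "lognormal" (strictly positive parameters) or "normal"
    (Slope, which can be negative).  ``direction`` records whether high or
    low values indicate progression; it is carried through to ROC analysis
    but does not affect sampling.
    """

    family: str
    median: float
    mad: float
    direction: str = "higher"

    def __post_init__(self):
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mad <= 0:
            raise ValueError("mad (scale) must be positive")
        if self.family == "lognormal" and self.median <= 0:
            raise ValueError("lognormal requires a positive median")

    def transform_standard_normal(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal draws to this marginal (monotone, for copula use)."""
        if self.family == "lognormal":
            mu, sigma = lognormal_from_median_mad(self.median, self.mad)
            return np.exp(mu + sigma * z)
        return self.median + normal_sigma_from_mad(self.mad) * z

    @property
    def log_sigma(self) -> float:
        if self.family != "lognormal":
            raise ValueError("log_sigma only defined for lognormal")
        return lognormal_from_median_mad(self.median, self.mad)[1]


def table2_distributions() -> dict[str, tuple[ClassDistribution, ClassDistribution]]:
    """Default class-conditional distributions (TP, TRC) for the five parameters.

    Medians and MADs match the study summaries; positive-valued parameters
    are lognormal, Slope is normal (its values straddle zero), and TTP is
    identically distributed in both classes (it did not discriminate).
    """
    ln, no = "lognormal", "normal"
    return {
        "rCBV_max": (ClassDistribution(ln, 2.90, 1.00), ClassDistribution(ln, 2.03, 0.52)),
        "TBR_max": (ClassDistribution(ln, 2.20, 0.40), ClassDistribution(ln, 1.90, 0.40)),
        "TBR_mean": (ClassDistribution(ln, 2.00, 0.20), ClassDistribution(ln, 1.90, 0.20)),
        "Slope_suv_per_h": (ClassDistribution(no, 0.23, 0.45, "lower"),
                            ClassDistribution(no, 0.74, 0.41, "lower")),
        "TTP_min": (ClassDistribution(ln, 32.5, 5.00), ClassDistribution(ln, 32.5, 5.00)),
    }


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``dist_per_parameter`` maps each parameter column to its (TP, TRC)
    distribution pair; ``corr_rcbv_tbr`` is the target observed-scale
    Pearson correlation between rCBV_max and TBR_max within each class,
    realized through a Gaussian copula.
    """

    n_tp: int = 83
    n_trc: int = 21
    dist_per_parameter: dict[str, tuple[ClassDistribution, ClassDistribution]] = field(
        default_factory=table2_distributions)
    seed: int = 0
    mode: str = "parameter"
    corr_rcbv_tbr: float = 0.55
    idh_probs: tuple[float, float, float] = (0.317, 0.664, 0.019)  # mutant, wildtype, unknown

    def __post_init__(self):
        if self.n_tp < 0 or self.n_trc < 0 or self.n_tp + self.n_trc < 2:
            raise ValueError("need n_tp >= 0, n_trc >= 0 and n_tp + n_trc >= 2")
        missing = set(PARAMETER_COLUMNS) - set(self.dist_per_parameter)
        if missing:
            raise ValueError(f"missing distributions for parameters: {sorted(missing)}")
        if self.mode not in ("parameter", "curve", "fixture"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _copula_rho(target_r: float, d1: ClassDistribution, d2: ClassDistribution) -> float:
    """Normal-scale correlation producing Pearson r = target on the observed scale.

    For a bivariate lognormal, r = (exp(rho*s1*s2) - 1) /
    sqrt((exp(s1^2)-1)(exp(s2^2)-1)); invert for rho.  Normal marginals pass
    the correlation through unchanged.
    """
    if target_r == 0.0:
        return 0.0
    if d1.family == "lognormal" and d2.family == "lognormal":
        s1, s2 = d1.log_sigma, d2.log_sigma
        arg = 1.0 + target_r * np.sqrt(np.expm1(s1 ** 2) * np.expm1(s2 ** 2))
        if arg <= 0:
            raise CalibrationError(f"correlation {target_r} unattainable for these marginals")
        rho = float(np.log(arg) / (s1 * s2))
    else:
        rho = float(target_r)
    if not -1.0 < rho < 1.0:
        raise CalibrationError(f"required copula correlation {rho:.3f} outside (-1, 1)")
    return rho


def _sample_class(n: int, label: str, cls_idx: int, config: CohortConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    params = list(PARAMETER_COLUMNS)
    p = len(params)
    corr = np.eye(p)
    i = params.index("rCBV_max")
    j = params.index("TBR_max")
    d_i = config.dist_per_parameter["rCBV_max"][cls_idx]
    d_j = config.dist_per_parameter["TBR_max"][cls_idx]
    rho = _copula_rho(config.corr_rcbv_tbr, d_i, d_j)
    corr[i, j] = corr[j, i] = rho
    z = rng.standard_normal((n, p)) @ np.linalg.cholesky(corr).T
    data = {}
    for k, name in enumerate(params):
        data[name] = config.dist_per_parameter[name][cls_idx].transform_standard_normal(z[:, k])
    df = pd.DataFrame(data)
    df.insert(0, "label", label)
    return df


def gen_parameter_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a labeled parameter-level cohort; reproducible under a fixed seed."""
    if config.mode != "parameter":
        raise ValueError("gen_parameter_cohort requires mode='parameter'")
    rng = np.random.default_rng(config.seed)
    parts = []
    if config.n_tp:
        parts.append(_sample_class(config.n_tp, "TP", 0, config, rng))
    if config.n_trc:
        parts.append(_sample_class(config.n_trc, "TRC", 1, config, rng))
    df = pd.concat(parts, ignore_index=True)
    n = len(df)
    df.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(n)])
    probs = np.asarray(config.idh_probs, dtype=float)
    probs = probs / probs.sum()
    df["idh_status"] = rng.choice(["mutant", "wildtype", "unknown"], size=n, p=probs)
    df["group"] = "all"
    return df


def gen_fig4_fixture() -> pd.DataFrame:
    """Deterministic 104-patient cohort reproducing the reference patient flow.

    83 progression (TP) / 21 treatment-related change (TRC); values sit at
    +-0.10 around the cutoffs (2.85, 1.95, 0.69), never on them, so the
    strict-inequality rule partitions the cohort into exactly:

    * stage 1 (rCBV_max > 2.85): 44 patients, all truly TP;
    * stage 2 on the remaining 60 (39 TP, 21 TRC): the combined PET rule
      (TBR_max > 1.95 or Slope < 0.69) calls 49 TP (37 true TP + 12 TRC)
      and 11 TRC (9 true TRC + 2 TP),

    giving 81/83 overall sensitivity, 9/21 specificity, 90/104 accuracy,
    37/39 stage-2 sensitivity and 9/11 stage-2 NPV.  The same value grid
    makes the fitted optimal cutoffs land exactly on 2.85 / 1.95 / 0.69
    (single midpoints between the two distinct values per parameter).
    """
    rc_hi, rc_lo = 2.95, 2.75
    tbr_hi, tbr_lo = 2.05, 1.85
    sl_lo, sl_hi = 0.59, 0.79
    # (count, label, rCBV, TBR_max, Slope)
    groups = [
        (44, "TP", rc_hi, tbr_hi, sl_lo),    # stage-1 TP calls
        (37, "TP", rc_lo, tbr_hi, sl_lo),    # stage-2 true positives
        (2, "TP", rc_lo, tbr_lo, sl_hi),     # stage-2 false negatives
        (12, "TRC", rc_lo, tbr_hi, sl_hi),   # stage-2 false positives
        (9, "TRC", rc_lo, tbr_lo, sl_hi),    # stage-2 true negatives
    ]
    rows = []
    for count, label, rcbv, tbr_max, slope in groups:
        for _ in range(count):
            rows.append({
                "label": label,
                "rCBV_max": rcbv,
                "TBR_max": tbr_max,
                "TBR_mean": 2.00 if label == "TP" else 1.90,
                "Slope_suv_per_h": slope,
                "TTP_min": 32.5,
            })
    df = pd.DataFrame(rows)
    df.insert(0, "patient_id", [f"F{i + 1:03d}" for i in range(len(df))])
    # deterministic scattered IDH assignment: 33 mutant, 69 wildtype, 2 unknown
    perm = np.random.default_rng(20160201).permutation(len(df))
    idh = np.array(["wildtype"] * len(df), dtype=object)
    idh[perm[:33]] = "mutant"
    idh[perm[33:35]] = "unknown"
    df["idh_status"] = idh
    df["group"] = "all"
    return df


def gen_binormal_scores(auc: float, n_per_class: int, direction: str = "higher",
                        rng: np.random.Generator | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Two-class unit-variance normal scores with an exact population AUC.

    The positive class is shifted by sqrt(2) * PHI^-1(auc) — upward for
    higher-positive markers, downward for lower-positive ones — which makes
    the binormal AUC equal to ``auc`` by construction.  Returns (scores,
    labels) with labels in {"TP", "TRC"}.
    """
    if not 0.5 <= auc < 1.0:
        raise ValueError("auc must be in [0.5, 1)")
    if rng is None:
        rng = np.random.default_rng()
    delta = float(np.sqrt(2.0) * norm.ppf(auc))
    if direction == "lower":
        delta = -delta
    elif direction != "higher":
        raise ValueError(f"unknown direction {direction!r}")
    pos = rng.standard_normal(n_per_class) + delta
    neg = rng.standard_normal(n_per_class)
    scores = np.concatenate([pos, neg])
    labels = np.array(["TP"] * n_per_class + ["TRC"] * n_per_class)
    return scores, labels


@dataclass
class PatientTruth:
    """Ground-truth generating values for one synthetic patient.

    Curve-mode truths: ``cbv_ratio`` is the leakage-free tumor/reference CBV
    ratio (the K1 of the generating model), ``k2`` the leakage coefficient
    (1/s), ``slope`` the late TAC slope in SUV/h, plus the target TBRs and
    TTP.  ``dsc_true_area`` is filled in by the DSC generator with the area
    under the leakage-free tumor dR2* curve.
    """

    label: str = "TP"
    cbv_ratio: float = 2.9
    k2: float = 0.0
    slope: float = 0.23
    tbr_mean: float = 2.0
    tbr_max: float = 2.2
    ttp: float = 32.5
    dsc_true_area: float | None = None

    def __post_init__(self):
        if self.label not in ("TP", "TRC"):
            raise ValueError("label must be TP or TRC")
        for name in ("cbv_ratio", "k2", "slope", "tbr_mean", "tbr_max", "ttp"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"truth field {name} must be finite")


DEFAULT_ACQUISITION = DscAcquisition(te=0.032, tr=1.9, n_frames=50, baseline_window=(0, 8))


def gamma_variate_bolus(times: np.ndarray, t0: float, alpha: float, beta: float,
                        peak: float = 0.01) -> np.ndarray:
    """Gamma-variate first-pass bolus, peak-normalized to ``peak`` (1/s).

    Any smooth unimodal curve works for the leakage-correction algebra; the
    gamma variate is the conventional choice.  Peaks at t0 + alpha*beta.
    """
    tau = np.clip(times - t0, 0.0, None)
    g = (tau / beta) ** alpha * np.exp(alpha - tau / beta)
    return peak * g / alpha ** alpha  # maximum of g is alpha^alpha at tau = alpha*beta


def gen_dsc_roi_curves(truth: PatientTruth, acquisition: DscAcquisition = DEFAULT_ACQUISITION,
                       noise_sd: float = 0.0, seed: int | None = None,
                       s0: float = 1000.0, bolus_t0_frame: float = 10.0,
                       bolus_alpha: float = 3.0, bolus_beta_frames: float = 1.5,
                       ) -> tuple[DscSeries, DscSeries]:
    """Synthetic (tumor, reference) ROI signal curves for one patient.

    The reference dR2* is a gamma-variate bolus; the tumor curve is
    cbv_ratio * reference - k2 * (running integral of the reference), i.e.
    exactly the Boxerman-Weisskoff generating model, so the leakage fit
    recovers (cbv_ratio, k2) identically at zero noise.  Signals are
    S0 * exp(-TE * dR2*) plus optional additive Gaussian noise.  The true
    leakage-free tumor area is stored on ``truth.dsc_true_area``.
    """
    if acquisition.n_frames < 20:
        raise ValueError("acquisition must have at least 20 frames")
    times = acquisition.times
    ref = gamma_variate_bolus(times, t0=bolus_t0_frame * acquisition.tr,
                              alpha=bolus_alpha, beta=bolus_beta_frames * acquisition.tr)
    big_r = cumulative_trapezoid(ref, times, initial=0.0)
    tumor = truth.cbv_ratio * ref - truth.k2 * big_r
    truth.dsc_true_area = float(np.trapezoid(truth.cbv_ratio * ref, times))

    rng = np.random.default_rng(seed)
    series = []
    for dr2 in (tumor, ref):
        signal = s0 * np.exp(-acquisition.te * dr2)
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        if np.any(signal <= 0):
            raise ValueError("generated signal is nonpositive; reduce noise_sd or dR2* scale")
        series.append(DscSeries(times=times, signal=signal, acquisition=acquisition))
    return series[0], series[1]


def gen_tac(truth: PatientTruth, frames: np.ndarray | None = None,
            noise_sd: float = 0.0, seed: int | None = None,
            patient_weight: float = 75_000.0, injected_activity: float = 180e6,
            anchor_suv: float = 2.5) -> Tac:
    """Synthetic PET time-activity curve honoring slope, TTP and TBR exactly.

    The tumor mean SUV is an early uptake ramp followed by an exactly linear
    20-40 min phase with the requested slope (SUV/h).  The peak is placed at
    the frame nearest ``truth.ttp`` by adding a bump orthogonal to {1, t} on
    the 20-40 min frames, which leaves both the OLS slope and the window
    mean (hence TBR) unchanged.  The background is constant so that the
    window-averaged tumor/background ratio equals ``truth.tbr_mean``; the
    tumor max curve is a fixed multiple giving ``truth.tbr_max``.
    """
    if frames is None:
        frames = np.arange(2.5, 50.0, 5.0)  # 5-min frames, mid-times 2.5..47.5
    t = np.asarray(frames, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("frame mid-times must be strictly increasing")
    if t.min() > 20.0 or t.max() < 40.0:
        raise ValueError("frames must span the 20-40 min window")
    win = (t >= 20.0) & (t <= 40.0)
    if win.sum() < 3:
        raise ValueError("need at least 3 frames inside 20-40 min")

    m = truth.slope / 60.0  # SUV per minute
    curve = np.empty_like(t)
    curve[t >= 20.0] = anchor_suv + m * (t[t >= 20.0] - 20.0)
    # early uptake ramp strictly below the late-phase minimum
    early = t < 20.0
    if early.any():
        floor = curve[t >= 20.0].min()
        curve[early] = 0.3 * floor + 0.6 * floor * (t[early] / 20.0)

    # place the peak without disturbing the window OLS slope or window mean
    j = int(np.argmin(np.abs(t - truth.ttp)))
    if win[j]:
        tw = t[win]
        design = np.column_stack([np.ones_like(tw), tw])
        hat = design @ np.linalg.solve(design.T @ design, design.T)
        e = np.zeros(int(win.sum()))
        e[np.flatnonzero(win).tolist().index(j)] = 1.0
        bump = e - hat @ e
        lead = bump[np.flatnonzero(win).tolist().index(j)]
        scale = (curve.max() - curve[j] + 0.5 * anchor_suv) / lead
        full = np.zeros_like(curve)
        full[win] = scale * bump
        curve = curve + full
    else:
        curve[j] = curve.max() + 0.5 * anchor_suv
    if np.any(curve <= 0):
        raise ValueError("generated TAC is nonpositive; adjust anchor_suv or slope")
    if int(np.argmax(curve)) != j:
        raise ValueError("could not place the peak at the requested TTP")

    bg_suv = curve[win].mean() / truth.tbr_mean
    tumor_max = curve * (truth.tbr_max / truth.tbr_mean)

    to_activity = injected_activity / patient_weight  # SUV -> Bq/g
    rng = np.random.default_rng(seed)
    arrays = []
    for suv_curve in (curve, tumor_max, np.full_like(curve, bg_suv)):
        act = suv_curve * to_activity
        if noise_sd > 0:
            act = act + rng.normal(0.0, noise_sd * to_activity, size=act.shape)
        arrays.append(act)
    return Tac(frame_mid_times=t, tumor_mean_activity=arrays[0],
               tumor_max_activity=arrays[1], background_mean_activity=arrays[2],
               patient_weight=patient_weight, injected_activity=injected_activity)
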